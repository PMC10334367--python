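"""Setting transfer functions, Wiener regularization and FIR realization.

The setting transfer function Gamma(f, x) is the magnitude ratio of the
system responses of two scanner settings, estimated as
``|Gamma| = sqrt(P_test / P_train)`` from depth-aware power spectra of a
stable-acquisition calibration view (the common tissue term cancels in the
ratio).  Two SNR-aware Wiener-regularized responses are derived from it:

    Gamma_W     = (1/|Gamma|) / ((1/|Gamma|)^2 + 1/SNR)   (train-time, -> |Gamma|)
    Gamma_W^-1  = |Gamma| / (|Gamma|^2 + 1/SNR)           (test-time,  -> 1/|Gamma|)

Both tend to zero at bins with SNR = 0 (denoising behaviour out of band)
and to the unregularized response as SNR -> infinity.  The responses are
realized as odd-length type-I linear-phase FIR filters via frequency
sampling and applied along the axial (fast-time) axis with centered
same-length convolution, so the symmetric kernel introduces no net delay
and patch-grid coordinates stay valid after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, firwin2

from .rf_io import RFFrame
from .spectra import PowerSpectrum, SNRProfile

__all__ = [
    "SettingTransferFunction",
    "FIRFilter",
    "compute_gamma",
    "wiener_regularize",
    "make_transfer_function",
    "design_linear_phase_fir",
    "apply_filter_to_frame",
    "filter_frequency_response",
]


@dataclass
class SettingTransferFunction:
    """Per-depth-line magnitude responses on a common frequency grid."""

    freqs_hz: np.ndarray
    gamma_mag: np.ndarray
    gamma_wiener: np.ndarray
    gamma_wiener_inv: np.ndarray
    depth_line: int
    snr: SNRProfile


@dataclass
class FIRFilter:
    """Odd-length, symmetric (type-I linear-phase) time-domain realization."""

    taps: np.ndarray
    depth_line: int = -1
    direction: str = ""  # "train_time" or "test_time"

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.taps.ndim != 1 or self.taps.size % 2 == 0:
            raise ValueError("taps must be a 1-D array of odd length")
        if not np.allclose(self.taps, self.taps[::-1], atol=1e-12):
            raise ValueError("taps must be symmetric (linear phase, type I)")

    @property
    def n_taps(self) -> int:
        return self.taps.size


def compute_gamma(ps_train: PowerSpectrum, ps_test: PowerSpectrum) -> np.ndarray:
    """|Gamma| per bin: sqrt of the test/train power-spectral ratio.

    Bins with zero train power get |Gamma| = 0 rather than infinity; such
    bins carry SNR = 0 and are zeroed by the Wiener step anyway, so no
    spurious gain can leak through.
    """
    if ps_train.freqs_hz.shape != ps_test.freqs_hz.shape or not np.allclose(
        ps_train.freqs_hz, ps_test.freqs_hz
    ):
        raise ValueError("power spectra are on different frequency grids")
    out = np.zeros_like(ps_train.power)
    ok = ps_train.power > 0
    out[ok] = np.sqrt(ps_test.power[ok] / ps_train.power[ok])
    return out


def wiener_regularize(
    gamma_mag: np.ndarray, snr: SNRProfile | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """SNR-weighted damping of Gamma and of its inverse.

    Returns ``(gamma_wiener, gamma_wiener_inv)``.  Algebraically
    ``gamma_wiener = g * s / (s + g^2)`` and
    ``gamma_wiener_inv = g * s / (g^2 * s + 1)`` with ``g = |Gamma|`` and
    ``s`` the per-bin SNR; both forms are total: s = 0 yields 0, and the
    high-SNR limits are g and 1/g.
    """
    g = np.asarray(gamma_mag, dtype=float)
    s = np.asarray(snr.snr if isinstance(snr, SNRProfile) else snr, dtype=float)
    if g.shape != s.shape:
        raise ValueError("gamma and snr must share the frequency grid")
    if np.any(g < 0) or np.any(s < 0):
        raise ValueError("gamma and snr must be nonnegative")

    gw = np.zeros_like(g)
    gwi = np.zeros_like(g)
    pos = s > 0
    gw[pos] = g[pos] * s[pos] / (s[pos] + g[pos] ** 2)
    gwi_num = g[pos] * s[pos]
    gwi[pos] = gwi_num / (g[pos] ** 2 * s[pos] + 1.0)
    return gw, gwi


def make_transfer_function(
    ps_train: PowerSpectrum,
    ps_test: PowerSpectrum,
    noise_band_hz: tuple[float, float] | None = None,
) -> SettingTransferFunction:
    """Gamma, SNR and the Wiener pair for one depth line in one call."""
    from .spectra import DEFAULT_NOISE_BAND_HZ, estimate_snr

    band = DEFAULT_NOISE_BAND_HZ if noise_band_hz is None else noise_band_hz
    snr = estimate_snr(ps_train, ps_test, band)
    gamma = compute_gamma(ps_train, ps_test)
    gw, gwi = wiener_regularize(gamma, snr)
    return SettingTransferFunction(
        freqs_hz=ps_train.freqs_hz,
        gamma_mag=gamma,
        gamma_wiener=gw,
        gamma_wiener_inv=gwi,
        depth_line=ps_train.depth_line,
        snr=snr,
    )


def design_linear_phase_fir(
    freqs_hz: Sequence[float] | np.ndarray,
    gains: Sequence[float] | np.ndarray,
    n_taps: int = 51,
    sampling_rate_hz: float = 40e6,
    depth_line: int = -1,
    direction: str = "",
) -> FIRFilter:
    """Frequency-sampling design of a type-I filter for a magnitude response.

    ``freqs_hz`` must be nondecreasing and cover [0, Nyquist]; for smooth
    gain profiles the realized magnitude response tracks the requested
    gains closely in band (the windowed design trades exactness at the grid
    points for suppressed ripple).
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    g = np.asarray(gains, dtype=float)
    if n_taps % 2 == 0 or n_taps < 3:
        raise ValueError("n_taps must be odd and >= 3")
    if freqs.shape != g.shape or freqs.ndim != 1:
        raise ValueError("freqs and gains must be matching 1-D arrays")
    nyq = sampling_rate_hz / 2.0
    if freqs[0] != 0.0 or not np.isclose(freqs[-1], nyq):
        raise ValueError("frequency grid must start at 0 and end at Nyquist")
    if np.any(g < 0):
        raise ValueError("gains must be nonnegative")
    # Kaiser taper (beta 3): markedly less smoothing bias than Hamming on
    # the steep Wiener responses while still suppressing ripple from the
    # out-of-band cutoffs
    taps = firwin2(n_taps, freqs, g, fs=sampling_rate_hz, window=("kaiser", 3.0))
    # enforce exact tap symmetry against floating-point asymmetry
    taps = 0.5 * (taps + taps[::-1])
    return FIRFilter(taps=taps, depth_line=depth_line, direction=direction)


def filter_frequency_response(
    filt: FIRFilter, freqs_hz: np.ndarray, sampling_rate_hz: float
) -> np.ndarray:
    """Magnitude of the filter's DTFT at arbitrary frequencies."""
    n = np.arange(filt.n_taps) - filt.n_taps // 2
    ph = np.exp(-2j * np.pi * np.outer(np.asarray(freqs_hz), n) / sampling_rate_hz)
    return np.abs(ph @ filt.taps)


def apply_filter_to_frame(frame: RFFrame, filt: FIRFilter) -> RFFrame:
    """Axial (time-direction) convolution, zero-padded, same output shape.

    The kernel center is aligned with each output sample, so the symmetric
    taps impose no net group delay.
    """
    if filt.n_taps > frame.n_axial:
        raise ValueError(
            f"filter length {filt.n_taps} exceeds frame axial size {frame.n_axial}"
        )
    out = fftconvolve(frame.samples.astype(float), filt.taps[:, None], mode="same")
    return frame.with_samples(out)
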