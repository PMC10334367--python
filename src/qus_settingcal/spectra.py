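"""Depth-aware power-spectrum, noise-floor and SNR estimation.

Power spectra of a calibration stack are estimated per depth line: the
200-sample axial gate of that line is Hann-windowed on every A-line of
every repeat frame and the periodograms are averaged (Bartlett averaging
over 256 lateral lines x repeats).  The noise floor is the mean power in a
band just below Nyquist, outside the transducer bandwidth (default
18-20 MHz at 40 MHz sampling), and the per-bin SNR used by the Wiener
regularization is the pairwise minimum over the two settings of
(power - floor)_+ / floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .patching import PatchGridSpec
from .rf_io import CalibrationStack

__all__ = [
    "PowerSpectrum",
    "SNRProfile",
    "DEFAULT_NOISE_BAND_HZ",
    "estimate_line_spectrum",
    "estimate_noise_floor",
    "estimate_snr",
]

DEFAULT_NOISE_BAND_HZ: tuple[float, float] = (18e6, 20e6)


@dataclass
class PowerSpectrum:
    """One-sided averaged periodogram for one depth line and setting."""

    freqs_hz: np.ndarray
    power: np.ndarray
    depth_line: int = -1
    setting_id: str = ""

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs_hz and power must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class SNRProfile:
    """Per-bin SNR (pairwise minimum over train/test) plus the noise floors."""

    freqs_hz: np.ndarray
    snr: np.ndarray
    noise_floor: float
    noise_floor_train: float = float("nan")
    noise_floor_test: float = float("nan")

    def __post_init__(self) -> None:
        self.snr = np.asarray(self.snr, dtype=float)
        if np.any(~np.isfinite(self.snr)) or np.any(self.snr < 0):
            raise ValueError("snr must be finite and nonnegative")


def estimate_line_spectrum(
    stack: CalibrationStack,
    depth_line: int,
    spec: PatchGridSpec = PatchGridSpec(),
    n_fft: int = 512,
) -> PowerSpectrum:
    """Averaged periodogram of one depth line's gate across the whole stack.

    The gate is Hann-windowed and zero-padded to ``n_fft``; scaling follows
    the one-sided periodogram density convention (all downstream uses are
    ratios, so the absolute scale is immaterial but kept consistent).
    """
    gate = spec.patch_axial
    if n_fft < gate:
        raise ValueError(f"n_fft={n_fft} must be >= gate length {gate}")
    a0 = spec.axial_start(depth_line)
    fs = stack.sampling_rate_hz
    if a0 + gate > stack.shape[0]:
        raise ValueError("depth line gate exceeds frame axial size")

    w = hann(gate, sym=False)
    scale = 1.0 / (fs * np.sum(w**2))
    acc = np.zeros(n_fft // 2 + 1, dtype=float)
    n_seg = 0
    for frame in stack.frames:
        seg = frame.samples[a0 : a0 + gate, :].astype(float) * w[:, None]
        spec_f = rfft(seg, n_fft, axis=0)
        p = (np.abs(spec_f) ** 2).sum(axis=1)
        acc += p
        n_seg += seg.shape[1]
    power = acc * scale / n_seg
    power[1:-1] *= 2.0  # one-sided
    return PowerSpectrum(
        freqs_hz=rfftfreq(n_fft, 1.0 / fs),
        power=power,
        depth_line=depth_line,
        setting_id=stack.setting_id,
    )


def _band_mask(freqs_hz: np.ndarray, band_hz: tuple[float, float]) -> np.ndarray:
    lo, hi = band_hz
    if hi <= lo:
        raise ValueError("noise band must satisfy lo < hi")
    mask = (freqs_hz >= lo) & (freqs_hz <= hi)
    if not np.any(mask):
        raise ValueError(
            f"noise band [{lo:.3g}, {hi:.3g}] Hz contains no frequency bins"
        )
    return mask


def estimate_noise_floor(
    ps: PowerSpectrum, noise_band_hz: tuple[float, float] = DEFAULT_NOISE_BAND_HZ
) -> float:
    """Mean power over the out-of-band noise region."""
    return float(np.mean(ps.power[_band_mask(ps.freqs_hz, noise_band_hz)]))


def estimate_snr(
    ps_train: PowerSpectrum,
    ps_test: PowerSpectrum,
    noise_band_hz: tuple[float, float] = DEFAULT_NOISE_BAND_HZ,
) -> SNRProfile:
    """Per-bin SNR: noise-subtracted power over floor, minimum of the pair.

    ``snr_i = min( (P_train,i - nf_train)_+ / nf_train,
                   (P_test,i  - nf_test)_+ / nf_test )``
    Bins at or below the floor are clipped to zero.
    """
    if ps_train.freqs_hz.shape != ps_test.freqs_hz.shape or not np.allclose(
        ps_train.freqs_hz, ps_test.freqs_hz
    ):
        raise ValueError("power spectra are on different frequency grids")
    nf_tr = estimate_noise_floor(ps_train, noise_band_hz)
    nf_te = estimate_noise_floor(ps_test, noise_band_hz)
    snr_tr = np.maximum(ps_train.power - nf_tr, 0.0) / nf_tr
    snr_te = np.maximum(ps_test.power - nf_te, 0.0) / nf_te
    return SNRProfile(
        freqs_hz=ps_train.freqs_hz,
        snr=np.minimum(snr_tr, snr_te),
        noise_floor=max(nf_tr, nf_te),
        noise_floor_train=nf_tr,
        noise_floor_test=nf_te,
    )
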