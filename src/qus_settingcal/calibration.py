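"""End-to-end train-time and test-time setting calibration.

A :class:`SettingCalibrator` bundles, for every depth line of the patch
grid, the estimated setting transfer function and its two 51-tap FIR
realizations: the train-time filter (response Gamma_Wiener, mapping
training-setting data to the testing setting) and the test-time filter
(response Gamma_Wiener^-1, mapping testing-setting data back to the
training setting).

Filtering is depth-aware.  The exact rule — used on the classifier path —
is: convolve the whole frame with depth line i's filter and take only that
line's patches from the result (:func:`extract_calibrated_patches`), which
keeps FIR edge transients out of the 200-sample gates.  The frame-level
operations compose a single output frame by assigning each axial sample to
its nearest gate center's filter; adjacent lines' responses differ only
smoothly, so the seams are negligible, and the patch path remains exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .patching import Patch, PatchGridSpec, extract_patches
from .rf_io import CalibrationStack, FrameSet, RFFrame
from .spectra import (
    DEFAULT_NOISE_BAND_HZ,
    estimate_line_spectrum,
)
from .transfer import (
    FIRFilter,
    SettingTransferFunction,
    design_linear_phase_fir,
    make_transfer_function,
)

__all__ = [
    "ANALYSIS_BAND_HZ",
    "SettingCalibrator",
    "build_setting_calibrator",
    "calibrate_frame",
    "extract_calibrated_patches",
    "calibrate_train_time",
    "calibrate_test_time",
    "in_band_spectral_distance_db",
]

#: Usable transducer bandwidth for in-band summaries.
ANALYSIS_BAND_HZ: tuple[float, float] = (2e6, 7.5e6)


@dataclass
class SettingCalibrator:
    """Per-depth-line transfer functions and FIR filter pairs."""

    transfer_functions: list[SettingTransferFunction]
    train_filters: list[FIRFilter]
    test_filters: list[FIRFilter]
    grid: PatchGridSpec
    provenance: dict = field(default_factory=dict)

    @property
    def n_depth_lines(self) -> int:
        return len(self.transfer_functions)

    def filters(self, direction: str) -> list[FIRFilter]:
        if direction == "train_time":
            return self.train_filters
        if direction == "test_time":
            return self.test_filters
        raise ValueError("direction must be 'train_time' or 'test_time'")


def build_setting_calibrator(
    train_stack: CalibrationStack,
    test_stack: CalibrationStack,
    spec: PatchGridSpec = PatchGridSpec(),
    n_taps: int = 51,
    n_fft: int = 512,
    noise_band_hz: tuple[float, float] = DEFAULT_NOISE_BAND_HZ,
) -> SettingCalibrator:
    """Estimate the full depth-aware calibrator from two calibration stacks.

    Per depth line: averaged gate spectra for both settings -> noise floors
    -> per-bin SNR -> |Gamma| -> Wiener pair -> FIR pair.
    """
    if train_stack.shape != test_stack.shape:
        raise ValueError(
            f"stack geometry mismatch: {train_stack.shape} vs {test_stack.shape}"
        )
    if train_stack.sampling_rate_hz != test_stack.sampling_rate_hz:
        raise ValueError("stacks have different sampling rates")
    fs = train_stack.sampling_rate_hz

    tfs: list[SettingTransferFunction] = []
    f_train: list[FIRFilter] = []
    f_test: list[FIRFilter] = []
    for line in range(spec.n_axial_lines):
        ps_tr = estimate_line_spectrum(train_stack, line, spec, n_fft)
        ps_te = estimate_line_spectrum(test_stack, line, spec, n_fft)
        tf = make_transfer_function(ps_tr, ps_te, noise_band_hz)
        tfs.append(tf)
        f_train.append(
            design_linear_phase_fir(
                tf.freqs_hz, tf.gamma_wiener, n_taps, fs, line, "train_time"
            )
        )
        f_test.append(
            design_linear_phase_fir(
                tf.freqs_hz, tf.gamma_wiener_inv, n_taps, fs, line, "test_time"
            )
        )
    return SettingCalibrator(
        transfer_functions=tfs,
        train_filters=f_train,
        test_filters=f_test,
        grid=spec,
        provenance=dict(
            train_setting=train_stack.setting_id,
            test_setting=test_stack.setting_id,
            n_frames_train=len(train_stack),
            n_frames_test=len(test_stack),
            n_taps=n_taps,
            n_fft=n_fft,
            noise_band_hz=tuple(noise_band_hz),
        ),
    )


def _gate_centers(spec: PatchGridSpec) -> np.ndarray:
    return np.array(
        [spec.axial_start(i) + spec.patch_axial // 2 for i in range(spec.n_axial_lines)]
    )


def _filtered_band(
    samples: np.ndarray, taps: np.ndarray, row_lo: int, row_hi: int
) -> np.ndarray:
    """Rows [row_lo, row_hi) of the full-frame 'same' convolution.

    Convolves only the needed band plus a half-kernel margin; within the
    band this equals the full-frame centered zero-padded convolution.
    """
    half = len(taps) // 2
    lo = max(0, row_lo - half)
    hi = min(samples.shape[0], row_hi + half)
    seg = fftconvolve(samples[lo:hi].astype(float), taps[:, None], mode="same")
    return seg[row_lo - lo : row_hi - lo]


def calibrate_frame(
    frame: RFFrame, cal: SettingCalibrator, direction: str
) -> RFFrame:
    """Depth-aware filtering of a whole frame (nearest-gate-center bands)."""
    filters = cal.filters(direction)
    spec = cal.grid
    centers = _gate_centers(spec)
    bounds = np.concatenate(
        ([0], ((centers[:-1] + centers[1:]) // 2).astype(int), [frame.n_axial])
    )
    out = np.empty_like(frame.samples, dtype=float)
    for i, filt in enumerate(filters):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        if hi > lo:
            out[lo:hi] = _filtered_band(frame.samples, filt.taps, lo, hi)
    return frame.with_samples(out)


def extract_calibrated_patches(
    frame: RFFrame,
    cal: SettingCalibrator,
    direction: str,
    spec: PatchGridSpec | None = None,
) -> list[Patch]:
    """Exact depth-aware path: per line, filter the frame and take that
    line's patches from the result (row-major order, as uncalibrated
    extraction)."""
    spec = cal.grid if spec is None else spec
    filters = cal.filters(direction)
    out: list[Patch] = []
    for i in range(spec.n_axial_lines):
        a0 = spec.axial_start(i)
        band = _filtered_band(
            frame.samples, filters[i].taps, a0, a0 + spec.patch_axial
        )
        for j in range(spec.n_lateral_lines):
            l0 = spec.lateral_start(j)
            out.append(
                Patch(
                    samples=band[:, l0 : l0 + spec.patch_lateral].copy(),
                    depth_line=i,
                    lateral_line=j,
                    frame_index=frame.frame_index,
                    label=frame.phantom_id,
                )
            )
    return out


def calibrate_train_time(
    training: FrameSet,
    cal: SettingCalibrator,
    fraction: float = 1.0,
    seed: int = 0,
) -> FrameSet:
    """Replace a uniform random fraction of the training frames by their
    train-time-filtered versions (domain mixing; labels and order kept)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = len(training)
    n_sel = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_sel, replace=False).tolist())
    frames = [
        calibrate_frame(f, cal, "train_time") if i in chosen else f
        for i, f in enumerate(training.frames)
    ]
    return FrameSet(frames=frames, labels=list(training.labels))


def calibrate_test_time(testing: FrameSet, cal: SettingCalibrator) -> FrameSet:
    """Filter every test frame back to the training setting."""
    frames = [calibrate_frame(f, cal, "test_time") for f in testing.frames]
    return FrameSet(frames=frames, labels=list(testing.labels))


def in_band_spectral_distance_db(
    set_a: FrameSet | CalibrationStack,
    set_b: FrameSet | CalibrationStack,
    spec: PatchGridSpec = PatchGridSpec(),
    band_hz: tuple[float, float] = ANALYSIS_BAND_HZ,
    n_fft: int = 512,
) -> float:
    """Mean absolute dB difference of depth-line spectra over the analysis band.

    Spectra are averaged over all frames and lateral lines per depth line;
    the distance is the mean of |10 log10(P_a / P_b)| over in-band bins and
    all depth lines.
    """
    def as_stack(s) -> CalibrationStack:
        if isinstance(s, CalibrationStack):
            return s
        return CalibrationStack(frames=list(s.frames), setting_id="")

    sa, sb = as_stack(set_a), as_stack(set_b)
    dists = []
    for line in range(spec.n_axial_lines):
        pa = estimate_line_spectrum(sa, line, spec, n_fft)
        pb = estimate_line_spectrum(sb, line, spec, n_fft)
        mask = (pa.freqs_hz >= band_hz[0]) & (pa.freqs_hz <= band_hz[1])
        ratio = pa.power[mask] / pb.power[mask]
        dists.append(np.mean(np.abs(10.0 * np.log10(ratio))))
    return float(np.mean(dists))
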