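"""Containers and I/O for post-beamformed ultrasound RF data.

An :class:`RFFrame` is one post-beamformed frame of raw radio-frequency
echo data, ``samples[axial, lateral]``: the axial index is fast time
(depth), the lateral index is the A-line number.  Indices are 0-based
everywhere.  Samples are kept as 32-bit floats — calibration is linear, so
integer ADC counts lose nothing but scale by the cast.

Framesets are persisted as a single HDF5 container with one
``frames [n_frames, n_axial, n_lateral]`` dataset plus string metadata,
which round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "RFFrame",
    "FrameSet",
    "CalibrationStack",
    "save_frameset",
    "load_frameset",
    "save_calibration_stack",
    "load_calibration_stack",
    "split_frames",
]


@dataclass
class RFFrame:
    """One post-beamformed RF frame with its sampling metadata.

    Parameters
    ----------
    samples
        Real matrix ``[n_axial, n_lateral]`` in arbitrary linear amplitude
        units; stored as float32.
    sampling_rate_hz
        Axial (fast-time) sampling rate, e.g. ``40e6``.
    axial_depth_m
        Imaging depth covered by the axial axis, e.g. ``0.04``.
    setting_id, phantom_id
        Free-form tokens identifying the scanner setting and the imaged
        medium.
    frame_index
        Position of the frame in its acquisition sequence.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    axial_depth_m: float = 0.04
    setting_id: str = ""
    phantom_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_axial, n_lateral] matrix")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("frame must have at least one axial and one lateral sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("frame contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.samples.shape[1]

    def with_samples(self, samples: np.ndarray) -> "RFFrame":
        """Copy of this frame with new sample data, metadata preserved."""
        return RFFrame(
            samples=samples,
            sampling_rate_hz=self.sampling_rate_hz,
            axial_depth_m=self.axial_depth_m,
            setting_id=self.setting_id,
            phantom_id=self.phantom_id,
            frame_index=self.frame_index,
        )


def _check_uniform(frames: Sequence[RFFrame]) -> None:
    if not frames:
        return
    shape = frames[0].samples.shape
    fs = frames[0].sampling_rate_hz
    for f in frames:
        if f.samples.shape != shape:
            raise ValueError(
                f"all frames must share dimensions; got {f.samples.shape} vs {shape}"
            )
        if f.sampling_rate_hz != fs:
            raise ValueError("all frames must share sampling_rate_hz")


@dataclass
class FrameSet:
    """Ordered collection of same-geometry frames with per-frame class labels."""

    frames: list[RFFrame] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.labels):
            raise ValueError("frames and labels must have equal length")
        _check_uniform(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[RFFrame, str]]:
        return iter(zip(self.frames, self.labels))


@dataclass
class CalibrationStack:
    """Repeated identical-view frames of the calibration medium at one setting.

    Intended use is a stable acquisition: the transducer is clamped so every
    repeat images the exact same medium realization and only noise varies;
    ten repeats is the conventional count, but any count >= 1 is accepted.
    """

    frames: list[RFFrame] = field(default_factory=list)
    setting_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("calibration stack needs at least one frame")
        _check_uniform(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def sampling_rate_hz(self) -> float:
        return self.frames[0].sampling_rate_hz

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].samples.shape


_STR = h5py.string_dtype(encoding="utf-8")


def _write_frames(g: h5py.Group, frames: Sequence[RFFrame]) -> None:
    data = np.stack([f.samples for f in frames]).astype(np.float32)
    g.create_dataset("frames", data=data)
    g.attrs["sampling_rate_hz"] = float(frames[0].sampling_rate_hz)
    g.attrs["axial_depth_m"] = float(frames[0].axial_depth_m)
    g.create_dataset("setting_id", data=[f.setting_id for f in frames], dtype=_STR)
    g.create_dataset("phantom_id", data=[f.phantom_id for f in frames], dtype=_STR)
    g.create_dataset("frame_index", data=[f.frame_index for f in frames], dtype=np.int64)


def _read_frames(g: h5py.Group, path: Path) -> list[RFFrame]:
    for key in ("frames", "setting_id", "phantom_id", "frame_index"):
        if key not in g:
            raise IOError(f"{path}: container is missing dataset '{key}'")
    for attr in ("sampling_rate_hz", "axial_depth_m"):
        if attr not in g.attrs:
            raise IOError(f"{path}: container is missing attribute '{attr}'")
    data = g["frames"][...]
    setting = [s.decode() if isinstance(s, bytes) else str(s) for s in g["setting_id"][...]]
    phantom = [s.decode() if isinstance(s, bytes) else str(s) for s in g["phantom_id"][...]]
    index = g["frame_index"][...]
    fs = float(g.attrs["sampling_rate_hz"])
    depth = float(g.attrs["axial_depth_m"])
    return [
        RFFrame(data[i], fs, depth, setting[i], phantom[i], int(index[i]))
        for i in range(data.shape[0])
    ]


def save_frameset(fs: FrameSet, path: str | Path) -> None:
    """Write a :class:`FrameSet` to an HDF5 container (lossless)."""
    path = Path(path)
    if len(fs) == 0:
        raise ValueError("refusing to save an empty FrameSet")
    with h5py.File(path, "w") as h5:
        _write_frames(h5, fs.frames)
        h5.create_dataset("labels", data=list(fs.labels), dtype=_STR)


def load_frameset(path: str | Path) -> FrameSet:
    """Read a :class:`FrameSet`; raises ``IOError`` naming any missing key."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        frames = _read_frames(h5, path)
        if "labels" not in h5:
            raise IOError(f"{path}: container is missing dataset 'labels'")
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["labels"][...]]
    return FrameSet(frames=frames, labels=labels)


def save_calibration_stack(stack: CalibrationStack, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        _write_frames(h5, stack.frames)
        h5.attrs["stack_setting_id"] = stack.setting_id


def load_calibration_stack(path: str | Path) -> CalibrationStack:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        frames = _read_frames(h5, path)
        setting_id = str(h5.attrs.get("stack_setting_id", ""))
    return CalibrationStack(frames=frames, setting_id=setting_id)


def split_frames(
    fs: FrameSet, n_select: int, seed: int
) -> tuple[FrameSet, FrameSet]:
    """Uniform random split of a FrameSet without replacement.

    Returns ``(selected, remainder)``; both preserve the original frame
    order internally, their union is the input and they are disjoint.  The
    split is deterministic for a fixed ``seed``.
    """
    n = len(fs)
    if not 0 <= n_select <= n:
        raise ValueError(f"n_select={n_select} out of range for {n} frames")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=n_select, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    sel = FrameSet(
        frames=[fs.frames[i] for i in range(n) if mask[i]],
        labels=[fs.labels[i] for i in range(n) if mask[i]],
    )
    rem = FrameSet(
        frames=[fs.frames[i] for i in range(n) if not mask[i]],
        labels=[fs.labels[i] for i in range(n) if not mask[i]],
    )
    return sel, rem
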