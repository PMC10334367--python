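"""Deterministic 9 x 9 patch-grid extraction from RF frames.

The grid skips the first 540 axial samples (near field), then places nine
axial lines of 200-sample gates at a 100-sample stride (50% axial overlap)
and nine lateral lines of 26 A-lines at a 26-line stride (exact lateral
tiling).  All coordinates are 0-based half-open intervals.  Each patch
carries its depth-line index so depth-aware calibration filters can be
matched to it downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rf_io import RFFrame

__all__ = ["PatchGridSpec", "Patch", "extract_patches", "depth_line_of"]


@dataclass(frozen=True)
class PatchGridSpec:
    """Patch extraction geometry (fixed line counts, not maximal tiling)."""

    skip_axial: int = 540
    patch_axial: int = 200
    patch_lateral: int = 26
    stride_axial: int = 100
    stride_lateral: int = 26
    n_axial_lines: int = 9
    n_lateral_lines: int = 9

    @property
    def min_axial(self) -> int:
        """Smallest frame axial size admitting the full grid."""
        return (
            self.skip_axial
            + (self.n_axial_lines - 1) * self.stride_axial
            + self.patch_axial
        )

    @property
    def min_lateral(self) -> int:
        return (self.n_lateral_lines - 1) * self.stride_lateral + self.patch_lateral

    def axial_start(self, depth_line: int) -> int:
        if not 0 <= depth_line < self.n_axial_lines:
            raise ValueError(f"depth_line {depth_line} out of range")
        return self.skip_axial + depth_line * self.stride_axial

    def lateral_start(self, lateral_line: int) -> int:
        if not 0 <= lateral_line < self.n_lateral_lines:
            raise ValueError(f"lateral_line {lateral_line} out of range")
        return lateral_line * self.stride_lateral


@dataclass
class Patch:
    """One classifier input block with its grid coordinates and label."""

    samples: np.ndarray
    depth_line: int
    lateral_line: int
    frame_index: int = 0
    label: str = ""


def extract_patches(frame: RFFrame, spec: PatchGridSpec = PatchGridSpec()) -> list[Patch]:
    """Extract the full grid, row-major (depth line outer, lateral inner).

    Patch (i, j) covers axial samples
    ``[skip + i*stride_axial, skip + i*stride_axial + patch_axial)`` and
    lateral lines ``[j*stride_lateral, j*stride_lateral + patch_lateral)``.
    """
    if frame.n_axial < spec.min_axial:
        raise ValueError(
            f"frame axial size {frame.n_axial} < required {spec.min_axial}"
        )
    if frame.n_lateral < spec.min_lateral:
        raise ValueError(
            f"frame lateral size {frame.n_lateral} < required {spec.min_lateral}"
        )
    out: list[Patch] = []
    for i in range(spec.n_axial_lines):
        a0 = spec.axial_start(i)
        for j in range(spec.n_lateral_lines):
            l0 = spec.lateral_start(j)
            out.append(
                Patch(
                    samples=frame.samples[
                        a0 : a0 + spec.patch_axial, l0 : l0 + spec.patch_lateral
                    ].copy(),
                    depth_line=i,
                    lateral_line=j,
                    frame_index=frame.frame_index,
                    label=frame.phantom_id,
                )
            )
    return out


def depth_line_of(axial_start: int, spec: PatchGridSpec = PatchGridSpec()) -> int:
    """Depth-line index i such that axial_start == skip + i*stride_axial."""
    off = axial_start - spec.skip_axial
    if off < 0 or off % spec.stride_axial != 0:
        raise ValueError(f"axial start {axial_start} is not on the patch grid")
    i = off // spec.stride_axial
    if i >= spec.n_axial_lines:
        raise ValueError(f"axial start {axial_start} is beyond the last depth line")
    return i
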