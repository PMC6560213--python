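"""Angiographic frame combination and maximum-intensity projections.

Fast inflowing spins carry fresh magnetization into the slice and stay
bright late in the flip-angle ramp, while stationary tissue is driven toward
saturation; summing the magnitudes of late frames therefore yields an
inflow-angiography-like image, and a maximum intensity projection across
slices renders the vasculature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProjectionSpec", "combine_frames", "mip"]


@dataclass(frozen=True)
class ProjectionSpec:
    """Inclusive, 0-based frame range and projection axis."""

    start: int
    end: int
    axis: int = 0

    def __post_init__(self):
        if not 0 <= self.start <= self.end:
            raise ValueError("need 0 <= start <= end")


def combine_frames(frames: np.ndarray, spec: ProjectionSpec) -> np.ndarray:
    """Sum |frame| over the inclusive range [start, end].

    ``frames``: complex array with the frame index on axis 0.  The default
    angiographic combination uses the last 160 of 260 frames, i.e.
    ``ProjectionSpec(100, 259)``.
    """
    if spec.end >= frames.shape[0]:
        raise ValueError("frame range exceeds the series length")
    return np.abs(frames[spec.start:spec.end + 1]).sum(axis=0)


def mip(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along ``axis``."""
    return np.max(volume, axis=axis)
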