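"""Frame-wise displacement from rigid-body realignment parameters.

Head motion between consecutive fMRI volumes is summarized per frame as

    FWD_t = sum_i |d translation_i| + r * sum_i |d rotation_i|

with translations in mm, rotations in radians converted to arc length on
a sphere of radius ``r`` (50 mm, the conventional head radius).  Frames
above a displacement threshold are flagged for quality review; censoring
itself is left to the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["FWDSeries", "framewise_displacement", "flag_frames"]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FWD_THRESHOLD_MM = 0.5


@dataclass
class FWDSeries:
    """Per-frame displacement (mm); the first frame is 0 by definition."""

    displacement: np.ndarray
    head_radius: float = DEFAULT_HEAD_RADIUS_MM

    @property
    def mean(self) -> float:
        return float(self.displacement.mean())

    def flagged(self, threshold: float = DEFAULT_FWD_THRESHOLD_MM) -> np.ndarray:
        return flag_frames(self, threshold)


def framewise_displacement(trace, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> FWDSeries:
    """Frame-wise displacement of a 6-parameter rigid-body motion trace.

    ``trace`` has one row per retained volume and columns
    ``(tx, ty, tz, rx, ry, rz)`` — translations in mm, rotations in
    radians.  Depends only on frame-to-frame differences, so a constant
    offset of the whole trace leaves the result unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise InvalidArgumentError("motion trace must be (n_frames, 6)")
    if trace.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 frames")
    if not np.all(np.isfinite(trace)):
        raise InvalidArgumentError("motion trace contains non-finite values")
    delta = np.abs(np.diff(trace, axis=0))
    fwd = delta[:, :3].sum(axis=1) + head_radius * delta[:, 3:].sum(axis=1)
    return FWDSeries(
        displacement=np.concatenate([[0.0], fwd]), head_radius=head_radius
    )


def flag_frames(fwd: FWDSeries | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of frames whose displacement exceeds ``threshold`` mm."""
    disp = fwd.displacement if isinstance(fwd, FWDSeries) else np.asarray(fwd, float)
    if threshold < 0:
        raise InvalidArgumentError("threshold must be nonnegative")
    return disp > threshold
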