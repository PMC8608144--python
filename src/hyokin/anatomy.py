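"""Anatomically normalized hyoid coordinates.

Raw pixel landmarks are mapped into a patient-intrinsic frame: the origin
sits at the anterior-inferior corner of C4, the y-axis runs along the
C2-C4 spine segment (superior positive), and the x-axis is the orthogonal
direction pointing anteriorly.  All distances are expressed as a percentage
of the C2-C4 length, written %(C2-4).  This single normalization removes
body-size, magnification and head-tilt differences between recordings, so
hyoid positions are comparable across participants and sessions.

Because the spine landmarks are re-marked on every frame, the scalar and
the axes are recomputed per frame by default, which keeps the coordinates
valid under patient motion during the swallow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .landmark_io import LandmarkFrame, SwallowRecording, ValidationError

__all__ = ["AnatomicalTrack", "compute_scalar", "to_anatomical", "track_recording"]

Facing = Literal["left", "right"]


@dataclass
class AnatomicalTrack:
    """Per-frame hyoid position in %(C2-4) units, C4 origin.

    ``X`` (anterior positive), ``Y`` (superior positive) and their
    hypotenuse ``XY`` are NaN exactly where the hyoid landmark was absent.
    ``scalar_px`` is the per-frame C2-C4 length in pixels.
    """

    frame_index: np.ndarray  # (n,) int
    X: np.ndarray  # (n,) float, NaN where hyoid absent
    Y: np.ndarray
    XY: np.ndarray
    scalar_px: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        for name in ("X", "Y", "XY", "scalar_px"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.XY)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def position(self, frame: int) -> int:
        """Array position of a frame index; raises if the frame is unknown."""
        hits = np.nonzero(self.frame_index == frame)[0]
        if not len(hits):
            raise ValueError(f"frame {frame} not in track")
        return int(hits[0])

    def xy_at(self, frame: int) -> float:
        return float(self.XY[self.position(frame)])


def compute_scalar(frame: LandmarkFrame) -> float:
    """C2-C4 spine length in pixels for one frame (the normalization scalar)."""
    scalar = float(np.linalg.norm(frame.c2 - frame.c4))
    if scalar == 0.0:
        raise ValidationError(
            f"frame {frame.frame_index}: C2 and C4 coincide, scalar undefined"
        )
    return scalar


def _axes(frame: LandmarkFrame, facing: Facing) -> tuple[np.ndarray, np.ndarray, float]:
    scalar = compute_scalar(frame)
    y_unit = (frame.c2 - frame.c4) / scalar
    # Orthogonal in the image plane; which of the two candidates is anterior
    # depends on which way the patient faces.  In image convention (y down),
    # for a right-facing patient anterior is toward increasing column.
    if facing == "right":
        x_unit = np.array([-y_unit[1], y_unit[0]])
    elif facing == "left":
        x_unit = np.array([y_unit[1], -y_unit[0]])
    else:
        raise ValueError(f"facing must be 'left' or 'right', got {facing!r}")
    return x_unit, y_unit, scalar


def to_anatomical(
    frame: LandmarkFrame, facing: Facing = "right"
) -> tuple[float, float, float, float]:
    """Map one frame's hyoid landmark into the C4-origin spine frame.

    Returns ``(X, Y, XY, scalar_px)`` in %(C2-4) units; all three
    coordinates are NaN when the hyoid is absent (never zeros, which would
    silently pin the hyoid to the origin).
    """
    x_unit, y_unit, scalar = _axes(frame, facing)
    if frame.hyoid is None:
        return (float("nan"), float("nan"), float("nan"), scalar)
    rel = frame.hyoid - frame.c4
    X = float(rel @ x_unit) / scalar * 100.0
    Y = float(rel @ y_unit) / scalar * 100.0
    return (X, Y, float(np.hypot(X, Y)), scalar)


def track_recording(
    rec: SwallowRecording,
    facing: Facing = "right",
    *,
    reference_frame: Optional[int] = None,
) -> AnatomicalTrack:
    """Convert every frame of a recording to anatomical coordinates.

    The C2-C4 scalar and axes are recomputed per frame; passing
    ``reference_frame`` instead normalizes every frame by that single
    frame's geometry (useful when spine annotations on other frames are
    unreliable).

    Emits a ``check facing`` warning when the mean anterior coordinate is
    negative, which almost always means the facing flag disagrees with the
    image orientation; values are left untouched.
    """
    if not rec.frames:
        raise ValidationError(f"recording {rec.recording_id}: no frames")
    if all(f.hyoid is None for f in rec.frames):
        raise ValidationError(f"recording {rec.recording_id}: no trackable hyoid")

    ref_axes = None
    if reference_frame is not None:
        ref = next((f for f in rec.frames if f.frame_index == reference_frame), None)
        if ref is None:
            raise ValueError(f"reference frame {reference_frame} not in recording")
        ref_axes = _axes(ref, facing)

    n = rec.n_frames
    idx = np.empty(n, dtype=int)
    X, Y, XY, scalar_px = (np.full(n, np.nan) for _ in range(4))
    for i, frame in enumerate(rec.frames):
        idx[i] = frame.frame_index
        if ref_axes is None:
            X[i], Y[i], XY[i], scalar_px[i] = to_anatomical(frame, facing)
        else:
            x_unit, y_unit, scalar = ref_axes
            scalar_px[i] = scalar
            if frame.hyoid is not None:
                rel = frame.hyoid - frame.c4
                X[i] = float(rel @ x_unit) / scalar * 100.0
                Y[i] = float(rel @ y_unit) / scalar * 100.0
                XY[i] = float(np.hypot(X[i], Y[i]))

    if np.nanmean(X) < 0:
        warnings.warn(
            f"recording {rec.recording_id}: mean hyoid X is negative - "
            "check facing (the hyoid should sit anterior to the spine)",
            stacklevel=2,
        )
    return AnatomicalTrack(idx, X, Y, XY, scalar_px)
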