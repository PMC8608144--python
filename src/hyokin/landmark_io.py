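"""Reading, validation and writing of per-frame landmark annotations.

Lateral-view videofluoroscopy raters mark three structures on every frame:
the anterior-inferior corners of the C2 and C4 vertebrae and of the hyoid
bone.  This module defines the in-memory model for those annotations
(:class:`LandmarkFrame`, :class:`SwallowRecording`), the stimulus coding
(:class:`StimulusLevel`), and plain-CSV readers/writers so datasets survive
round trips through spreadsheets and tracking tools.

Pixel coordinates use image convention: ``x`` is the column index increasing
rightward, ``y`` is the row index increasing downward.  The anatomical
coordinate flip is owned by :mod:`hyokin.anatomy`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "Consistency",
    "Thickener",
    "Administration",
    "StimulusLevel",
    "STIMULUS_ORDER",
    "LandmarkFrame",
    "SwallowRecording",
    "read_landmarks",
    "write_landmarks",
    "validate_recording",
]

LANDMARK_COLUMNS = [
    "recording_id",
    "frame_index",
    "c2_x",
    "c2_y",
    "c4_x",
    "c4_y",
    "hyoid_x",
    "hyoid_y",
]

METADATA_COLUMNS = [
    "recording_id",
    "participant_id",
    "consistency",
    "thickener",
    "repetition",
    "sip_volume_ml",
    "frame_rate_hz",
    "annotated_burst_frame",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Annotation content violates a structural invariant."""


class Consistency(Enum):
    """IDDSI liquid consistency levels, thin (0) through extremely thick (4)."""

    TN0 = 0
    ST1 = 1
    MT2 = 2
    MO3 = 3
    EX4 = 4


class Thickener(Enum):
    NONE = "none"
    GUM = "gum"
    STARCH = "starch"


class Administration(Enum):
    CUP = "cup"
    SPOON = "spoon"


@dataclass(frozen=True)
class StimulusLevel:
    """One of the nine liquid stimuli: a consistency plus a thickener.

    Thin liquid carries no thickener; every thickened level exists in a
    gum- and a starch-based variant.  Administration is derived from
    consistency: moderately and extremely thick liquids are taken by
    teaspoon, everything thinner by cup sip.
    """

    consistency: Consistency
    thickener: Thickener

    def __post_init__(self) -> None:
        if self.consistency is Consistency.TN0:
            if self.thickener is not Thickener.NONE:
                raise ValidationError("thin liquid takes no thickener")
        elif self.thickener is Thickener.NONE:
            raise ValidationError(
                f"{self.consistency.name} requires a gum or starch thickener"
            )

    @property
    def administration(self) -> Administration:
        if self.consistency in (Consistency.MO3, Consistency.EX4):
            return Administration.SPOON
        return Administration.CUP

    @property
    def label(self) -> str:
        """Short code as used in figure legends, e.g. ``ST1-G``, ``TN0``."""
        if self.consistency is Consistency.TN0:
            return "TN0"
        suffix = "G" if self.thickener is Thickener.GUM else "S"
        return f"{self.consistency.name}-{suffix}"

    @classmethod
    def parse(cls, label: str) -> "StimulusLevel":
        label = label.strip()
        if label == "TN0":
            return cls(Consistency.TN0, Thickener.NONE)
        try:
            cons_part, thick_part = label.split("-")
            consistency = Consistency[cons_part]
            thickener = {"G": Thickener.GUM, "S": Thickener.STARCH}[thick_part]
        except (ValueError, KeyError) as exc:
            raise FormatError(f"unrecognized stimulus label {label!r}") from exc
        return cls(consistency, thickener)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Canonical table row order: thin first, then by increasing thickness with
#: the starch variant before the gum variant within each level.
STIMULUS_ORDER: tuple[StimulusLevel, ...] = (
    StimulusLevel(Consistency.TN0, Thickener.NONE),
    StimulusLevel(Consistency.ST1, Thickener.STARCH),
    StimulusLevel(Consistency.ST1, Thickener.GUM),
    StimulusLevel(Consistency.MT2, Thickener.STARCH),
    StimulusLevel(Consistency.MT2, Thickener.GUM),
    StimulusLevel(Consistency.MO3, Thickener.STARCH),
    StimulusLevel(Consistency.MO3, Thickener.GUM),
    StimulusLevel(Consistency.EX4, Thickener.STARCH),
    StimulusLevel(Consistency.EX4, Thickener.GUM),
)


def _as_point(value) -> np.ndarray:
    if isinstance(value, np.ndarray) and value.shape == (2,) and value.dtype == np.float64:
        arr = value
    else:
        arr = np.asarray(value, dtype=float)
        if arr.shape != (2,):
            raise ValidationError(
                f"a landmark point must be 2-D, got shape {arr.shape}"
            )
    if not (math.isfinite(arr[0]) and math.isfinite(arr[1])):
        raise ValidationError("landmark coordinates must be finite")
    return arr


@dataclass
class LandmarkFrame:
    """Raw pixel landmarks for a single video frame.

    ``hyoid`` is ``None`` when the hyoid was out of the field of view or
    obstructed; the frame is still kept so the timeline stays intact.
    """

    frame_index: int
    c2: np.ndarray
    c4: np.ndarray
    hyoid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError("frame_index must be non-negative")
        self.c2 = _as_point(self.c2)
        self.c4 = _as_point(self.c4)
        if self.hyoid is not None:
            self.hyoid = _as_point(self.hyoid)
        if self.c2[0] == self.c4[0] and self.c2[1] == self.c4[1]:
            raise ValidationError(
                f"frame {self.frame_index}: C2 and C4 coincide (zero-length spine)"
            )


@dataclass
class SwallowRecording:
    """All frames of one bolus swallow plus its protocol metadata."""

    recording_id: str
    participant_id: str
    stimulus: StimulusLevel
    repetition: int
    sip_volume_ml: float
    frames: list[LandmarkFrame] = field(default_factory=list)
    frame_rate_hz: float = 30.0
    annotated_burst_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")
        if self.sip_volume_ml < 0:
            raise ValidationError("sip_volume_ml must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        indices = [f.frame_index for f in self.frames]
        if len(set(indices)) != len(indices):
            raise ValidationError(
                f"recording {self.recording_id}: duplicate frame indices"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_hyoid_present(self) -> int:
        return sum(1 for f in self.frames if f.hyoid is not None)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_landmarks(path, metadata_path) -> list[SwallowRecording]:
    """Read a landmark CSV plus its metadata CSV into recordings.

    Empty ``hyoid_x``/``hyoid_y`` cells become absent hyoid points.  Frames
    are returned sorted by frame index; one recording per ``recording_id``
    in the metadata file order.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    ids_as_text = {"recording_id": str, "participant_id": str}
    landmarks = pd.read_csv(
        path, dtype={"recording_id": str}, float_precision="round_trip"
    )
    metadata = pd.read_csv(
        metadata_path, dtype=ids_as_text, float_precision="round_trip"
    )
    _require_columns(landmarks, LANDMARK_COLUMNS, path)
    _require_columns(metadata, METADATA_COLUMNS, metadata_path)

    grouped = dict(tuple(landmarks.groupby("recording_id", sort=False)))
    recordings: list[SwallowRecording] = []
    for row in metadata.itertuples(index=False):
        rec_id = str(row.recording_id)
        rows = grouped.pop(rec_id, None)
        if rows is None:
            raise FormatError(f"{path}: no landmark rows for recording {rec_id!r}")
        frames = []
        for fr in rows.sort_values("frame_index").itertuples(index=False):
            hyoid = None
            if not (pd.isna(fr.hyoid_x) or pd.isna(fr.hyoid_y)):
                hyoid = (float(fr.hyoid_x), float(fr.hyoid_y))
            try:
                frames.append(
                    LandmarkFrame(
                        frame_index=int(fr.frame_index),
                        c2=(float(fr.c2_x), float(fr.c2_y)),
                        c4=(float(fr.c4_x), float(fr.c4_y)),
                        hyoid=hyoid,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"recording {rec_id!r}: {exc}") from exc
        burst = None
        if not pd.isna(row.annotated_burst_frame):
            burst = int(row.annotated_burst_frame)
        frame_rate = 30.0 if pd.isna(row.frame_rate_hz) else float(row.frame_rate_hz)
        recordings.append(
            SwallowRecording(
                recording_id=rec_id,
                participant_id=str(row.participant_id),
                stimulus=StimulusLevel(
                    Consistency[str(row.consistency)],
                    Thickener(str(row.thickener)),
                ),
                repetition=int(row.repetition),
                sip_volume_ml=float(row.sip_volume_ml),
                frames=frames,
                frame_rate_hz=frame_rate,
                annotated_burst_frame=burst,
            )
        )
    if grouped:
        orphans = ", ".join(repr(k) for k in grouped)
        raise FormatError(f"{metadata_path}: no metadata for recording(s) {orphans}")
    return recordings


def write_landmarks(recordings: Sequence[SwallowRecording], path, metadata_path) -> None:
    """Write recordings to a landmark CSV and a metadata CSV.

    The written files round-trip exactly through :func:`read_landmarks`:
    coordinates are emitted at full ``repr`` precision and absent hyoid
    points become empty cells.
    """
    lm_rows = []
    md_rows = []
    for rec in recordings:
        for fr in rec.frames:
            hx, hy = ("", "") if fr.hyoid is None else (fr.hyoid[0], fr.hyoid[1])
            lm_rows.append(
                (rec.recording_id, fr.frame_index, fr.c2[0], fr.c2[1], fr.c4[0], fr.c4[1], hx, hy)
            )
        md_rows.append(
            (
                rec.recording_id,
                rec.participant_id,
                rec.stimulus.consistency.name,
                rec.stimulus.thickener.value,
                rec.repetition,
                rec.sip_volume_ml,
                rec.frame_rate_hz,
                "" if rec.annotated_burst_frame is None else rec.annotated_burst_frame,
            )
        )
    # repr(float) gives the shortest decimal that round-trips exactly
    fmt = lambda v: repr(float(v))  # noqa: E731
    pd.DataFrame(lm_rows, columns=LANDMARK_COLUMNS).to_csv(
        path, index=False, float_format=fmt
    )
    pd.DataFrame(md_rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, index=False, float_format=fmt
    )


def validate_recording(
    rec: SwallowRecording,
    *,
    max_missing_fraction: float = 0.5,
    max_spine_jump_fraction: float = 0.1,
) -> list[str]:
    """Screen a recording for annotation problems.

    Returns human-readable findings rather than raising; an empty list means
    the recording looks clean.  Flags raised:

    - ``"non-monotone frame indices"`` — frames out of order;
    - ``"untrackable"`` — hyoid missing on more than ``max_missing_fraction``
      of frames (out-of-view or obstructed for most of the swallow);
    - ``"unstable spine annotation"`` — a C2 or C4 marker jumps more than
      ``max_spine_jump_fraction`` of the local C2-C4 length between
      consecutive frames, which usually indicates a mis-click.
    """
    findings: list[str] = []
    indices = [f.frame_index for f in rec.frames]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        findings.append("non-monotone frame indices")
    if rec.n_frames:
        missing_frac = 1.0 - rec.n_hyoid_present / rec.n_frames
        if missing_frac > max_missing_fraction:
            findings.append(
                f"untrackable: hyoid missing on {missing_frac:.0%} of frames"
            )
    for prev, cur in zip(rec.frames, rec.frames[1:]):
        scalar = float(np.linalg.norm(prev.c2 - prev.c4))
        jump = max(
            float(np.linalg.norm(cur.c2 - prev.c2)),
            float(np.linalg.norm(cur.c4 - prev.c4)),
        )
        if jump > max_spine_jump_fraction * scalar:
            findings.append(
                "unstable spine annotation: "
                f"jump of {jump:.1f} px between frames {prev.frame_index} and "
                f"{cur.frame_index} exceeds {max_spine_jump_fraction:.0%} of the "
                f"C2-C4 length ({scalar:.1f} px)"
            )
            break
    return findings
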