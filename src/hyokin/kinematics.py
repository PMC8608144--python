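"""Per-swallow hyoid kinematic outcomes.

Three outcomes are derived from an anatomical track, measured between the
hyoid burst onset (the abrupt start of anterosuperior movement that marks
the pharyngeal swallow phase) and the frame of peak XY position:

- ``peak_xy``        maximal hyoid distance from the C4 origin, %(C2-4);
- ``time_to_peak_ms``  elapsed time burst -> peak, in ms;
- ``xy_speed``       (XY at peak - XY at burst) / elapsed time, %(C2-4)/s.

Burst onset is taken from the rater's annotation when available; the
threshold-based detector here is a reproducible surrogate for recordings
that lack one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .anatomy import AnatomicalTrack, Facing, track_recording
from .landmark_io import SwallowRecording, ValidationError

__all__ = [
    "KinematicSummary",
    "detect_burst_onset",
    "find_peak",
    "time_to_peak_ms",
    "xy_speed",
    "summarize_swallow",
    "summarize_dataset",
]


@dataclass
class KinematicSummary:
    """Outcome bundle for one swallow; ``status`` is ``"ok"`` or a failure
    reason, in which case the numeric fields are ``None`` (never zeros)."""

    recording_id: str
    status: str = "ok"
    burst_frame: Optional[int] = None
    peak_frame: Optional[int] = None
    peak_xy: Optional[float] = None
    burst_xy: Optional[float] = None
    time_to_peak_ms: Optional[float] = None
    xy_speed: Optional[float] = None
    burst_source: Optional[str] = None  # "annotated" | "detected"

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def time_to_peak_ms_tabulated(self) -> Optional[int]:
        """Time-to-peak rounded to integer milliseconds for tables; speed is
        always computed from the unrounded value."""
        if self.time_to_peak_ms is None:
            return None
        return int(round(self.time_to_peak_ms))


def detect_burst_onset(
    track: AnatomicalTrack, *, delta: float = 2.0, run_length: int = 3
) -> int:
    """Detect the hyoid burst onset frame from the XY history.

    Baseline is the median XY of the first five present frames (annotation
    intervals conventionally start five frames before the burst).  Onset is
    the first present frame whose XY exceeds baseline by ``delta`` %(C2-4)
    and is followed by ``run_length`` present frames of sustained rise
    (non-decreasing within a ``delta/4`` tolerance), which rejects isolated
    noise spikes.
    """
    present = np.nonzero(track.present)[0]
    if len(present) < run_length + 5:
        raise ValidationError(
            f"burst detection needs at least {run_length + 5} present frames, "
            f"have {len(present)}"
        )
    baseline = float(np.median(track.XY[present[:5]]))
    xy = track.XY[present]
    for j in range(len(present) - run_length):
        if xy[j] - baseline <= delta:
            continue
        window = xy[j : j + run_length + 1]
        if np.all(np.diff(window) >= -delta / 4.0):
            return int(track.frame_index[present[j]])
    raise ValidationError("no burst detected")


def find_peak(track: AnatomicalTrack, burst_frame: int) -> tuple[int, float]:
    """Frame of greatest XY excursion at or after the burst, with its value.

    Absent frames are skipped; exact ties go to the earliest frame.
    """
    eligible = track.present & (track.frame_index >= burst_frame)
    if not eligible.any():
        raise ValidationError("no present frames at or after the burst")
    pos = np.nonzero(eligible)[0]
    best = pos[int(np.argmax(track.XY[pos]))]  # argmax returns first maximum
    return int(track.frame_index[best]), float(track.XY[best])


def time_to_peak_ms(burst_frame: int, peak_frame: int, frame_rate_hz: float) -> float:
    """Elapsed time from burst to peak in milliseconds (unrounded)."""
    if frame_rate_hz <= 0:
        raise ValidationError("frame_rate_hz must be positive")
    if peak_frame < burst_frame:
        raise ValidationError("peak frame precedes burst frame")
    return (peak_frame - burst_frame) / frame_rate_hz * 1000.0


def xy_speed(
    track: AnatomicalTrack, burst_frame: int, peak_frame: int, frame_rate_hz: float
) -> float:
    """Average XY speed from burst to peak in %(C2-4) per second.

    Uses the unrounded elapsed time.  The displacement may come out
    negative on noisy tracks (peak XY below burst XY after tie-breaking);
    that is reported as-is rather than clamped.
    """
    if peak_frame <= burst_frame:
        raise ValidationError("undefined speed at zero interval")
    displacement = track.xy_at(peak_frame) - track.xy_at(burst_frame)
    elapsed_s = (peak_frame - burst_frame) / frame_rate_hz
    return displacement / elapsed_s


def summarize_swallow(
    rec: SwallowRecording,
    facing: Facing = "right",
    *,
    burst_delta: float = 2.0,
    burst_run_length: int = 3,
) -> KinematicSummary:
    """Run the full track -> burst -> peak -> timing/speed chain for one swallow.

    A rater-annotated burst frame always takes precedence over detection.
    Any stage failure yields a summary flagged with the failure reason
    instead of an exception, mirroring how untrackable swallows are logged
    as missing datapoints rather than dropped silently.
    """
    try:
        track = track_recording(rec, facing)
    except ValidationError as exc:
        return KinematicSummary(rec.recording_id, status=_reason(exc))

    try:
        if rec.annotated_burst_frame is not None:
            burst, source = rec.annotated_burst_frame, "annotated"
            if burst not in track.frame_index:
                raise ValidationError(
                    f"annotated burst frame {burst} outside recording"
                )
            if np.isnan(track.xy_at(burst)):
                raise ValidationError("hyoid absent on the annotated burst frame")
        else:
            burst = detect_burst_onset(
                track, delta=burst_delta, run_length=burst_run_length
            )
            source = "detected"
        peak_frame, peak = find_peak(track, burst)
        ttp = time_to_peak_ms(burst, peak_frame, rec.frame_rate_hz)
        speed = (
            xy_speed(track, burst, peak_frame, rec.frame_rate_hz)
            if peak_frame > burst
            else 0.0
        )
    except ValidationError as exc:
        return KinematicSummary(rec.recording_id, status=_reason(exc))

    return KinematicSummary(
        recording_id=rec.recording_id,
        burst_frame=burst,
        peak_frame=peak_frame,
        peak_xy=peak,
        burst_xy=track.xy_at(burst),
        time_to_peak_ms=ttp,
        xy_speed=speed,
        burst_source=source,
    )


def summarize_dataset(
    recordings,
    facing: Facing = "right",
    *,
    burst_delta: float = 2.0,
    burst_run_length: int = 3,
):
    """Long-format per-swallow outcome table for a list of recordings.

    One row per recording, carrying the protocol metadata alongside the
    kinematic outcomes; failed swallows keep their row with NaN outcomes and
    the failure reason in ``status``, so generated = analyzed + dropped
    always balances.
    """
    import pandas as pd

    rows = []
    for rec in recordings:
        s = summarize_swallow(
            rec, facing, burst_delta=burst_delta, burst_run_length=burst_run_length
        )
        rows.append(
            {
                "recording_id": rec.recording_id,
                "participant_id": rec.participant_id,
                "stimulus": rec.stimulus.label,
                "consistency": rec.stimulus.consistency.name,
                "thickener": rec.stimulus.thickener.value,
                "administration": rec.stimulus.administration.value,
                "repetition": rec.repetition,
                "sip_volume_ml": rec.sip_volume_ml,
                "burst_frame": s.burst_frame,
                "peak_frame": s.peak_frame,
                "peak_xy": s.peak_xy,
                "time_to_peak_ms": s.time_to_peak_ms,
                "time_to_peak_ms_tabulated": s.time_to_peak_ms_tabulated,
                "xy_speed": s.xy_speed,
                "burst_source": s.burst_source,
                "status": s.status,
            }
        )
    return pd.DataFrame(rows)


def _reason(exc: Exception) -> str:
    msg = str(exc)
    # strip the "recording XYZ:" prefix some layers add
    return msg.split(": ", 1)[1] if ": " in msg else msg
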