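"""Synthetic videofluoroscopy cohorts with known ground truth.

The generator emits landmark-level recordings shaped like the reference
study protocol: 39 healthy participants, each swallowing 27 boluses (3 thin
cup sips plus, for each of the four IDDSI thickened levels, 3 starch- and 3
gum-thickened boluses; the two thickest levels are taken by teaspoon), all
recorded at 30 frames/s.  Every recording carries its ground truth (true
burst and peak frames, peak XY, timing, speed, sip volume), so the full
landmark -> kinematics -> statistics pipeline can be exercised and checked
for parameter recovery without any real data.

What is emulated and how:

- Per-swallow outcome distributions (peak XY position, time to peak, XY
  speed) default to published per-stimulus reference means and SDs for
  healthy adults; a participant random intercept on peak XY induces the
  within-participant correlation a mixed model should absorb.
- Time-to-peak is drawn in milliseconds and then discretized to whole
  frames at the recording frame rate, reproducing the granularity that
  makes tabulated timing quartiles multiples of ~33 ms.
- The hyoid trajectory is a rest plateau, a smoothstep rise from burst to
  peak along a fixed anterosuperior ray, and a smoothstep descent; the
  emitted interval runs from 5 frames before the burst to 5 frames into
  the descent, matching rater annotation practice.
- Annotation error is white pixel noise on the hyoid marker and a small
  jitter on the spine markers; whole-recording missingness (hyoid out of
  view / shoulder obstruction) is homogeneous Bernoulli.

The trajectory shape, the anterior/superior split, the noise and sip-volume
distributions are generator design choices, not published quantities; only
the outcome means/SDs and the protocol counts are reference-derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmark_io import (
    STIMULUS_ORDER,
    Administration,
    LandmarkFrame,
    StimulusLevel,
    SwallowRecording,
    write_landmarks,
)

__all__ = [
    "GeneratorConfig",
    "PEAK_XY_BY_STIMULUS",
    "TIME_TO_PEAK_MS_BY_STIMULUS",
    "XY_SPEED_BY_STIMULUS",
    "default_protocol",
    "sample_sip_volume",
    "simulate_trajectory",
    "generate_dataset",
    "write_dataset",
]

# Per-stimulus (mean, SD) of the three outcomes in healthy adults, used as
# generator defaults.  Keys follow the table row order: thin, then starch
# before gum within each thickened level.
PEAK_XY_BY_STIMULUS = {  # %(C2-4)
    "TN0": (169.0, 16.0),
    "ST1-S": (169.0, 16.0),
    "ST1-G": (168.0, 18.0),
    "MT2-S": (168.0, 15.0),
    "MT2-G": (170.0, 16.0),
    "MO3-S": (168.0, 15.0),
    "MO3-G": (168.0, 18.0),
    "EX4-S": (170.0, 14.0),
    "EX4-G": (168.0, 15.0),
}
TIME_TO_PEAK_MS_BY_STIMULUS = {  # ms
    "TN0": (393.0, 123.0),
    "ST1-S": (384.0, 121.0),
    "ST1-G": (376.0, 114.0),
    "MT2-S": (391.0, 137.0),
    "MT2-G": (385.0, 130.0),
    "MO3-S": (403.0, 108.0),
    "MO3-G": (395.0, 111.0),
    "EX4-S": (408.0, 91.0),
    "EX4-G": (410.0, 120.0),
}
XY_SPEED_BY_STIMULUS = {  # %(C2-4)/s
    "TN0": (124.0, 43.0),
    "ST1-S": (123.0, 42.0),
    "ST1-G": (125.0, 45.0),
    "MT2-S": (123.0, 49.0),
    "MT2-G": (128.0, 54.0),
    "MO3-S": (112.0, 37.0),
    "MO3-G": (114.0, 36.0),
    "EX4-S": (116.0, 34.0),
    "EX4-G": (121.0, 46.0),
}


def default_protocol() -> list[tuple[StimulusLevel, int]]:
    """The 27-bolus protocol: (stimulus, repetition) pairs per participant.

    Three thin cup sips plus three repetitions of each of the eight
    consistency-thickener combinations.
    """
    protocol = []
    for stim in STIMULUS_ORDER:
        for rep in range(1, 4):
            protocol.append((stim, rep))
    return protocol


@dataclass
class GeneratorConfig:
    """Population and protocol parameters for one synthetic cohort.

    Outcome means/SDs default to the healthy-adult reference values; the
    remaining knobs (anatomy, noise, volumes, coupling) are generator
    choices documented in the package methods note.
    """

    n_participants: int = 39
    frame_rate_hz: float = 30.0
    seed: int = 0

    # anatomy: participant C2-C4 length in pixels
    scalar_px_mean: float = 60.0
    scalar_px_sd: float = 6.0

    # outcome distributions, keyed by stimulus label
    peak_xy_by_stimulus: dict = field(
        default_factory=lambda: dict(PEAK_XY_BY_STIMULUS)
    )
    time_to_peak_ms_by_stimulus: dict = field(
        default_factory=lambda: dict(TIME_TO_PEAK_MS_BY_STIMULUS)
    )
    xy_speed_by_stimulus: dict = field(
        default_factory=lambda: dict(XY_SPEED_BY_STIMULUS)
    )
    min_time_to_peak_frames: int = 2
    min_xy_speed: float = 5.0  # %(C2-4)/s floor when truncating the draw
    # physical floor on the rest position: the hyoid never sits on the C4
    # origin; jointly extreme draws (high speed x long rise exceeding the
    # peak position) are reconciled by clamping rest here and recording the
    # implied effective speed as ground truth
    min_rest_xy: float = 20.0  # %(C2-4)

    # participant random intercept on peak XY; 11.3 = 16/sqrt(2) makes the
    # within-participant intraclass correlation about 0.5 at the thin-liquid
    # marginal SD of 16 %(C2-4)
    participant_sd: float = 11.3

    # trajectory shape
    anterior_fraction: float = 0.6  # anterior vs superior share of the motion
    pre_burst_frames: int = 5
    post_descent_frames: int = 5

    # sip volumes: cup sips are free, spoon boluses are limited by the spoon
    cup_volume_median_ml: float = 18.0
    cup_volume_sigma_log: float = 0.4
    spoon_volume_mean_ml: float = 5.0
    spoon_volume_sd_ml: float = 1.0
    spoon_volume_max_ml: float = 10.0

    # linear coupling of peak XY to (volume - stimulus mean volume)
    volume_coupling_slope: float = 0.3  # %(C2-4) per ml

    # annotation error and missingness.  Marking error is modeled per
    # landmark as a per-recording systematic offset (a rater's consistent
    # placement choice on that clip) plus independent per-frame scatter.
    # The offset dominates: frame-to-frame scatter must stay small relative
    # to the trajectory's curvature near the peak, otherwise picking the
    # frame of greatest excursion systematically inflates recovered peaks
    # and speeds, and recovered means would no longer be unbiased for the
    # configured ones.  Hyoid defaults combine to ~1 px marginal error.
    annotation_noise_px_sd: float = 0.45  # hyoid per-frame scatter
    annotation_offset_px_sd: float = 0.9  # hyoid per-recording offset
    spine_jitter_px: float = 0.3  # per-frame, uniform half-width
    spine_offset_px: float = 1.0  # per-recording, uniform half-width
    missing_prob: float = 78.0 / 1053.0

    # restrict the protocol to a subset of stimulus labels (None = all nine;
    # e.g. ("TN0",) simulates only the three thin cup sips per participant)
    stimuli: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        for name in (
            "scalar_px_sd",
            "participant_sd",
            "annotation_noise_px_sd",
            "annotation_offset_px_sd",
            "spine_jitter_px",
            "spoon_volume_sd_ml",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def protocol(self) -> list[tuple[StimulusLevel, int]]:
        protocol = default_protocol()
        if self.stimuli is None:
            return protocol
        keep = set(self.stimuli)
        unknown = keep - {s.label for s in STIMULUS_ORDER}
        if unknown:
            raise ValueError(f"unknown stimulus labels: {sorted(unknown)}")
        return [(s, r) for s, r in protocol if s.label in keep]

    def mean_volume(self, stimulus: StimulusLevel) -> float:
        """Expected sip volume under the stimulus's administration route."""
        if stimulus.administration is Administration.CUP:
            return self.cup_volume_median_ml * math.exp(
                self.cup_volume_sigma_log**2 / 2.0
            )
        key = (self.spoon_volume_mean_ml, self.spoon_volume_sd_ml, self.spoon_volume_max_ml)
        cache = self.__dict__.setdefault("_spoon_mean_cache", {})
        if key not in cache:
            a = (0.0 - key[0]) / key[1]
            b = (key[2] - key[0]) / key[1]
            cache[key] = float(sps.truncnorm.mean(a, b, loc=key[0], scale=key[1]))
        return cache[key]


def sample_sip_volume(
    stimulus: StimulusLevel, rng: np.random.Generator, config: GeneratorConfig
) -> float:
    """Draw one sip volume in ml.

    Cup sips are log-normal (uncontrolled comfortable sips are right-skewed
    and never negative); teaspoon boluses are normal truncated to
    (0, spoon_volume_max_ml], stochastically smaller than cup sips because
    the spoon bounds the amount taken.
    """
    if stimulus.administration is Administration.CUP:
        return float(
            rng.lognormal(math.log(config.cup_volume_median_ml), config.cup_volume_sigma_log)
        )
    while True:  # rejection sampling keeps the stream reproducible per-draw
        v = rng.normal(config.spoon_volume_mean_ml, config.spoon_volume_sd_ml)
        if 0.0 < v <= config.spoon_volume_max_ml:
            return float(v)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_trajectory(
    *,
    peak_xy: float,
    rest_xy: float,
    time_to_peak_frames: int,
    scalar_px: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    spine_tilt_rad: float = 0.0,
    missing: bool = False,
) -> tuple[list[LandmarkFrame], int, int]:
    """Render one swallow as pixel landmark frames.

    The hyoid moves along a fixed anterosuperior ray from the C4 origin:
    rest plateau, smoothstep rise from ``rest_xy`` to ``peak_xy`` over
    ``time_to_peak_frames``, then a smoothstep descent at the same pace.
    The emitted window spans ``pre_burst_frames`` before the burst through
    ``post_descent_frames`` after the peak.  Hyoid annotation error is a
    per-recording offset (``annotation_offset_px_sd``) plus per-frame
    scatter (``annotation_noise_px_sd``); spine markers get uniform jitter
    within ``+/- spine_jitter_px``.

    Returns ``(frames, burst_frame, peak_frame)``; with ``missing=True``
    every hyoid cell is blanked (out-of-view swallow) but the spine
    timeline is still emitted.
    """
    tp = int(time_to_peak_frames)
    if tp < 1:
        raise ValueError("time_to_peak_frames must be >= 1")
    if peak_xy < rest_xy:
        raise ValueError("peak_xy must be >= rest_xy")
    pre = config.pre_burst_frames
    post = config.post_descent_frames
    burst = pre
    peak = pre + tp
    n = pre + tp + post + 1

    # XY magnitude profile
    k = np.arange(n)
    xy = np.full(n, rest_xy, dtype=float)
    rise = (k >= burst) & (k <= peak)
    xy[rise] = rest_xy + (peak_xy - rest_xy) * _smoothstep((k[rise] - burst) / tp)
    desc = k > peak
    xy[desc] = peak_xy - (peak_xy - rest_xy) * _smoothstep((k[desc] - peak) / tp)

    # anatomical direction of travel (unit ray, anterior/superior split)
    d = np.array([config.anterior_fraction, 1.0 - config.anterior_fraction])
    d = d / np.linalg.norm(d)

    # pixel geometry: C4 fixed, spine tilted from image-vertical; patient
    # faces right, so anterior is +column and superior is -row
    c4 = np.array([300.0, 400.0])
    y_unit = np.array([math.sin(spine_tilt_rad), -math.cos(spine_tilt_rad)])
    x_unit = np.array([-y_unit[1], y_unit[0]])
    c2 = c4 + scalar_px * y_unit

    spine_offset = rng.uniform(-config.spine_offset_px, config.spine_offset_px, 4)
    spine_noise = rng.uniform(-config.spine_jitter_px, config.spine_jitter_px, (n, 4))
    c2_all = c2 + spine_offset[:2] + spine_noise[:, :2]
    c4_all = c4 + spine_offset[2:] + spine_noise[:, 2:]
    hyoid_all = None
    if not missing:
        anat = xy[:, None] * d  # (n, 2) anatomical X, Y
        hy = c4 + (anat[:, :1] * x_unit + anat[:, 1:] * y_unit) * scalar_px / 100.0
        offset = rng.normal(0.0, config.annotation_offset_px_sd, 2)
        hyoid_all = hy + offset + rng.normal(0.0, config.annotation_noise_px_sd, (n, 2))

    frames = [
        LandmarkFrame(
            frame_index=i,
            c2=c2_all[i],
            c4=c4_all[i],
            hyoid=None if hyoid_all is None else hyoid_all[i],
        )
        for i in range(n)
    ]
    return frames, burst, peak


def generate_dataset(
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
) -> tuple[list[SwallowRecording], pd.DataFrame]:
    """Generate one full cohort: recordings plus a ground-truth table.

    Per swallow, peak XY is drawn from its stimulus distribution plus the
    participant intercept plus the volume coupling; time-to-peak is drawn
    in ms and discretized to frames; the drawn XY speed fixes the
    burst-to-peak displacement (``rest = peak - speed * elapsed``), so all
    three outcomes are mutually consistent by construction.  Whole
    recordings are independently flagged missing with ``missing_prob``;
    ground truth is emitted for every recording, missing ones included.

    Identical config and seed give byte-identical output.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    recordings: list[SwallowRecording] = []
    truth_rows = []
    width = max(2, len(str(config.n_participants)))
    for p in range(config.n_participants):
        pid = f"P{p + 1:0{width}d}"
        scalar_px = max(20.0, rng.normal(config.scalar_px_mean, config.scalar_px_sd))
        intercept = rng.normal(0.0, config.participant_sd)
        for stim, rep in config.protocol:
            rec_id = f"{pid}_{stim.label}_{rep}"
            volume = sample_sip_volume(stim, rng, config)

            mu_xy, sd_xy = config.peak_xy_by_stimulus[stim.label]
            resid_sd = math.sqrt(max(sd_xy**2 - config.participant_sd**2, 1.0))
            peak_xy = (
                mu_xy
                + intercept
                + config.volume_coupling_slope * (volume - config.mean_volume(stim))
                + rng.normal(0.0, resid_sd)
            )

            mu_t, sd_t = config.time_to_peak_ms_by_stimulus[stim.label]
            tp_frames = int(round(rng.normal(mu_t, sd_t) / 1000.0 * config.frame_rate_hz))
            tp_frames = max(tp_frames, config.min_time_to_peak_frames)

            mu_v, sd_v = config.xy_speed_by_stimulus[stim.label]
            speed = max(rng.normal(mu_v, sd_v), config.min_xy_speed)

            elapsed_s = tp_frames / config.frame_rate_hz
            rest_xy = peak_xy - speed * elapsed_s
            if rest_xy < config.min_rest_xy:
                rest_xy = config.min_rest_xy
                speed = (peak_xy - rest_xy) / elapsed_s
            tilt = rng.normal(0.0, math.radians(5.0))
            missing = bool(rng.random() < config.missing_prob)

            frames, burst, peak = simulate_trajectory(
                peak_xy=peak_xy,
                rest_xy=rest_xy,
                time_to_peak_frames=tp_frames,
                scalar_px=scalar_px,
                config=config,
                rng=rng,
                spine_tilt_rad=tilt,
                missing=missing,
            )
            recordings.append(
                SwallowRecording(
                    recording_id=rec_id,
                    participant_id=pid,
                    stimulus=stim,
                    repetition=rep,
                    sip_volume_ml=volume,
                    frames=frames,
                    frame_rate_hz=config.frame_rate_hz,
                    annotated_burst_frame=burst,
                )
            )
            truth_rows.append(
                {
                    "recording_id": rec_id,
                    "participant_id": pid,
                    "stimulus": stim.label,
                    "repetition": rep,
                    "sip_volume_ml": volume,
                    "participant_intercept": intercept,
                    "burst_frame": burst,
                    "peak_frame": peak,
                    "peak_xy": peak_xy,
                    "rest_xy": rest_xy,
                    "time_to_peak_ms": tp_frames / config.frame_rate_hz * 1000.0,
                    "xy_speed": speed,
                    "missing": missing,
                }
            )
    return recordings, pd.DataFrame(truth_rows)


def write_dataset(
    recordings: list[SwallowRecording],
    truth: pd.DataFrame,
    out_dir,
) -> dict[str, Path]:
    """Write a generated cohort as the standard CSV trio."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "landmarks": out / "landmarks.csv",
        "metadata": out / "metadata.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_landmarks(recordings, paths["landmarks"], paths["metadata"])
    truth.to_csv(paths["ground_truth"], index=False)
    return paths
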