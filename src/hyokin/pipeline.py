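"""End-to-end analysis runs: landmarks -> summaries -> tables and models.

The run mirrors the two-step statistical logic of the study design:
Spearman screening of sip volume against each outcome decides (at p < .05)
whether volume enters that outcome's mixed model as a covariate, and the
timing and speed outcomes are Blom rank-normalized before modeling because
their residuals are skewed.  All outputs are plain CSV/text files in the
output directory; every generated swallow is accounted for either in the
analysis or in the dropped-swallow log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as hstats
from .kinematics import summarize_dataset
from .landmark_io import read_landmarks, validate_recording

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("hyokin")

OUTCOMES = ("peak_xy", "time_to_peak_ms", "xy_speed")
#: Outcomes that are Blom rank-normalized before mixed modeling.
RANK_NORMALIZED = ("time_to_peak_ms", "xy_speed")


@dataclass
class RunConfig:
    landmarks_path: Path
    metadata_path: Path
    out_dir: Path
    facing: str = "right"
    burst_delta: float = 2.0
    burst_run_length: int = 3
    confidence: float = 0.95
    screening_alpha: float = 0.05
    rank_normalize: bool = True
    force_volume: bool = False
    covariance: str = "compound_symmetry"

    def __post_init__(self) -> None:
        self.landmarks_path = Path(self.landmarks_path)
        self.metadata_path = Path(self.metadata_path)
        self.out_dir = Path(self.out_dir)
        for p in (self.landmarks_path, self.metadata_path):
            if not p.exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    tables: dict
    correlations: pd.DataFrame
    models: dict
    carried_covariates: dict
    n_generated: int = 0
    n_analyzed: int = 0
    n_dropped: int = 0
    outputs: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the result bundle to ``out_dir``.

    Outputs: ``summary.csv`` (per-swallow outcomes with status),
    ``validation_log.txt``, ``correlations.csv`` (volume screening),
    ``table_<outcome>.csv`` (nine-row descriptive tables),
    ``model_report.txt`` and ``pairwise_<outcome>.csv`` where applicable.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    recordings = read_landmarks(config.landmarks_path, config.metadata_path)
    log_lines = []
    for rec in recordings:
        for finding in validate_recording(rec):
            log_lines.append(f"{rec.recording_id}: {finding}")

    summary = summarize_dataset(
        recordings,
        config.facing,
        burst_delta=config.burst_delta,
        burst_run_length=config.burst_run_length,
    )
    usable = summary[summary["status"] == "ok"]
    dropped = summary[summary["status"] != "ok"]
    for row in dropped.itertuples(index=False):
        log_lines.append(f"{row.recording_id}: dropped ({row.status})")
    logger.info(
        "generated=%d analyzed=%d dropped=%d",
        len(summary),
        len(usable),
        len(dropped),
    )
    if usable.empty:
        raise ValueError("no usable swallows after validation")

    # step 1: Spearman screening of sip volume against each outcome
    corr_rows = []
    carried = {}
    for outcome in OUTCOMES:
        res = hstats.spearman_rs(
            usable["sip_volume_ml"].to_numpy(), usable[outcome].to_numpy()
        )
        carry = config.force_volume or res.p_value < config.screening_alpha
        carried[outcome] = carry
        corr_rows.append(
            {
                "outcome": outcome,
                "r_s": res.r_s,
                "p_value": res.p_value,
                "n": res.n,
                "carried_forward": carry,
            }
        )
    correlations = pd.DataFrame(corr_rows)

    # step 2: descriptive tables and mixed models
    tables = {}
    models = {}
    for outcome in OUTCOMES:
        tables[outcome] = hstats.descriptive_table(
            usable, outcome, config.confidence
        )
        models[outcome] = hstats.fit_mixed_model(
            usable,
            outcome,
            rank_normalize=config.rank_normalize and outcome in RANK_NORMALIZED,
            include_volume=carried[outcome],
            covariance=config.covariance,
        )

    outputs = _write_bundle(
        out, summary, log_lines, correlations, tables, models, config
    )
    return PipelineResult(
        summary=summary,
        tables=tables,
        correlations=correlations,
        models=models,
        carried_covariates=carried,
        n_generated=len(summary),
        n_analyzed=len(usable),
        n_dropped=len(dropped),
        outputs=outputs,
    )


def _write_bundle(out, summary, log_lines, correlations, tables, models, config):
    outputs = {}

    outputs["summary"] = out / "summary.csv"
    summary.to_csv(outputs["summary"], index=False)

    outputs["validation_log"] = out / "validation_log.txt"
    outputs["validation_log"].write_text(
        "\n".join(log_lines) + ("\n" if log_lines else ""), encoding="utf-8"
    )

    outputs["correlations"] = out / "correlations.csv"
    correlations.to_csv(outputs["correlations"], index=False)

    for outcome, table in tables.items():
        key = f"table_{outcome}"
        outputs[key] = out / f"{key}.csv"
        table.to_csv(outputs[key], index=False)

    lines = []
    for outcome, fit in models.items():
        lines.append(f"=== {outcome} ===")
        lines.append(
            f"n_obs={fit.n_obs} participants={fit.n_participants} "
            f"covariance={fit.covariance_structure} "
            f"rank_normalized={fit.rank_normalized} converged={fit.converged}"
        )
        for d in fit.diagnostics:
            lines.append(f"  ! {d}")
        for t in fit.terms:
            lines.append(
                f"  {t.name}: F({t.df_num:g}, {t.df_den:g}) = {t.F:.2f}, "
                f"p = {t.p:.4f}"
            )
        stim = next((t for t in fit.terms if t.name == "stimulus"), None)
        if stim is not None and np.isfinite(stim.p) and stim.p < 0.05:
            pw = hstats.pairwise_comparisons(fit)
            key = f"pairwise_{outcome}"
            outputs[key] = out / f"{key}.csv"
            pd.DataFrame(
                [
                    (c.stimulus_a, c.stimulus_b, c.estimate, c.p_raw, c.p_sidak)
                    for c in pw
                ],
                columns=["stimulus_a", "stimulus_b", "estimate", "p_raw", "p_sidak"],
            ).to_csv(outputs[key], index=False)
            n_sig = sum(1 for c in pw if c.p_sidak < 0.05)
            lines.append(
                f"  post hoc Sidak: {n_sig} of {len(pw)} pairwise contrasts "
                f"significant at .05 -> {outputs[key].name}"
            )
        lines.append("")
    outputs["model_report"] = out / "model_report.txt"
    outputs["model_report"].write_text("\n".join(lines), encoding="utf-8")
    return outputs
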