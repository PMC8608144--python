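"""Statistical workflow for per-swallow kinematic outcomes.

The analysis chain mirrors standard practice for repeated-measures
videofluoroscopy protocols:

1. descriptive tables per stimulus (mean, SD, 95% CI, quartiles);
2. rank-based inverse-normal (Blom) transformation for outcomes with
   asymmetric residuals;
3. Spearman screening of sip volume against each outcome to decide whether
   volume enters the models as a covariate;
4. linear mixed models with a stimulus factor, a sip-volume covariate and
   their interaction, a participant random intercept, and a
   compound-symmetry structure across repetitions of the same stimulus;
5. Sidak-adjusted pairwise stimulus contrasts when the stimulus factor is
   significant.

Model fitting is delegated to :mod:`statsmodels` (``MixedLM``); the
compound-symmetry repeated structure is expressed as a participant-by-
stimulus variance component, which induces equal correlation among the
repetitions of one stimulus within a participant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri

from .landmark_io import STIMULUS_ORDER

__all__ = [
    "DescriptiveRow",
    "CorrelationResult",
    "TermTest",
    "MixedModelResult",
    "PairwiseComparison",
    "blom_transform",
    "spearman_rs",
    "descriptive_row",
    "descriptive_table",
    "fit_mixed_model",
    "sidak_adjust",
    "pairwise_comparisons",
]

#: Number of unordered stimulus pairs among the nine stimuli; the default
#: family size for Sidak adjustment.
N_STIMULUS_PAIRS = 36


@dataclass
class DescriptiveRow:
    label: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    q25: float
    q75: float


@dataclass
class CorrelationResult:
    r_s: float
    p_value: float
    n: int


@dataclass
class TermTest:
    """Wald F test for one fixed-effect term."""

    name: str
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class MixedModelResult:
    outcome: str
    terms: list[TermTest]
    covariance_structure: str
    converged: bool
    n_obs: int
    n_participants: int
    rank_normalized: bool
    diagnostics: list[str] = field(default_factory=list)
    result: object = None  # underlying statsmodels MixedLMResults

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class PairwiseComparison:
    stimulus_a: str
    stimulus_b: str
    estimate: float
    p_raw: float
    p_sidak: float


def blom_transform(values) -> np.ndarray:
    """Rank-based inverse-normal scores using Blom's proportion estimate.

    Each value is replaced by ``Phi^-1((r - 3/8) / (n + 1/4))`` where ``r``
    is its rank (average rank for ties).  The output is in input order and
    is invariant under any strictly monotone transform of the inputs, which
    is what makes it a robust normalizer for skewed outcomes.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("blom_transform needs a 1-D array of length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("blom_transform requires finite inputs")
    ranks = sps.rankdata(values, method="average")
    return ndtri((ranks - 0.375) / (len(values) + 0.25))


def spearman_rs(x, y) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete deletion.

    Ties receive average ranks; the two-sided p-value uses the
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(r_s=float(rho), p_value=float(p), n=len(x))


def descriptive_row(values, confidence: float = 0.95, label: str = "") -> DescriptiveRow:
    """Mean, sample SD, t-based CI and interpolated quartiles for one cell.

    The CI treats swallows as independent observations, matching how such
    reference tables are conventionally reported; see
    :func:`descriptive_table` for a cluster-bootstrap alternative that
    respects the repeated measures per participant.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        raise ValueError("descriptive_row needs at least 2 finite values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n)
    q25, q75 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    return DescriptiveRow(
        label=label,
        n=n,
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        q25=float(q25),
        q75=float(q75),
    )


def descriptive_table(
    data: pd.DataFrame,
    outcome: str,
    confidence: float = 0.95,
    *,
    ci_method: str = "t",
    cluster_col: str = "participant_id",
    n_boot: int = 2000,
    rng=None,
) -> pd.DataFrame:
    """Nine-row descriptive table (one row per stimulus, thin -> extremely
    thick, starch before gum within level).

    ``ci_method="cluster-bootstrap"`` resamples participants with
    replacement instead of assuming independent swallows.
    """
    rows = []
    for stim in STIMULUS_ORDER:
        sub = data[data["stimulus"] == stim.label]
        vals = sub[outcome].to_numpy(dtype=float)
        row = descriptive_row(vals, confidence, label=stim.label)
        if ci_method == "cluster-bootstrap":
            row.ci_low, row.ci_high = _cluster_bootstrap_ci(
                sub, outcome, cluster_col, confidence, n_boot, rng
            )
        elif ci_method != "t":
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows.append(row)
    return pd.DataFrame(
        [
            (r.label, r.n, r.mean, r.sd, r.ci_low, r.ci_high, r.q25, r.q75)
            for r in rows
        ],
        columns=["stimulus", "n", "mean", "sd", "ci_low", "ci_high", "q25", "q75"],
    )


def _cluster_bootstrap_ci(sub, outcome, cluster_col, confidence, n_boot, rng):
    rng = np.random.default_rng(rng)
    groups = [
        g[outcome].to_numpy(dtype=float) for _, g in sub.groupby(cluster_col)
    ]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g)]
    means = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(groups), len(groups))
        means[b] = np.concatenate([groups[i] for i in pick]).mean()
    alpha = 1.0 - confidence
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def sidak_adjust(p_raw: float, m: int = N_STIMULUS_PAIRS) -> float:
    """Sidak familywise adjustment ``1 - (1 - p)^m`` for ``m`` comparisons."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw must be in [0, 1], got {p_raw}")
    if m < 1:
        raise ValueError("m must be >= 1")
    # -expm1(m * log1p(-p)) is the numerically stable form of 1 - (1-p)^m
    if p_raw == 1.0:
        return 1.0
    return float(min(1.0, -np.expm1(m * np.log1p(-p_raw))))


def fit_mixed_model(
    data: pd.DataFrame,
    outcome: str,
    *,
    rank_normalize: bool = False,
    include_volume: bool = True,
    include_administration: bool = False,
    covariance: str = "compound_symmetry",
    stimulus_col: str = "stimulus",
    participant_col: str = "participant_id",
    volume_col: str = "sip_volume_ml",
) -> MixedModelResult:
    """Repeated-measures linear mixed model for one kinematic outcome.

    Fixed effects: the nine-level stimulus factor, sip volume, and their
    interaction (plus optionally administration method, though it is
    confounded with consistency).  Random structure: a participant
    intercept and, under ``covariance="compound_symmetry"``, a
    participant-by-stimulus variance component so the repetitions of one
    stimulus within a participant are equicorrelated.  Estimation is REML.

    ``rank_normalize`` applies :func:`blom_transform` to the outcome first,
    the usual remedy when residuals are visibly skewed (timing and speed
    outcomes typically are).

    F statistics are Type-III style Wald tests on the REML fit: the
    covariate is centered at its sample mean, so the stimulus test compares
    stimuli at the mean sip volume, the volume test is the unweighted
    average of the nine within-stimulus slopes, and the interaction test is
    the 8-df test of slope heterogeneity.  Denominator degrees of freedom
    are ``n_obs - rank(X)``, a large-sample approximation rather than a
    Satterthwaite or Kenward-Roger correction.
    Rows with a missing outcome are dropped.  Non-convergence and
    degenerate designs are reported through ``converged`` /
    ``diagnostics``, never silently.
    """
    import statsmodels.formula.api as smf

    df = data.loc[np.isfinite(data[outcome].astype(float))].copy()
    if df.empty:
        raise ValueError("no usable observations")
    if include_volume:
        df[volume_col] = df[volume_col] - df[volume_col].mean()
    ycol = outcome
    if rank_normalize:
        ycol = f"_blom_{outcome}"
        df[ycol] = blom_transform(df[outcome].to_numpy(dtype=float))

    order = [s.label for s in STIMULUS_ORDER if s.label in set(df[stimulus_col])]
    stim_term = f"C({stimulus_col}, levels={order!r})"
    parts = [stim_term]
    if include_volume:
        parts += [volume_col, f"{stim_term}:{volume_col}"]
    if include_administration:
        parts.append("administration")
    formula = f"{ycol} ~ " + " + ".join(parts)

    diagnostics: list[str] = []
    n_participants = df[participant_col].nunique()
    if n_participants < 2:
        diagnostics.append(
            "random effect degenerate: fewer than 2 participants; "
            "participant variance is not identifiable"
        )

    vc = None
    if covariance == "compound_symmetry":
        vc = {"participant_x_stimulus": f"0 + C({stimulus_col})"}
    elif covariance != "random_intercept":
        raise ValueError(f"unknown covariance structure {covariance!r}")

    model = smf.mixedlm(
        formula,
        df,
        groups=df[participant_col],
        re_formula="1",
        vc_formula=vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["powell", "lbfgs"], maxiter=2000)
    converged = bool(res.converged)
    if not converged:
        diagnostics.append("REML optimization did not converge")

    terms = _term_f_tests(model, res)
    return MixedModelResult(
        outcome=outcome,
        terms=terms,
        covariance_structure=covariance,
        converged=converged,
        n_obs=len(df),
        n_participants=n_participants,
        rank_normalized=rank_normalize,
        diagnostics=diagnostics,
        result=res,
    )


def _term_f_tests(model, res) -> list[TermTest]:
    """Type-III style Wald F test per fixed-effect term.

    A plain covariate that also appears in an interaction with a factor is
    tested as the unweighted average of its per-level slopes (the Type-III
    main effect under effect coding); every other term is the joint test of
    its own design columns.
    """
    design_info = model.data.design_info
    slices = design_info.term_name_slices
    k_fe = model.k_fe
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    df_den = float(model.nobs - k_fe)
    tests = []
    for name, sl in slices.items():
        if name == "Intercept":
            continue
        cols = np.arange(k_fe)[sl]
        interaction = next(
            (
                s
                for n2, s in slices.items()
                if ":" in n2 and name in n2.split(":")
            ),
            None,
        )
        if ":" not in name and not name.startswith("C(") and interaction is not None:
            # average slope across the factor's levels: the reference level
            # carries the plain coefficient, the others add their
            # interaction contrasts
            inter_cols = np.arange(k_fe)[interaction]
            n_levels = len(inter_cols) + 1
            L = np.zeros((1, k_fe))
            L[0, cols] = 1.0
            L[0, inter_cols] = 1.0 / n_levels
        else:
            L = np.zeros((len(cols), k_fe))
            L[np.arange(len(cols)), cols] = 1.0
        q = L.shape[0]
        Lb = L @ beta
        middle = L @ cov @ L.T
        try:
            F = float(Lb @ np.linalg.solve(middle, Lb)) / q
        except np.linalg.LinAlgError:
            F = float("nan")
        p = float(sps.f.sf(F, q, df_den)) if np.isfinite(F) else float("nan")
        tests.append(TermTest(_clean_term_name(name), F, float(q), df_den, p))
    return tests


def _clean_term_name(name: str) -> str:
    """Collapse patsy's ``C(stimulus, levels=[...])`` spelling back to the
    plain column name, e.g. ``stimulus:sip_volume_ml`` for the interaction."""
    parts = name.split(":")
    cleaned = []
    for part in parts:
        if part.startswith("C(") and "," in part:
            cleaned.append(part[2:].split(",", 1)[0].strip())
        elif part.startswith("C(") and part.endswith(")"):
            cleaned.append(part[2:-1].strip())
        else:
            cleaned.append(part)
    return ":".join(cleaned)


def pairwise_comparisons(
    fit: MixedModelResult,
    *,
    stimulus_col: str = "stimulus",
) -> list[PairwiseComparison]:
    """Sidak-adjusted pairwise stimulus contrasts from a fitted model.

    Contrasts are differences of adjusted stimulus means, evaluated at the
    sample mean sip volume when the model includes the covariate; raw
    p-values come from large-sample Wald z tests and the Sidak family is
    all 36 unordered pairs.
    """
    res = fit.result
    model = res.model
    design_info = model.data.design_info
    k_fe = model.k_fe
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    exog = model.exog
    frame = pd.DataFrame(exog, columns=design_info.column_names)
    stim_labels = [s.label for s in STIMULUS_ORDER]
    # mean design row per stimulus = adjusted mean at observed covariate mix
    stim_of_row = model.data.frame[stimulus_col].to_numpy()
    rows = {}
    for label in stim_labels:
        mask = stim_of_row == label
        if mask.any():
            rows[label] = frame[mask].mean(axis=0).to_numpy()
    comparisons = []
    pairs = list(itertools.combinations([l for l in stim_labels if l in rows], 2))
    m = len(pairs)
    for a, b in pairs:
        L = rows[a] - rows[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else float("inf")
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        comparisons.append(
            PairwiseComparison(a, b, est, p_raw, sidak_adjust(p_raw, m))
        )
    return comparisons
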