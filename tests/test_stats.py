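import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hyokin.landmark_io import STIMULUS_ORDER
from hyokin.stats import (
    blom_transform,
    descriptive_row,
    descriptive_table,
    fit_mixed_model,
    pairwise_comparisons,
    sidak_adjust,
    spearman_rs,
)


class TestBlomTransform:
    def test_three_point_normal_scores(self):
        # Phi^-1((r - 3/8)/3.25) for r = 1, 2, 3; outer values frozen from a
        # high-precision erfinv evaluation
        scores = blom_transform([10, 20, 30])
        np.testing.assert_allclose(
            scores, [-0.869423773289, 0.0, 0.869423773289], atol=1e-6
        )

    def test_output_in_input_order(self):
        scores = blom_transform([30, 10, 20])
        assert scores[1] < scores[2] < scores[0]

    def test_ties_share_average_rank_score(self):
        scores = blom_transform([5, 5, 9])
        assert scores[0] == scores[1] < scores[2]

    def test_antisymmetric_under_negation_and_centered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=51)
        s = blom_transform(x)
        np.testing.assert_allclose(s + blom_transform(-x), 0.0, atol=1e-12)
        assert abs(s.sum()) < 1e-10

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2,
                    max_size=40, unique=True))
    def test_invariant_to_monotone_transforms(self, xs):
        """Rank-based scores depend only on the ordering of the inputs."""
        x = np.array(xs)
        np.testing.assert_allclose(
            blom_transform(x), blom_transform(np.argsort(np.argsort(x)) + 1.0),
            atol=1e-12,
        )

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            blom_transform([1.0])
        with pytest.raises(ValueError):
            blom_transform([1.0, np.nan, 2.0])


class TestSpearman:
    def test_perfect_inverse_monotone(self):
        assert spearman_rs([1, 2, 3], [3, 2, 1]).r_s == pytest.approx(-1.0)

    def test_single_swap(self):
        # sum d^2 = 2 -> 1 - 6*2/(4*15) = 0.8
        assert spearman_rs([1, 2, 3, 4], [1, 3, 2, 4]).r_s == pytest.approx(0.8)

    def test_pairwise_deletion_reduces_n(self):
        res = spearman_rs([1, 2, np.nan, 4], [1, 3, 2, 4])
        assert res.n == 3

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rs([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_pearson_on_average_ranks(self):
        """Oracle identity: Spearman's r_s is Pearson's r computed on
        (average) ranks, including under ties."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = rng.integers(5, 40)
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = x * rng.normal(1, 1) + rng.integers(0, 4, n)
            got = spearman_rs(x, y).r_s
            want = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
            assert got == pytest.approx(want, abs=1e-12)


class TestDescriptiveRow:
    def test_frozen_five_point_example(self):
        row = descriptive_row([1, 2, 3, 4, 5])
        assert row.mean == pytest.approx(3.0)
        assert row.sd == pytest.approx(1.5811, abs=1e-4)
        assert row.ci_low == pytest.approx(1.0368, abs=1e-4)
        assert row.ci_high == pytest.approx(4.9632, abs=1e-4)
        assert (row.q25, row.q75) == (2.0, 4.0)

    def test_constant_vector(self):
        row = descriptive_row([7, 7, 7])
        assert (row.sd, row.ci_low, row.ci_high) == (0.0, 7.0, 7.0)

    def test_linear_in_scale(self):
        a = descriptive_row([1.0, 2.5, 3.5, 8.0])
        b = descriptive_row([10.0, 25.0, 35.0, 80.0])
        for f in ("mean", "sd", "ci_low", "ci_high", "q25", "q75"):
            assert getattr(b, f) == pytest.approx(10 * getattr(a, f))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            descriptive_row([3.0])


class TestSidak:
    def test_closed_form_for_36_pairs(self):
        assert sidak_adjust(0.01, 36) == pytest.approx(0.303587, abs=1e-6)

    def test_identity_for_single_comparison(self):
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)

    def test_boundaries(self):
        assert sidak_adjust(0.0, 36) == 0.0
        assert sidak_adjust(1.0, 36) == 1.0

    def test_monotone_in_p_and_m(self):
        ps = np.linspace(0, 1, 25)
        adj = [sidak_adjust(p, 36) for p in ps]
        assert all(b >= a for a, b in zip(adj, adj[1:]))
        for p in (0.001, 0.05, 0.4):
            by_m = [sidak_adjust(p, m) for m in (1, 2, 8, 36, 100)]
            assert all(b >= a for a, b in zip(by_m, by_m[1:]))
            assert all(v >= p for v in by_m)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.2, 36)


def _simulate_cohort(rng, n_part=15, slope=0.0, stim_effects=None):
    rows = []
    for p in range(n_part):
        b = rng.normal(0, 11.3)
        for s in STIMULUS_ORDER:
            cell = rng.normal(0, 6.0)
            eff = 0.0 if stim_effects is None else stim_effects[s.label]
            for rep in range(1, 4):
                vol = (
                    rng.lognormal(np.log(18), 0.4)
                    if s.administration.value == "cup"
                    else rng.normal(5, 1)
                )
                y = 169 + eff + b + cell + slope * vol + rng.normal(0, 10.0)
                rows.append((f"P{p:02d}", s.label, rep, vol, y))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "stimulus", "repetition", "sip_volume_ml",
                 "peak_xy"],
    )


class TestMixedModel:
    def test_term_structure_and_convergence(self):
        df = _simulate_cohort(np.random.default_rng(1))
        fit = fit_mixed_model(df, "peak_xy")
        names = [t.name for t in fit.terms]
        assert names == ["stimulus", "sip_volume_ml", "stimulus:sip_volume_ml"]
        assert fit.converged
        assert fit.term("stimulus").df_num == 8
        assert fit.term("sip_volume_ml").df_num == 1
        for t in fit.terms:
            assert t.F >= 0 and 0 <= t.p <= 1

    def test_volume_slope_sign_recovered(self):
        df = _simulate_cohort(np.random.default_rng(2), slope=1.0)
        fit = fit_mixed_model(df, "peak_xy")
        assert fit.term("sip_volume_ml").p < 0.05
        # fitted slope carries the simulated sign
        assert fit.result.fe_params["sip_volume_ml"] > 0

    def test_single_participant_flagged_degenerate(self):
        df = _simulate_cohort(np.random.default_rng(3), n_part=1)
        fit = fit_mixed_model(df, "peak_xy")
        assert any("degenerate" in d for d in fit.diagnostics)

    def test_rank_normalized_outcome(self):
        df = _simulate_cohort(np.random.default_rng(4))
        fit = fit_mixed_model(df, "peak_xy", rank_normalize=True)
        assert fit.rank_normalized
        assert fit.converged

    def test_volume_can_be_excluded(self):
        df = _simulate_cohort(np.random.default_rng(5))
        fit = fit_mixed_model(df, "peak_xy", include_volume=False)
        assert [t.name for t in fit.terms] == ["stimulus"]


class TestPairwise:
    def test_full_family_with_sidak_ordering(self):
        df = _simulate_cohort(np.random.default_rng(6))
        fit = fit_mixed_model(df, "peak_xy")
        pw = pairwise_comparisons(fit)
        assert len(pw) == 36
        for c in pw:
            assert c.p_sidak >= c.p_raw
            assert 0 <= c.p_sidak <= 1

    def test_large_injected_contrast_detected(self):
        effects = {s.label: 0.0 for s in STIMULUS_ORDER}
        effects["EX4-G"] = 25.0
        df = _simulate_cohort(np.random.default_rng(7), stim_effects=effects)
        fit = fit_mixed_model(df, "peak_xy")
        pw = pairwise_comparisons(fit)
        hits = [c for c in pw if "EX4-G" in (c.stimulus_a, c.stimulus_b)]
        assert any(c.p_sidak < 0.05 for c in hits)


class TestDescriptiveTable:
    def test_nine_rows_in_table_order(self):
        df = _simulate_cohort(np.random.default_rng(8))
        table = descriptive_table(df, "peak_xy")
        assert list(table["stimulus"]) == [s.label for s in STIMULUS_ORDER]
        assert (table["ci_low"] <= table["mean"]).all()
        assert (table["mean"] <= table["ci_high"]).all()
        assert (table["q25"] <= table["q75"]).all()

    def test_cluster_bootstrap_ci_available(self):
        df = _simulate_cohort(np.random.default_rng(9))
        t1 = descriptive_table(df, "peak_xy", ci_method="cluster-bootstrap",
                               n_boot=200, rng=0)
        assert (t1["ci_low"] < t1["mean"]).all()
        assert (t1["mean"] < t1["ci_high"]).all()
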