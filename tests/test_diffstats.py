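import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from kinoproteo.diffstats import (
    bh_fdr,
    call_significance,
    classify_magnitude,
    dose_fate,
    effect_size_from_groups,
    effect_sizes,
    fit_moderated_de,
    hedges_j,
    intersection_summary,
)
from kinoproteo.errors import ValidationError
from kinoproteo.io_formats import SampleDesign
from kinoproteo.preprocess import QuantMatrix


def make_matrix(values, design, counts=None):
    vals = pd.DataFrame(values, columns=list(design.channels))
    vals.index = [f"P{i}" for i in range(len(vals))]
    counts = pd.Series(counts if counts is not None else 1, index=vals.index,
                       name="psm_count")
    return QuantMatrix(values=vals, psm_counts=counts, design=design,
                       is_log2=True)


class TestBhFdr:
    def test_matches_brute_force_step_up(self):
        p = [0.01, 0.02, 0.03]
        np.testing.assert_allclose(bh_fdr(p), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr(p), oracles.bh_stepup(p))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_equals_oracle_and_is_monotone_in_ranks(self, p):
        adj = bh_fdr(p)
        np.testing.assert_allclose(adj, oracles.bh_stepup(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert (np.asarray(adj) <= 1).all()

    def test_degenerate_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)


class TestModeratedDe:
    def test_d0_zero_limit_equals_classical_t(self, two_group_design):
        rng = np.random.default_rng(42)
        vals = rng.normal(20, 0.5, size=(120, 6))
        counts = rng.integers(1, 40, size=120)
        m = make_matrix(vals, two_group_design, counts)
        res = fit_moderated_de(m, two_group_design, prior_df=0.0)
        table = res["10uM_vs_vehicle"]
        t_classic, _ = stats.ttest_ind(vals[:, 3:], vals[:, :3], axis=1,
                                       equal_var=True)
        np.testing.assert_allclose(table["t"], t_classic, rtol=1e-10)

    def test_flat_psm_counts_equal_flat_prior_moderation(self, two_group_design):
        """All proteins at one PSM count: the trend collapses to a constant
        and results match a directly-coded count-free moderation."""
        rng = np.random.default_rng(7)
        vals = rng.normal(20, 0.5, size=(200, 6))
        m = make_matrix(vals, two_group_design, counts=10)
        res = fit_moderated_de(m, two_group_design)["10uM_vs_vehicle"]
        t_oracle, d0_oracle = oracles.flat_prior_moderation(
            vals, [[0, 1, 2], [3, 4, 5]], contrast=(1, 0))
        np.testing.assert_allclose(res["t"], t_oracle, rtol=1e-6)
        assert res.attrs["prior_df"] == pytest.approx(d0_oracle, rel=1e-4)

    def test_zero_variance_protein_gets_finite_t(self, two_group_design):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 0.5, size=(80, 6))
        vals[0] = [20, 20, 20, 22, 22, 22]  # no within-group variance
        m = make_matrix(vals, two_group_design)
        res = fit_moderated_de(m, two_group_design)["10uM_vs_vehicle"]
        assert np.isfinite(res["t"].iloc[0])
        assert res.attrs["prior_df"] > 0

    def test_large_prior_df_shrinks_to_trend(self, two_group_design):
        rng = np.random.default_rng(11)
        vals = rng.normal(20, 0.5, size=(100, 6))
        m = make_matrix(vals, two_group_design, counts=5)
        res_inf = fit_moderated_de(m, two_group_design,
                                   prior_df=np.inf)["10uM_vs_vehicle"]
        # with d0 = inf all proteins share the trend variance: t is
        # proportional to log2fc
        ratio = res_inf["t"] / res_inf["log2fc"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_unknown_contrast_group_rejected(self, design11):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(20, 0.5, size=(30, 11)), design11)
        with pytest.raises(ValidationError, match="50uM"):
            fit_moderated_de(m, design11, contrasts=[("50uM", "vehicle")])

    def test_singleton_group_rejected_at_design_level(self, design11):
        """The design itself refuses groups with fewer than 2 samples, so a
        <2-sample contrast can never reach the fit."""
        with pytest.raises(ValidationError, match="fewer than 2"):
            SampleDesign(
                channels=design11.channels,
                groups=("vehicle",) * 3 + ("1uM",) * 3 + ("2.5uM",) * 4
                + ("10uM",),
                doses=(0.0,) * 3 + (1.0,) * 3 + (2.5,) * 4 + (10.0,))


class TestCallSignificance:
    @pytest.mark.parametrize("fdr,lfc,expected", [
        (0.04, 0.6, True),    # passes both arms
        (0.01, 0.5, False),   # fails the fold-change arm
        (0.06, 3.0, False),   # fails the FDR arm
    ])
    def test_conjunction_rule(self, fdr, lfc, expected):
        res = pd.DataFrame({"fdr": [fdr], "log2fc": [lfc]})
        calls = call_significance(res)
        assert bool(calls["result"]["significant"].iloc[0]) is expected

    def test_reports_both_counting_rules(self):
        res = pd.DataFrame({"fdr": [0.01, 0.01, 0.2],
                            "log2fc": [2.0, 0.1, 2.0]})
        calls = call_significance(res)
        assert calls["n_significant"] == 1
        assert calls["n_fdr_only"] == 2


class TestEffectSizes:
    def test_worked_example(self):
        out = effect_size_from_groups([1, 2, 3], [4, 5, 6])
        assert out["d"] == pytest.approx(-3.0)
        assert out["J"] == pytest.approx(0.8)
        assert out["g"] == pytest.approx(-2.4)
        assert out["magnitude_class"] == "strong"

    def test_identical_groups_are_small(self):
        out = effect_size_from_groups([5, 6, 7], [5, 6, 7])
        assert out["d"] == 0.0 and out["g"] == 0.0
        assert out["magnitude_class"] == "small"

    @pytest.mark.parametrize("n1,n2,expected", [
        (3, 2, 1 - 3 / 11),  # the 10 uM design
        (3, 3, 1 - 3 / 15),
        (2, 2, 1 - 3 / 7),
    ])
    def test_hedges_correction_factor(self, n1, n2, expected):
        assert hedges_j(n1, n2) == pytest.approx(expected)

    @pytest.mark.parametrize("g,label", [
        (0.79, "small"), (0.8, "notable"), (1.49, "notable"),
        (1.5, "strong"), (2.99, "strong"), (3.0, "definitive"),
        (4.49, "definitive"), (-4.49, "definitive"),
    ])
    def test_magnitude_classes(self, g, label):
        assert classify_magnitude(g) == label

    def test_zero_pooled_sd_is_undefined_not_infinite(self):
        out = effect_size_from_groups([5, 5, 5], [7, 7, 7])
        assert np.isnan(out["d"]) and np.isnan(out["g"])
        assert out["magnitude_class"] == "undefined"

    def test_vectorised_matches_per_protein(self, two_group_design):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 0.5, size=(50, 6))
        m = make_matrix(vals, two_group_design)
        table = effect_sizes(m, two_group_design, ("10uM", "vehicle"))
        for i in [0, 17, 49]:
            single = effect_size_from_groups(vals[i, 3:], vals[i, :3])
            assert table["g"].iloc[i] == pytest.approx(single["g"])

    def test_recovers_planted_effect_magnitude(self, two_group_design):
        """Mean Hedges' g over many proteins approaches the analytic value
        implied by the planted shift and the within-group SD."""
        from kinoproteo.preprocess import preprocess_pipeline
        from kinoproteo.synthetic import generate_psm_dataset

        psms, truth = generate_psm_dataset(
            n_proteins=1200, design=two_group_design, frac_de=1.0,
            effect_log2fc=2.0, missing_rate=0.0, psm_count_range=(25, 40),
            psm_noise_sd=0.1, within_group_sd=0.25, seed=17)
        matrix, _ = preprocess_pipeline(psms, seed=1)
        table = effect_sizes(matrix, two_group_design, ("10uM", "vehicle"))
        signs = truth.per_protein.set_index("protein")["true_log2fc_10uM"] \
            .reindex(table.index).apply(np.sign)
        g_aligned = table["g"] * signs
        # Hedges' g is (near-)unbiased for the population standardized
        # effect: planted shift / within-group SD
        analytic = 2.0 / 0.25
        assert abs(g_aligned.mean() - analytic) / analytic < 0.15


class TestDoseFate:
    def test_rule_application(self):
        lfc = pd.DataFrame({"1uM": [0.1], "2.5uM": [-0.7], "10uM": [-2.9]},
                           index=["P1"])
        states, _ = dose_fate(lfc)
        assert list(states.loc["P1"]) == ["stable", "down", "down"]

    def test_all_zero_is_all_stable(self):
        lfc = pd.DataFrame(np.zeros((4, 3)), columns=["a", "b", "c"])
        states, _ = dose_fate(lfc)
        assert (states == "stable").all().all()

    def test_transition_counts_conserve_universe(self):
        rng = np.random.default_rng(2)
        lfc = pd.DataFrame(rng.normal(0, 1, size=(100, 3)),
                           columns=["1uM", "2.5uM", "10uM"])
        _, transitions = dose_fate(lfc)
        for counter in transitions.values():
            assert sum(counter.values()) == 100


class TestIntersectionSummary:
    def test_enumerated_example(self):
        out = intersection_summary({"s1": {"A", "B"}, "s2": {"B", "C"}})
        assert out["exclusive"][frozenset({"s1"})] == 1
        assert out["exclusive"][frozenset({"s1", "s2"})] == 1
        assert out["exclusive"][frozenset({"s2"})] == 1
        assert out["consistent_ge2"] == 1

    def test_identical_sets_single_cell(self):
        out = intersection_summary({"a": {"X", "Y"}, "b": {"X", "Y"}})
        assert out["exclusive"] == {frozenset({"a", "b"}): 2}

    def test_disjoint_sets_share_nothing(self):
        out = intersection_summary({"a": {"X"}, "b": {"Y"}})
        assert out["consistent_ge2"] == 0
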