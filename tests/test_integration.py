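import numpy as np
import pandas as pd
import pytest

import oracles
from kinoproteo.errors import ValidationError
from kinoproteo.integration import (
    assign_quadrant,
    classify_inhibition,
    concordance_correlation,
    merge_kinome_proteomics,
    pathway_mean_inhibition,
    preprocess_kinome,
    rrho_map,
    substrate_enrichment,
    top_substrate_selection,
)
from kinoproteo.io_formats import SubstrateMap


def panel_frame(rows):
    return pd.DataFrame(rows, columns=["kinase", "percent_control", "pathway"])


class TestPreprocessKinome:
    def test_percent_control_31_is_strong_inhibition(self):
        out = preprocess_kinome(panel_frame([("PAK2", 31.0, "PAK")]))
        rec = out.iloc[0]
        assert rec["inhibition"] == pytest.approx(69.0)
        assert rec["inhibition_class"] == "strong"

    def test_duplicates_keep_max_inhibition(self):
        out = preprocess_kinome(panel_frame([
            ("KIN1", 60.0, "PAK"),   # inhibition 40
            ("kin1", 45.0, "PAK"),   # inhibition 55 wins
        ]))
        assert len(out) == 1
        assert out.iloc[0]["inhibition"] == pytest.approx(55.0)

    @pytest.mark.parametrize("inhibition,cls", [
        (69.0, "strong"), (50.0, "moderate"), (50.1, "strong"),
        (30.0, "moderate"), (29.9, "weak"), (0.0, "weak"),
    ])
    def test_class_boundaries(self, inhibition, cls):
        assert classify_inhibition(inhibition) == cls

    def test_dedup_is_idempotent(self):
        panel = panel_frame([("A", 20.0, "x"), ("A", 70.0, "x"),
                             ("B", 55.0, "y")])
        once = preprocess_kinome(panel)
        twice = preprocess_kinome(once[["kinase", "percent_control",
                                        "pathway"]])
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_pathway_mean_inhibition(self):
        out = preprocess_kinome(panel_frame([
            ("A", 40.0, "JAK/STAT"), ("B", 20.0, "JAK/STAT"),
            ("C", 90.0, "PAK")]))
        means = pathway_mean_inhibition(out)
        assert means["JAK/STAT"] == pytest.approx(70.0)
        assert means["PAK"] == pytest.approx(10.0)


class TestMergeAndQuadrants:
    @pytest.mark.parametrize("inhibition,g,quadrant", [
        (69.0, -1.2, "ConcordantHigh"),
        (10.0, 0.1, "ConcordantLow"),
        (80.0, 2.0, "Discordant"),
        (80.0, 0.0, "Discordant"),   # zero g is not "negative"
        (10.0, -1.0, "Discordant"),
        (30.0, -1.0, "Discordant"),  # boundary inhibition
    ])
    def test_quadrant_rule(self, inhibition, g, quadrant):
        assert assign_quadrant(inhibition, g) == quadrant

    def test_merge_inner_joins_and_lists_unmatched(self):
        profile = preprocess_kinome(panel_frame([
            ("PAK2", 31.0, "PAK"), ("GHOST", 40.0, "PAK")]))
        effects = pd.DataFrame({"g": [-1.2], "fdr": [0.03]}, index=["pak2"])
        merged, unmatched = merge_kinome_proteomics(profile, effects)
        assert list(merged["symbol"]) == ["PAK2"]
        assert merged.iloc[0]["quadrant"] == "ConcordantHigh"
        assert unmatched == ["GHOST"]

    def test_quadrants_partition_exhaustively(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame({
            "inhibition": rng.uniform(0, 100, 200),
            "g_signed": rng.normal(0, 2, 200),
        })
        quadrants = [assign_quadrant(i, g) for i, g in
                     zip(records["inhibition"], records["g_signed"])]
        assert set(quadrants) <= {"ConcordantHigh", "ConcordantLow",
                                  "Discordant"}
        assert len(quadrants) == 200  # every record classified exactly once


class TestConcordance:
    def _records(self, inhibition, g):
        return pd.DataFrame({"inhibition": inhibition, "g_signed": g,
                             "g_abs": np.abs(g)})

    def test_perfect_antimonotone_is_minus_one(self):
        rec = self._records([10, 20, 30, 40, 50], [5.0, 4.0, 3.0, 2.0, 1.0])
        assert concordance_correlation(rec)["rho"] == pytest.approx(-1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng.uniform(0, 100, 20), rng.normal(0, 1, 20))
        rho1 = concordance_correlation(rec)["rho"]
        rho2 = concordance_correlation(
            rec.sample(frac=1, random_state=0))["rho"]
        assert rho1 == pytest.approx(rho2)

    def test_matches_sum_d_squared_formula(self):
        inhibition = [12.0, 45.0, 3.0, 78.0, 56.0]
        g = [-0.5, 1.2, 0.3, -2.0, 0.9]
        rec = self._records(inhibition, g)
        rho = concordance_correlation(rec, use_signed=True)["rho"]
        assert rho == pytest.approx(oracles.spearman_rho_d2(inhibition, g))

    def test_signed_and_absolute_modes_differ(self):
        rec = self._records([10, 30, 50, 70, 90],
                            [-0.1, -0.5, -1.0, -2.0, -4.0])
        signed = concordance_correlation(rec, use_signed=True)["rho"]
        absolute = concordance_correlation(rec, use_signed=False)["rho"]
        assert signed == pytest.approx(-1.0)
        assert absolute == pytest.approx(1.0)

    def test_needs_three_records(self):
        with pytest.raises(ValidationError):
            concordance_correlation(self._records([1, 2], [0.1, 0.2]))


class TestRrho:
    def test_identical_rankings_top5_of_10(self):
        ranking = [f"S{i}" for i in range(10)]
        out = rrho_map(ranking, ranking, step=5).set_index(
            ["threshold_a", "threshold_b"])
        cell = out.loc[(5, 5)]
        assert cell["overlap"] == 5
        assert cell["p_hyper"] == pytest.approx(1 / 252)

    def test_full_threshold_is_forced_overlap_p_one(self):
        ranking = [f"S{i}" for i in range(10)]
        reversed_b = ranking[::-1]
        out = rrho_map(ranking, reversed_b, step=5).set_index(
            ["threshold_a", "threshold_b"])
        assert out.loc[(10, 5)]["overlap"] == 5
        assert out.loc[(10, 5)]["p_hyper"] == pytest.approx(1.0)

    def test_matches_enumeration_for_all_cells(self):
        rng = np.random.default_rng(8)
        universe = [f"S{i}" for i in range(12)]
        a = list(rng.permutation(universe))
        b = list(rng.permutation(universe))
        out = rrho_map(a, b, step=1)
        for row in out.itertuples():
            expected = oracles.hypergeom_ge(
                row.overlap, 12, row.threshold_a, row.threshold_b)
            assert row.p_hyper == pytest.approx(expected, rel=1e-9)
            assert row.overlap <= min(row.threshold_a, row.threshold_b)

    def test_reversed_ranking_mirrors_overlap_to_opposite_corner(self):
        """With ranking_b reversed, the top of A matches the bottom of B:
        small-threshold cells lose overlap, complementary corner gains it."""
        universe = [f"S{i}" for i in range(8)]
        fwd = rrho_map(universe, universe, step=2).set_index(
            ["threshold_a", "threshold_b"])
        rev = rrho_map(universe, universe[::-1], step=2).set_index(
            ["threshold_a", "threshold_b"])
        assert fwd.loc[(2, 2)]["overlap"] == 2
        assert rev.loc[(2, 2)]["overlap"] == 0
        # reversed rankings only overlap once the prefixes must intersect:
        # overlap(i, j) = max(0, i + j - N)
        for row in rev.reset_index().itertuples():
            assert row.overlap == max(0, row.threshold_a + row.threshold_b - 8)

    def test_universe_mismatch_lists_difference(self):
        with pytest.raises(ValidationError, match="S99"):
            rrho_map(["S1", "S2", "S99"], ["S1", "S2", "S3"])


class TestSubstrateEnrichment:
    def _map(self, pairs):
        return SubstrateMap(pairs=pd.DataFrame(pairs,
                                               columns=["kinase", "substrate"]))

    def test_2x2_example_matches_enumeration(self):
        universe = {f"G{i}" for i in range(10)}
        subs = sorted(universe)[:4]
        down = set(subs[:3]) | set(sorted(universe - set(subs))[:2])
        smap = self._map([("K", s) for s in subs])
        out = substrate_enrichment(smap, down, universe)
        row = out.iloc[0]
        assert row["odds_ratio"] == pytest.approx(6.0)
        assert row["p"] == pytest.approx(oracles.fisher_greater_p(
            [[3, 1], [2, 4]]))

    def test_kinase_without_substrates_in_universe_is_skipped(self):
        universe = {"G1", "G2"}
        smap = self._map([("K1", "G1"), ("K2", "ZZZ")])
        out = substrate_enrichment(smap, {"G1"}, universe)
        assert list(out["kinase"]) == ["K1"]
        assert out.attrs["skipped"] == ["K2"]

    def test_null_generator_false_positive_rate_near_nominal(self):
        """With no planted enrichment, about 5% (+/-2%) of kinases reach
        p < 0.05 over 200 generated maps."""
        from kinoproteo.synthetic import generate_substrate_map
        proteins = [f"P{i:04d}" for i in range(4000)]
        rng = np.random.default_rng(0)
        down = set(rng.choice(proteins, size=400, replace=False))
        hits = total = 0
        for seed in range(200):
            smap, _ = generate_substrate_map(
                ["K1", "K2"], proteins, "K1", 1.0, seed=seed,
                downregulated=down, n_substrates=100)
            res = substrate_enrichment(smap, down, set(proteins))
            hits += int((res["p"] < 0.05).sum())
            total += len(res)
        assert abs(hits / total - 0.05) <= 0.02

    def test_zero_cell_uses_haldane_correction(self):
        universe = {f"G{i}" for i in range(6)}
        subs = sorted(universe)[:3]
        smap = self._map([("K", s) for s in subs])
        out = substrate_enrichment(smap, set(subs), universe)  # b = c = 0
        row = out.iloc[0]
        assert np.isfinite(row["odds_ratio"])
        assert row["odds_ratio"] == pytest.approx(
            (3.5 * 3.5) / (0.5 * 0.5))


class TestTopSubstrates:
    def _effects(self, lfc_by_symbol):
        return pd.DataFrame({"log2fc": pd.Series(lfc_by_symbol)})

    def test_returns_fewer_when_fewer_exist(self):
        smap = SubstrateMap(pairs=pd.DataFrame(
            [("K", s) for s in ["A", "B", "C"]],
            columns=["kinase", "substrate"]))
        eff = self._effects({"A": 1.0, "B": -2.0, "C": 0.5, "D": 9.0})
        out = top_substrate_selection("K", smap, eff, k=5)
        assert len(out) == 3
        assert list(out["substrate"]) == ["B", "A", "C"]

    def test_ordering_matches_full_sort(self):
        rng = np.random.default_rng(4)
        symbols = [f"S{i:02d}" for i in range(30)]
        lfc = dict(zip(symbols, rng.normal(0, 2, 30)))
        smap = SubstrateMap(pairs=pd.DataFrame(
            [("K", s) for s in symbols], columns=["kinase", "substrate"]))
        out = top_substrate_selection("K", smap, self._effects(lfc), k=5)
        expected = sorted(symbols, key=lambda s: (-abs(lfc[s]), s))[:5]
        assert list(out["substrate"]) == expected

    def test_tie_broken_lexicographically(self):
        smap = SubstrateMap(pairs=pd.DataFrame(
            [("K", s) for s in ["ZED", "ANN", "MID"]],
            columns=["kinase", "substrate"]))
        eff = self._effects({"ZED": 2.0, "ANN": -2.0, "MID": 1.0})
        out = top_substrate_selection("K", smap, eff, k=2)
        assert list(out["substrate"]) == ["ANN", "ZED"]

    def test_no_quantified_substrate_errors(self):
        smap = SubstrateMap(pairs=pd.DataFrame(
            [("K", "GHOST")], columns=["kinase", "substrate"]))
        with pytest.raises(ValidationError):
            top_substrate_selection("K", smap, self._effects({"A": 1.0}))
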