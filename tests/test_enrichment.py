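"""Null-model and enrichment statistics, checked against independent oracles:
exact geometry for the tandem null, exhaustive hypergeometric enumeration for
Fisher p-values, and a hand-computed step-up for the BH correction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinodup.classify import FamilyCounts
from kinodup.enrichment import (
    TandemNullConfig,
    analytic_expected_tandem,
    benjamini_hochberg,
    classify_ratios,
    expected_segmental,
    fisher_enrichment,
    interpolate_expected,
    phenotype_enrichment,
    simulate_expected_tandem,
)
from kinodup.io import ValidationError
from kinodup.simulate import sample_mode_counts, sample_phenotypes


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum probabilities of all tables with
    the same margins whose point probability does not exceed the observed
    table's (computed from factorials only)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestTandemNull:
    def test_analytic_matches_geometry_constant(self):
        # band area (2wL' - w^2)/L'^2 with L' = 99999 kb, w = 50 kb
        assert analytic_expected_tandem(2) == pytest.approx(0.00099976, abs=5e-9)

    def test_window_covering_genome_counts_all_pairs(self):
        lp = 100_000.0 - 1.0
        assert analytic_expected_tandem(10, window=lp) == pytest.approx(math.comb(10, 2))

    def test_tiny_families_have_zero_expectation(self):
        assert analytic_expected_tandem(0) == 0.0
        assert analytic_expected_tandem(1) == 0.0

    def test_simulation_agrees_with_closed_form(self):
        exp = simulate_expected_tandem(TandemNullConfig(seed=123))
        for N in (10, 100, 300):
            mean, se = exp[N]
            assert abs(mean - analytic_expected_tandem(N)) <= 3 * se

    def test_expectations_increase_with_family_size(self):
        exp = simulate_expected_tandem(TandemNullConfig(seed=5, replicates=200))
        means = [exp[n][0] for n in sorted(exp)]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_deterministic_under_seed(self):
        cfg = TandemNullConfig(seed=9, replicates=50, family_sizes=(10, 50))
        assert simulate_expected_tandem(cfg) == simulate_expected_tandem(cfg)

    def test_interpolation_on_and_off_grid(self):
        exp = {10: (1.0, 0.0), 20: (3.0, 0.0)}
        assert interpolate_expected(exp, 10) == 1.0
        assert interpolate_expected(exp, 15) == 2.0


class TestExpectedSegmental:
    @pytest.mark.parametrize("n,expect", [(100, 75.0), (0, 0.0), (13, 9.75)])
    def test_values(self, n, expect):
        assert expected_segmental(n) == expect


class TestRatioBands:
    @staticmethod
    def fam(name, tandem_pairs, segmental, n=40, et=1.0, es=1.0):
        obs = {"tandem": 0, "wgd_segmental": segmental, "dispersed": 0,
               "proximal": 0, "transposed": 0,
               "singleton": n - segmental}
        return FamilyCounts(name, n, obs, expected_tandem=et,
                            expected_segmental=es,
                            observed_tandem_pairs=tandem_pairs)

    def test_three_family_bands(self):
        # tandem ratios {1,2,3}: median 2, sample SD 1; boundary ratios
        # fall in the band away from the median, the median in the box.
        fams = [self.fam("a", 1, 2), self.fam("b", 2, 2), self.fam("c", 3, 2)]
        rc = classify_ratios(fams)
        assert rc.tandem_median == 2 and rc.tandem_sd == 1
        bands = dict(zip(rc.table["family"], rc.table["tandem_band"]))
        assert bands == {"a": "-2SD..-1SD", "b": "box", "c": "+1SD..+2SD"}

    def test_extreme_ratio_beyond_two_sd(self):
        fams = [self.fam("a", 10, 2), self.fam("b", 20, 2), self.fam("c", 30, 2),
                self.fam("d", 45, 2)]
        rc = classify_ratios(fams)
        bands = dict(zip(rc.table["family"], rc.table["tandem_band"]))
        med, sd = rc.tandem_median, rc.tandem_sd
        assert bands["d"] == ("above+2SD" if 45 >= med + 2 * sd else bands["d"])

    def test_family_at_both_medians_is_boxed(self):
        fams = [self.fam("a", 1, 1), self.fam("b", 2, 2), self.fam("c", 3, 3)]
        rc = classify_ratios(fams)
        row = rc.table.set_index("family").loc["b"]
        assert row["tandem_band"] == "box" and row["segmental_band"] == "box"

    def test_order_invariant(self):
        fams = [self.fam("a", 1, 4), self.fam("b", 2, 2), self.fam("c", 3, 1)]
        fwd = classify_ratios(fams).table
        rev = classify_ratios(fams[::-1]).table
        pd.testing.assert_frame_equal(fwd, rev)

    def test_zero_expectations_rejected(self):
        fams = [self.fam("a", 1, 1, et=0.0, es=0.0),
                self.fam("b", 1, 1, et=0.0, es=0.0)]
        with pytest.raises(ValidationError, match="zero expectations"):
            classify_ratios(fams)


class TestFisherEnrichment:
    def test_balanced_table_is_null(self):
        mat = pd.DataFrame([[10, 10], [10, 10]], index=["f1", "f2"],
                           columns=["tandem", "other"])
        res = fisher_enrichment(mat)
        assert all(r.p_value == pytest.approx(1.0) for r in res)
        assert all(r.pearson_residual == pytest.approx(0.0) for r in res)

    def test_diagonal_table_p_value(self):
        mat = pd.DataFrame([[5, 0], [0, 5]], index=["f1", "f2"],
                           columns=["m1", "m2"])
        res = fisher_enrichment(mat)
        p = next(r.p_value for r in res if (r.family, r.mode) == ("f1", "m1"))
        assert p == pytest.approx(2 / 252)

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            mat = pd.DataFrame(
                rng.integers(0, 8, size=(3, 3)),
                index=["f1", "f2", "f3"], columns=["m1", "m2", "m3"],
            )
            if mat.to_numpy().sum() > 60:
                continue
            for r in fisher_enrichment(mat):
                if r.degenerate:
                    continue
                row = mat.loc[r.family]
                a = int(row[r.mode])
                b = int(row.sum()) - a
                c = int(mat[r.mode].sum()) - a
                d = int(mat.to_numpy().sum()) - a - b - c
                assert r.p_value == pytest.approx(
                    hypergeom_two_sided(a, b, c, d), rel=1e-9
                ), (a, b, c, d)

    def test_residual_zero_when_observed_equals_expected(self):
        mat = pd.DataFrame([[2, 4], [4, 8]], index=["f1", "f2"],
                           columns=["m1", "m2"])
        res = fisher_enrichment(mat)
        assert all(abs(r.pearson_residual) < 1e-12 for r in res)

    def test_degenerate_margin_flagged(self):
        mat = pd.DataFrame([[0, 0], [3, 4]], index=["f1", "f2"],
                           columns=["m1", "m2"])
        res = fisher_enrichment(mat)
        f1 = [r for r in res if r.family == "f1"]
        assert all(r.degenerate and r.p_value == 1.0 and r.pearson_residual == 0
                   for r in f1)

    def test_false_positive_rate_under_global_null(self):
        base = {"wgd_segmental": 0.26, "dispersed": 0.41, "proximal": 0.046,
                "tandem": 0.10, "singleton": 0.184}
        sizes = {f"fam{i:02d}": 60 for i in range(1, 11)}
        sizes["bg"] = 2400
        fracs = []
        for rep in range(200):
            counts = sample_mode_counts(sizes, base, seed=50_000 + rep)
            ps = [r.p_value for r in fisher_enrichment(counts) if not r.degenerate]
            fracs.append(np.mean([p <= 0.05 for p in ps]))
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_planted_tandem_family_detected(self):
        base = {"wgd_segmental": 0.26, "dispersed": 0.41, "proximal": 0.046,
                "tandem": 0.10, "singleton": 0.184}
        sizes = {"famX": 60, "bg": 2940}
        hit = 0
        for rep in range(100):
            counts = sample_mode_counts(
                sizes, base, boost={("famX", "tandem"): 3.0}, seed=rep
            )
            r = next(x for x in fisher_enrichment(counts)
                     if (x.family, x.mode) == ("famX", "tandem"))
            if r.p_adjusted < 0.05 and r.pearson_residual > 0:
                hit += 1
        assert hit >= 90


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        # p*(m/rank): .01*4=.04, .02*2=.04, .03*4/3=.04, .04*1=.04
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == [0.3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.1, 1.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_in_sorted_order_and_dominates_raw(self, ps):
        adj = benjamini_hochberg(ps)
        order = np.argsort(ps)
        sorted_adj = np.array(adj)[order]
        assert np.all(np.diff(sorted_adj) >= -1e-12)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))


class TestPhenotypeEnrichment:
    def test_planted_odds_ratio_three_detected(self):
        hit = 0
        for rep in range(100):
            phen, focal = sample_phenotypes(
                2000, 150, boost_class="essential", odds_ratio=3.0, seed=rep
            )
            r = next(x for x in phenotype_enrichment(phen, focal)
                     if x.mode == "essential")
            if r.p_adjusted < 0.05 and r.pearson_residual > 0:
                hit += 1
        assert hit >= 90

    def test_null_p_values_are_flat(self):
        ps = []
        for rep in range(40):
            phen, focal = sample_phenotypes(2000, 150, seed=9_000 + rep)
            ps.append(next(x for x in phenotype_enrichment(phen, focal)
                           if x.mode == "essential").p_value)
        assert np.median(ps) >= 0.3

    def test_single_class_degenerates_to_one(self):
        phen = {f"g{i}": "conditional" for i in range(50)}
        res = phenotype_enrichment(phen, {"g0", "g1"})
        assert all(r.p_value == 1.0 for r in res)

    def test_empty_focal_rejected(self):
        with pytest.raises(ValidationError, match="focal"):
            phenotype_enrichment({"g": "none"}, set())
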