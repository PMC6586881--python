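"""Replicate correlation, empirical null, germline genotyping, expression test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvseq.concordance import (GermlineLocus, empirical_null, empirical_p,
                                expression_association, genotype_locus,
                                locus_ratios, pair_correlation)
from cnvseq.simdata import simulate_germline_cohort
from cnvseq.tiling import build_tiling


class TestPairCorrelation:
    def test_identical_profiles(self, rng):
        v = rng.normal(0, 1, 100)
        assert pair_correlation(v, v) == pytest.approx(1.0)

    def test_anti_correlated(self, rng):
        v = rng.normal(0, 1, 100)
        assert pair_correlation(v, -v) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        a = rng.normal(0, 1, 30_000)
        b = rng.normal(0, 1, 30_000)
        assert abs(pair_correlation(a, b)) < 0.02

    def test_mask_and_missing_excluded(self, rng):
        a = rng.normal(0, 1, 50)
        b = a.copy()
        b[0] = 100.0                      # would wreck r if included...
        mask = np.zeros(50, bool)
        mask[0] = True                    # ...but is masked
        a[1] = np.nan                     # and missing windows are dropped
        assert pair_correlation(a, b, mask) == pytest.approx(1.0)


class TestEmpiricalNull:
    def test_pair_count_closed_form(self, rng):
        profiles = {f"s{i}": rng.normal(0, 1, 20) for i in range(300)}
        persons = {f"s{i}": f"p{i}" for i in range(300)}
        null = empirical_null(profiles, persons)
        assert null.size == 300 * 299 // 2 == 44_850
        assert round(null.size, -3) == 45_000

    def test_three_persons(self, rng):
        profiles = {s: rng.normal(0, 1, 10) for s in "abc"}
        null = empirical_null(profiles, {"a": "pa", "b": "pb", "c": "pc"})
        assert null.size == 3

    def test_same_person_pairs_excluded(self, rng):
        profiles = {s: rng.normal(0, 1, 10) for s in ("a1", "a2", "b1")}
        persons = {"a1": "A", "a2": "A", "b1": "B"}
        null = empirical_null(profiles, persons)
        assert null.size == 2  # a1-b1 and a2-b1 only

    def test_add_one_p(self):
        null = np.linspace(-0.5, 0.5, 99)
        assert empirical_p(1.0, null) == pytest.approx(1 / 100)
        assert empirical_p(-1.0, null) == pytest.approx(1.0)
        assert empirical_p(0.0, null) > 0


class TestGermlineLocus:
    def test_disjoint_required(self):
        with pytest.raises(ValueError):
            GermlineLocus(np.array([5, 6]), np.array([6, 7]))

    def test_from_span_on_esv_coordinates(self):
        tiling = build_tiling([("chr9", 23_500_000)], 10_000)
        locus = GermlineLocus.from_span(tiling, "chr9", 23_362_412, 23_378_071,
                                        n_flank=10)
        np.testing.assert_array_equal(locus.locus_windows, [2336, 2337])
        assert locus.flank_windows.size == 20
        assert set(locus.flank_windows) == set(range(2326, 2336)) | set(range(2338, 2348))

    def test_flank_skips_blacklisted(self):
        tiling = build_tiling([("chr1", 400_000)], 10_000)
        bl = np.zeros(40, bool)
        bl[18] = True
        locus = GermlineLocus.from_span(tiling, "chr1", 200_000, 220_000,
                                        n_flank=3, blacklist=bl)
        assert 18 not in locus.flank_windows
        assert locus.flank_windows.size == 6


class TestLocusRatios:
    def _table(self, locus_counts, flank_value=100.0, n_flank=10):
        n_locus = len(locus_counts)
        v = np.full(n_flank * 2 + n_locus, flank_value)
        v[n_flank:n_flank + n_locus] = locus_counts
        return {"s": v}, GermlineLocus(
            np.arange(n_flank, n_flank + n_locus),
            np.concatenate([np.arange(n_flank),
                            np.arange(n_flank + n_locus, n_flank * 2 + n_locus)]))

    def test_heterozygous_ratio_half(self):
        table, locus = self._table([50.0, 50.0])
        assert locus_ratios(table, locus)["s"] == pytest.approx(0.5)

    def test_homozygous_deletion_ratio_zero(self):
        table, locus = self._table([0.0, 0.0])
        assert locus_ratios(table, locus)["s"] == pytest.approx(0.0)

    def test_depth_scaling_invariance(self, rng):
        v = rng.poisson(100, 22).astype(float)
        locus = GermlineLocus(np.array([10, 11]),
                              np.concatenate([np.arange(10), np.arange(12, 22)]))
        r1 = locus_ratios({"s": v}, locus)["s"]
        r2 = locus_ratios({"s": v * 3.7}, locus)["s"]
        assert r1 == pytest.approx(r2)

    def test_mostly_blacklisted_flank_is_missing(self):
        table, locus = self._table([50.0, 50.0])
        bl = np.zeros(22, bool)
        bl[:11] = True  # 10 of 20 flank windows + one locus window
        assert np.isnan(locus_ratios(table, locus, blacklist=bl)["s"])


class TestGenotypeLocus:
    def test_hardy_weinberg_cohort_three_modes_and_accuracy(self):
        """300-sample cohort, deletion allele frequency 0.4, depth 100:
        the mixture finds 3 dosage modes and >= 95% genotype accuracy."""
        table, truth, locus_idx = simulate_germline_cohort(
            n_samples=300, allele_frequency=0.4, depth=100.0, seed=42)
        locus = GermlineLocus(locus_idx,
                              np.setdiff1d(np.arange(table.shape[0]), locus_idx))
        res = genotype_locus(table, locus, seed=0)
        assert res["n_modes"] == 3
        acc = (res["genotypes"] == truth).mean()
        assert acc >= 0.95

    def test_single_mode_cohort_collapses(self, rng):
        counts = rng.poisson(100, (22, 120)).astype(float)
        table = pd.DataFrame(counts, columns=[f"s{i}" for i in range(120)])
        locus = GermlineLocus(np.array([10, 11]),
                              np.concatenate([np.arange(10), np.arange(12, 22)]))
        res = genotype_locus(table, locus, seed=0)
        assert res["n_modes"] <= 2  # no segregating deletion: < 3 modes


class TestExpressionAssociation:
    def test_identical_groups(self, rng):
        expr = pd.Series(rng.normal(10, 1, 40), index=[f"s{i}" for i in range(40)])
        res = expression_association(expr, deletion_samples=[f"s{i}" for i in range(20)])
        # same distribution: no significant shift, fold change near 1
        assert res["p_value"] > 0.05
        assert res["fold_change"] == pytest.approx(1.0, abs=0.2)

    def test_four_fold_reduction_detected(self, rng):
        base = rng.lognormal(np.log(100), 0.1, 30)
        reduced = rng.lognormal(np.log(25), 0.1, 15)
        expr = pd.Series(np.concatenate([base, reduced]),
                         index=[f"s{i}" for i in range(45)])
        res = expression_association(expr, [f"s{i}" for i in range(30, 45)])
        assert res["p_value"] < 1e-4
        assert 2.0 <= res["fold_change"] <= 5.0

    def test_empty_group_is_error(self, rng):
        expr = pd.Series(rng.normal(size=5), index=list("abcde"))
        with pytest.raises(ValueError):
            expression_association(expr, deletion_samples=[])

    def test_u_statistic_matches_bruteforce_pair_count(self, rng):
        """Mann-Whitney U equals the count of (normal > deletion) pairs
        (+ half ties) on every small instance."""
        for _ in range(25):
            n1, n2 = rng.integers(2, 11, size=2)
            a = rng.integers(0, 8, n1).astype(float)   # ties likely
            b = rng.integers(0, 8, n2).astype(float)
            expr = pd.Series(np.concatenate([a, b]),
                             index=[f"x{i}" for i in range(n1 + n2)])
            res = expression_association(expr, [f"x{i}" for i in range(n1, n1 + n2)])
            brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert res["U"] == pytest.approx(brute)
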