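"""Robust LOESS bias correction, composite normal and log2 ratios."""

import numpy as np
import pytest
from scipy import stats

from cnvseq.normalize import (build_composite_normal, cn_log2_ratio,
                              correct_sample, loess_correct)
import pandas as pd


def _labels(n, chrom="chr1"):
    return np.full(n, chrom)


class TestLoessCorrect:
    def test_constant_covariate_is_identity(self, rng):
        counts = rng.poisson(100, 500).astype(float)
        adj = loess_correct(counts, np.full(500, 0.45), _labels(500))
        np.testing.assert_allclose(adj, counts, rtol=1e-6)

    def test_quadratic_gc_bias_removed(self, rng):
        """Poisson counts with quadratic GC bias: |Spearman| < 0.05 after."""
        n = 5000
        gc = rng.uniform(0.4, 0.7, n)  # off-peak range: bias is monotone in GC
        bias = 1.0 - 3.0 * (gc - 0.45) ** 2
        counts = rng.poisson(100 * bias).astype(float)
        rho_before = stats.spearmanr(counts, gc).statistic
        adj = loess_correct(counts, gc, _labels(n))
        rho_after = stats.spearmanr(adj, gc).statistic
        assert abs(rho_before) > 0.2
        assert abs(rho_after) < 0.05

    def test_robust_to_extreme_outlier(self, rng):
        n = 2000
        gc = rng.uniform(0.3, 0.6, n)
        counts = rng.poisson(100, n).astype(float)
        spiked = counts.copy()
        spiked[1000] *= 50
        adj_clean = loess_correct(counts, gc, _labels(n))
        adj_spiked = loess_correct(spiked, gc, _labels(n))
        near = np.abs(gc - gc[1000]) < 0.02
        near[1000] = False
        rel = np.abs(adj_spiked[near] - adj_clean[near]) / adj_clean[near]
        assert np.median(rel) < 0.01

    def test_median_preserved_per_chromosome(self, rng):
        n = 1200
        gc = rng.uniform(0.3, 0.6, n)
        counts = rng.poisson(100 * (1 - 2 * (gc - 0.45) ** 2)).astype(float)
        labels = np.where(np.arange(n) < 700, "chr1", "chr2")
        adj = loess_correct(counts, gc, labels)
        for chrom in ("chr1", "chr2"):
            sel = labels == chrom
            assert np.median(adj[sel]) == pytest.approx(np.median(counts[sel]), rel=1e-9)

    def test_small_chromosome_passes_through(self, rng):
        counts = rng.poisson(50, 10).astype(float)
        with pytest.warns(UserWarning, match="informative windows"):
            adj = loess_correct(counts, rng.uniform(0, 1, 10), _labels(10))
        np.testing.assert_array_equal(adj, counts)

    def test_missing_covariate_passes_through(self, rng):
        n = 200
        gc = rng.uniform(0.3, 0.6, n)
        gc[5] = np.nan
        counts = rng.poisson(100, n).astype(float)
        adj = loess_correct(counts, gc, _labels(n))
        assert adj[5] == counts[5]


class TestCorrectSample:
    def _annot(self, gc, mapp):
        return pd.DataFrame({"gc": gc, "mappability": mapp})

    def test_flat_biases_identity(self, rng):
        n = 300
        counts = rng.poisson(120, n).astype(float)
        annot = self._annot(np.full(n, 0.5), np.full(n, 1.0))
        np.testing.assert_allclose(correct_sample(counts, annot, _labels(n)),
                                   counts, rtol=1e-6)

    def test_gc_only_bias_leaves_mappability_pass_near_identity(self, rng):
        n = 3000
        gc = rng.uniform(0.3, 0.6, n)
        mapp = rng.uniform(0.9, 1.0, n)  # no real mappability effect
        counts = rng.poisson(100 * (1 - 2.5 * (gc - 0.45) ** 2)).astype(float)
        after_gc = loess_correct(counts, gc, _labels(n))
        both = correct_sample(counts, self._annot(gc, mapp), _labels(n))
        rel = np.abs(both - after_gc) / np.maximum(after_gc, 1.0)
        assert np.median(rel) < 0.01

    def test_recovers_poisson_variation(self, rng):
        """After removing both biases the residual CV is Poisson-like."""
        n = 5000
        gc = rng.uniform(0.3, 0.6, n)
        mapp = rng.uniform(0.6, 1.0, n)
        mean = 200 * (1 - 2.0 * (gc - 0.45) ** 2) * mapp
        counts = rng.poisson(mean).astype(float)
        adj = correct_sample(counts, self._annot(gc, mapp), _labels(n))
        cv = adj.std() / adj.mean()
        poisson_cv = 1 / np.sqrt(adj.mean())
        assert cv == pytest.approx(poisson_cv, rel=0.2)

    def test_scale_equivariance_of_log2_ratio(self, rng):
        n = 1000
        gc = rng.uniform(0.3, 0.6, n)
        annot = self._annot(gc, np.ones(n))
        counts = rng.poisson(100, n).astype(float)
        comp = rng.poisson(700, n).astype(float)
        a1 = correct_sample(counts, annot, _labels(n))
        a2 = correct_sample(counts * 7, annot, _labels(n))
        l1 = cn_log2_ratio(a1, comp)
        l2 = cn_log2_ratio(a2, comp)
        np.testing.assert_allclose(l1, l2, atol=1e-9)

    def test_idempotent_in_the_limit(self, rng):
        n = 3000
        gc = rng.uniform(0.3, 0.6, n)
        counts = rng.poisson(100 * (1 - 2.0 * (gc - 0.45) ** 2)).astype(float)
        annot = self._annot(gc, np.ones(n))
        once = correct_sample(counts, annot, _labels(n))
        twice = correct_sample(once, annot, _labels(n))
        rel = np.abs(twice - once) / np.maximum(once, 1.0)
        assert np.median(rel) < 0.01


class TestCompositeNormal:
    def test_raw_is_elementwise_sum(self, rng):
        v = rng.poisson(100, 200)
        annot = pd.DataFrame({"gc": np.full(200, 0.5)})
        comp = build_composite_normal([v] * 7, annot, _labels(200))
        np.testing.assert_array_equal(comp.raw, 7 * v)

    def test_single_vector_equals_sample_correction(self, rng):
        n = 500
        gc = rng.uniform(0.3, 0.6, n)
        annot = pd.DataFrame({"gc": gc})
        v = rng.poisson(100, n)
        comp = build_composite_normal([v], annot, _labels(n))
        np.testing.assert_allclose(comp.adjusted,
                                   correct_sample(v, annot, _labels(n)))

    def test_pooling_reduces_cv(self, rng):
        n = 2000
        annot = pd.DataFrame({"gc": np.full(n, 0.5)})
        normals = [rng.poisson(100, n) for _ in range(7)]
        comp = build_composite_normal(normals, annot, _labels(n))
        comp_cv = comp.adjusted.std() / comp.adjusted.mean()
        indiv_cvs = [v.std() / v.mean() for v in normals]
        assert comp_cv < min(indiv_cvs)

    def test_empty_normals_rejected(self):
        with pytest.raises(ValueError):
            build_composite_normal([], pd.DataFrame(), np.array([]))


class TestCnLog2Ratio:
    def test_identical_profiles_are_zero(self, rng):
        v = rng.poisson(100, 300).astype(float) + 1
        np.testing.assert_allclose(cn_log2_ratio(v, v), 0.0, atol=1e-12)

    def test_half_depth_windows_near_minus_one(self, rng):
        n = 4000
        comp = np.full(n, 700.0)
        mean = np.full(n, 100.0)
        mean[[100, 101]] = 50.0
        sample = rng.poisson(mean).astype(float)
        log2 = cn_log2_ratio(sample, comp)
        assert np.nanmedian(log2[[100, 101]]) == pytest.approx(-1.0, abs=0.35)
        assert np.nanmedian(log2) == pytest.approx(0.0, abs=0.02)

    def test_whole_chromosome_doubling_closed_form(self):
        # noiseless: chr2 (500 of 5500 windows) doubled
        comp = np.full(5500, 100.0)
        sample = np.full(5500, 100.0)
        sample[5000:] *= 2
        log2 = cn_log2_ratio(sample, comp)
        total_ratio = sample.sum() / comp.sum()
        expected = 1.0 - np.log2(total_ratio)
        assert np.median(log2[5000:]) == pytest.approx(expected, abs=1e-12)

    def test_zero_sample_window_missing_without_pseudocount(self):
        s = np.array([100.0, 0.0, 100.0])
        c = np.array([100.0, 100.0, 100.0])
        log2 = cn_log2_ratio(s, c)
        assert np.isnan(log2[1])
        with_pc = cn_log2_ratio(s, c, pseudocount=0.5)
        assert np.isfinite(with_pc[1]) and with_pc[1] < -5

    def test_blacklisted_and_zero_composite_missing(self):
        s = np.array([100.0, 100.0, 100.0])
        c = np.array([100.0, 0.0, 100.0])
        mask = np.array([True, False, False])
        log2 = cn_log2_ratio(s, c, blacklist=mask)
        assert np.isnan(log2[0]) and np.isnan(log2[1]) and np.isfinite(log2[2])
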