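"""Replicate concordance, cross-person null, germline-CNV genotyping,
and copy-number-vs-expression association.

Replicate pairs (re-sequenced libraries, repeat cores, etc.) are compared
by Pearson correlation of bias-corrected window counts over jointly
retained windows.  Significance comes from an empirical null: the
correlations of all cross-person sample pairs, with an add-one p-value so
p is never zero.

A biallelic germline deletion polymorphism gives an internal truth
standard: the ratio of mean corrected counts over the deleted span to the
flanking windows falls into three dosage classes (2/1/0 intact copies),
recovered by a seeded three-component Gaussian mixture whose degenerate
components are collapsed — the number of surviving components is the
number of detected peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .tiling import WindowTiling

__all__ = [
    "pair_correlation",
    "empirical_null",
    "empirical_p",
    "GermlineLocus",
    "locus_ratios",
    "genotype_locus",
    "expression_association",
]

REPLICATE_TYPES = ("technical", "method", "concentration", "core", "tumour")


def pair_correlation(profile_a: np.ndarray, profile_b: np.ndarray,
                     mask: np.ndarray | None = None) -> float:
    """Pearson correlation over windows retained (finite, unmasked) in both."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 jointly retained windows")
    return float(np.corrcoef(a[keep], b[keep])[0, 1])


def empirical_null(profiles: Mapping[str, np.ndarray],
                   person_labels: Mapping[str, str],
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Correlations of all distinct unordered cross-person sample pairs."""
    samples = list(profiles)
    missing = [s for s in samples if s not in person_labels]
    if missing:
        raise ValueError(f"samples without person labels: {missing}")
    out = []
    for a, b in combinations(samples, 2):
        if person_labels[a] == person_labels[b]:
            continue
        out.append(pair_correlation(profiles[a], profiles[b], mask))
    return np.asarray(out)


def empirical_p(observed_r: float, null: np.ndarray) -> float:
    """Add-one empirical p: (1 + #null >= r) / (1 + #null); never zero."""
    null = np.asarray(null, dtype=float)
    return float((1 + (null >= observed_r).sum()) / (1 + null.size))


@dataclass
class GermlineLocus:
    """Windows over a germline CNV span plus disjoint flanking windows.

    The flanks (``n_flank`` windows on each side, skipping blacklisted
    windows) normalise away somatic changes in the surrounding region.
    """

    locus_windows: np.ndarray
    flank_windows: np.ndarray

    def __post_init__(self):
        self.locus_windows = np.asarray(self.locus_windows, dtype=int)
        self.flank_windows = np.asarray(self.flank_windows, dtype=int)
        if np.intersect1d(self.locus_windows, self.flank_windows).size:
            raise ValueError("locus and flank windows must be disjoint")

    @classmethod
    def from_span(cls, tiling: WindowTiling, chrom: str, start: int, end: int,
                  n_flank: int = 10,
                  blacklist: np.ndarray | None = None) -> "GermlineLocus":
        """Locus = all windows overlapping [start, end); n_flank retained
        windows on each side within the chromosome."""
        sl = tiling.chrom_slice(chrom)
        ws, we = tiling.starts[sl], tiling.ends[sl]
        hit = np.flatnonzero((ws < end) & (we > start)) + sl.start
        if hit.size == 0:
            raise ValueError("span overlaps no windows")
        bl = (np.asarray(blacklist, dtype=bool) if blacklist is not None
              else np.zeros(tiling.n_windows, bool))
        left = [w for w in range(hit[0] - 1, sl.start - 1, -1) if not bl[w]][:n_flank]
        right = [w for w in range(hit[-1] + 1, sl.stop) if not bl[w]][:n_flank]
        return cls(hit, np.asarray(sorted(left) + right, dtype=int))


def locus_ratios(adjusted_counts: Mapping[str, np.ndarray] | pd.DataFrame,
                 locus: GermlineLocus,
                 blacklist: np.ndarray | None = None) -> pd.Series:
    """Per-sample ratio of mean corrected counts: locus windows / flank windows.

    Invariant to each sample's overall depth.  If more than half the flank
    windows are unavailable (blacklisted or non-finite) the ratio is NaN.
    """
    if isinstance(adjusted_counts, pd.DataFrame):
        items = {c: adjusted_counts[c].to_numpy(dtype=float)
                 for c in adjusted_counts.columns}
    else:
        items = {k: np.asarray(v, dtype=float) for k, v in adjusted_counts.items()}
    bl = None if blacklist is None else np.asarray(blacklist, dtype=bool)
    out = {}
    n_flank_total = locus.flank_windows.size
    for sample, v in items.items():
        fl = v[locus.flank_windows]
        ok = np.isfinite(fl)
        if bl is not None:
            ok &= ~bl[locus.flank_windows]
        lo = v[locus.locus_windows]
        lo_ok = np.isfinite(lo)
        if ok.sum() <= n_flank_total / 2 or not lo_ok.any() or fl[ok].mean() <= 0:
            out[sample] = np.nan
            continue
        out[sample] = float(lo[lo_ok].mean() / fl[ok].mean())
    return pd.Series(out, name="locus_ratio")


def genotype_locus(adjusted_counts: Mapping[str, np.ndarray] | pd.DataFrame,
                   locus: GermlineLocus,
                   blacklist: np.ndarray | None = None,
                   seed: int | None = 0,
                   n_restarts: int = 5) -> dict:
    """Genotype a biallelic deletion locus from locus/flank depth ratios.

    Fits a 3-component univariate Gaussian mixture to the per-sample
    ratios (5 seeded restarts); components with weight < 2/n are collapsed
    and the survivors counted as modes.  Components ordered by descending
    mean map to genotypes 0/1/2 deleted alleles.
    """
    ratios = locus_ratios(adjusted_counts, locus, blacklist)
    vals = ratios.dropna().to_numpy(dtype=float)
    n = vals.size
    if n < 3:
        raise ValueError("need at least 3 samples with defined ratios")
    k = min(3, n)
    gm = GaussianMixture(n_components=k, n_init=n_restarts,
                         random_state=seed, reg_covar=1e-4)
    gm.fit(vals.reshape(-1, 1))
    weights = gm.weights_
    keep = weights >= 2.0 / n
    n_modes = _count_density_modes(gm, keep, vals)
    means = gm.means_.ravel()
    # genotype = number of deleted alleles; highest-mean component = 0 deleted
    order = np.argsort(means)[::-1]
    rank_of_component = {comp: rank for rank, comp in enumerate(order)}
    comp = gm.predict(vals.reshape(-1, 1))
    genotype = pd.Series(np.nan, index=ratios.index, name="genotype")
    genotype.loc[ratios.dropna().index] = [rank_of_component[c] for c in comp]
    return {
        "ratios": ratios,
        "genotypes": genotype,
        "n_modes": n_modes,
        "component_means": means[order],
        "component_weights": weights[order],
    }


def _count_density_modes(gm: GaussianMixture, keep: np.ndarray,
                         vals: np.ndarray, n_grid: int = 512) -> int:
    """Modes of the fitted mixture density after dropping degenerate components.

    Components below the weight floor are removed (renormalising the rest);
    the surviving density is evaluated on a grid spanning the data and its
    strict local maxima counted — overlapping components that merge into
    one hump therefore count once.
    """
    w = gm.weights_[keep]
    if w.size == 0:
        return 0
    w = w / w.sum()
    mu = gm.means_.ravel()[keep]
    sd = np.sqrt(gm.covariances_.ravel()[keep])
    lo, hi = vals.min(), vals.max()
    pad = 0.05 * (hi - lo + 1e-9)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    dens = np.zeros_like(grid)
    for wk, mk, sk in zip(w, mu, sd):
        dens += wk * np.exp(-0.5 * ((grid - mk) / sk) ** 2) / sk
    interior = dens[1:-1]
    is_max = (interior > dens[:-2]) & (interior >= dens[2:])
    return max(int(is_max.sum()), 1)


def expression_association(expression_by_sample: Mapping[str, float] | pd.Series,
                           deletion_samples: Sequence[str]) -> dict:
    """Mann-Whitney U of expression in deletion vs no-change samples.

    Returns the U statistic, two-sided p (exact where SciPy deems it
    feasible) and the fold-change of group medians
    (no-change median / deletion median).
    """
    expr = pd.Series(expression_by_sample, dtype=float)
    deletion = expr.loc[expr.index.intersection(deletion_samples)].dropna()
    normal = expr.drop(deletion.index, errors="ignore").dropna()
    if deletion.empty or normal.empty:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(normal.to_numpy(), deletion.to_numpy(),
                             alternative="two-sided")
    med_d = float(deletion.median())
    fold = float(normal.median() / med_d) if med_d != 0 else float("inf")
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "fold_change": fold,
        "n_deletion": int(deletion.size),
        "n_no_change": int(normal.size),
    }
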