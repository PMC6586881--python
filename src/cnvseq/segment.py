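"""Circular binary segmentation (CBS) with permutation acceptance and SD-undo.

CBS recursively finds the arc of a (circularised) sequence of log2 ratios
whose mean differs most from its complement.  The maximising statistic is

    U(i, j) = |T_j - T_i| / sqrt(L (1 - L/n)),   L = j - i,

where T is the cumulative sum of the mean-centred values.  For a fixed
segment, U is a monotone transform of the pooled-variance two-sample
t statistic between arc and complement (the total sum of squares is
permutation-invariant), so the arc maximising U maximises t, and a
permutation test on U is identical to one on t.  A split is accepted when
its permutation p-value is below ``alpha``; the recursion then continues
on the resulting pieces.

The permutation test is exact: every shuffle asks whether ANY arc reaches
the observed maximum.  Arc lengths are scanned in order of increasing
denominator, pruned by two bounds (the range of the cumulative-sum bridge,
and L x the largest absolute deviation), and the scan exits on the first
exceedance — almost all work is skipped while the counted distribution is
exactly the full-scan one.  Testing stops early once enough exceedances
have accrued that the p-value can no longer fall below alpha.

After recursion, change-points whose adjacent segment means differ by less
than ``undo_sd`` x noise SD are removed greedily (weakest first); the noise
SD is the normalised MAD of lag-1 differences divided by sqrt(2), which is
robust to true copy-number steps.  Segmentation never crosses chromosome
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .tiling import WindowTiling

__all__ = [
    "SegmentationParams",
    "max_circular_split",
    "segment_values",
    "cbs_segment",
    "amplitude",
    "sweep_parameters",
    "noise_sd",
]

_MAD_SCALE = 1.4826


@dataclass
class SegmentationParams:
    """Break-point acceptance level, undo threshold and permutation budget.

    ``smooth`` applies the customary pre-segmentation outlier smoothing:
    isolated points are clipped to within ``smooth_cap_sd`` noise SDs of a
    running median, which stops single heavy-tailed windows (common at low
    read depth) from inflating the permutation null, while leaving runs of
    two or more concordant windows — real focal events — intact.
    """

    alpha: float = 0.03
    undo_sd: float = 3.0
    n_permutations: int = 10_000
    seed: int | None = None
    smooth: bool = True
    smooth_cap_sd: float = 4.0
    smooth_half_window: int = 2

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.undo_sd < 0:
            raise ValueError(f"undo_sd must be >= 0, got {self.undo_sd}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


@njit(cache=True)
def _best_split_kernel(T, denoms):
    """Full O(n^2) scan for the maximal arc statistic; leftmost tie-break."""
    n = T.size - 1
    best_u = -1.0
    best_i = 0
    best_j = 0
    for i in range(n):
        for j in range(i + 1, n + 1):
            L = j - i
            if L == n:
                continue
            u = abs(T[j] - T[i]) / denoms[L]
            if u > best_u:
                best_u = u
                best_i = i
                best_j = j
    return best_i, best_j, best_u


@njit(cache=True)
def _perm_pvalue_kernel(xc, b, nperm, limit, order, denoms, seed):
    """Exact permutation p-value of the max arc statistic via pruned scans.

    Returns count/nperm, or an early-stopped estimate >= alpha once
    ``limit`` exceedances have accrued (the split is then not accepted).
    """
    n = xc.size
    mmax = 0.0
    for k in range(n):
        a = abs(xc[k])
        if a > mmax:
            mmax = a
    np.random.seed(seed)
    T = np.empty(n + 1)
    count = 0
    for p in range(nperm):
        np.random.shuffle(xc)
        T[0] = 0.0
        tmin = 0.0
        tmax = 0.0
        for k in range(n):
            T[k + 1] = T[k] + xc[k]
            if T[k + 1] < tmin:
                tmin = T[k + 1]
            elif T[k + 1] > tmax:
                tmax = T[k + 1]
        R = tmax - tmin
        exceeded = False
        for t in range(order.size):
            L = order[t]
            thr = b * denoms[L]
            if R < thr:
                break  # denominators ascend along `order`: nothing later can exceed
            if L * mmax < thr:
                continue
            for i in range(n - L + 1):
                if abs(T[i + L] - T[i]) >= thr:
                    exceeded = True
                    break
            if exceeded:
                break
        if exceeded:
            count += 1
            if count >= limit:
                return count / (p + 1.0)
    return count / nperm


def _denominators(n: int) -> np.ndarray:
    L = np.arange(n + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        d = np.sqrt(L * (1.0 - L / n))
    d[0] = np.inf
    d[n] = np.inf
    return d


def max_circular_split(values: np.ndarray) -> tuple[int, int, float]:
    """Arc boundaries (i, j) maximising the circular statistic, plus its value.

    The arc is values[i:j]; ties resolve to the lexicographically smallest
    (i, j).  Requires len(values) >= 2.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    T = np.concatenate(([0.0], np.cumsum(x - x.mean())))
    i, j, u = _best_split_kernel(T, _denominators(n))
    return int(i), int(j), float(u)


def smooth_outliers(values: np.ndarray, cap_sd: float = 4.0,
                    half_window: int = 2) -> np.ndarray:
    """Clip isolated outliers to within cap_sd noise SDs of a running median.

    The running median spans ``2 * half_window + 1`` points, so a pair of
    adjacent extreme windows (a genuine focal event) is measured against
    its normal neighbourhood and clipped symmetrically — the pair survives
    as a pair — while lone spikes are tamed.  No-op when the noise SD is 0
    (noiseless input must not be distorted).
    """
    from scipy.ndimage import median_filter

    x = np.asarray(values, dtype=float)
    sd = noise_sd(x)
    if sd <= 0 or x.size < 2 * half_window + 1:
        return x
    m = median_filter(x, size=2 * half_window + 1, mode="nearest")
    return np.clip(x, m - cap_sd * sd, m + cap_sd * sd)


def noise_sd(values: np.ndarray) -> float:
    """Robust noise SD: normalised MAD of lag-1 differences / sqrt(2)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(_MAD_SCALE * mad / np.sqrt(2.0))


def _recurse(x: np.ndarray, s: int, e: int, params: SegmentationParams,
             root_seed: int, boundaries: list[int]) -> None:
    n = e - s
    if n < 2:
        return
    seg = x[s:e]
    i, j, u = max_circular_split(seg)
    if u <= 1e-12:
        return
    limit = max(int(np.ceil(params.alpha * params.n_permutations)), 1)
    xc = (seg - seg.mean()).copy()
    # seed keyed to the interval, not to recursion order, so the same test
    # sees the same permutations whatever alpha/undo_sd is in force
    seed = int(np.random.SeedSequence((root_seed, s, e)).generate_state(1)[0] & 0x7FFFFFFF)
    p = _perm_pvalue_kernel(xc, u, params.n_permutations, limit,
                            _scan_order(n), _denominators(n), seed)
    if p >= params.alpha:
        return
    cuts = [c for c in (s + i, s + j) if s < c < e]
    boundaries.extend(cuts)
    pieces = sorted({s, *cuts, e})
    for a, b in zip(pieces[:-1], pieces[1:]):
        _recurse(x, a, b, params, root_seed, boundaries)


def _scan_order(n: int) -> np.ndarray:
    d = _denominators(n)
    Ls = np.arange(1, n)
    return Ls[np.argsort(d[1:n], kind="stable")].astype(np.int64)


def _sd_undo(x: np.ndarray, boundaries: list[int], undo_sd: float) -> list[int]:
    """Greedily drop change-points with |mean difference| < undo_sd * noise SD."""
    if not boundaries or undo_sd <= 0:
        return sorted(boundaries)
    thresh = undo_sd * noise_sd(x)
    bounds = sorted(boundaries)
    while bounds:
        edges = [0, *bounds, x.size]
        means = [x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(bounds))]
        weakest = int(np.argmin(diffs))
        if diffs[weakest] >= thresh:
            break
        bounds.pop(weakest)
    return bounds


def segment_values(values: np.ndarray, params: SegmentationParams | None = None
                   ) -> list[tuple[int, int, float]]:
    """Segment one chromosome's finite log2 ratios.

    Returns (start, end, mean) triples, half-open on positions within
    ``values``, ordered and jointly covering the whole array.
    """
    params = params or SegmentationParams()
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite (drop missing windows first)")
    if x.size == 0:
        return []
    if x.size < 2:
        return [(0, x.size, float(x.mean()))]
    if params.smooth:
        x = smooth_outliers(x, params.smooth_cap_sd, params.smooth_half_window)
    root_seed = params.seed if params.seed is not None \
        else int(np.random.default_rng().integers(0, 2**31 - 1))
    boundaries: list[int] = []
    _recurse(x, 0, x.size, params, root_seed, boundaries)
    bounds = _sd_undo(x, boundaries, params.undo_sd)
    edges = [0, *bounds, x.size]
    return [(a, b, float(x[a:b].mean())) for a, b in zip(edges[:-1], edges[1:])]


def cbs_segment(log2_ratio: np.ndarray, tiling: WindowTiling,
                params: SegmentationParams | None = None,
                sample_id: str = "sample") -> pd.DataFrame:
    """Segment a genome-wide log2-ratio vector per chromosome.

    Missing (NaN) windows — blacklisted or undefined ratios — are dropped
    before segmentation.  Output columns: sample, chrom, start, end (bp,
    half-open, spanning the first to last retained window of the segment),
    first_window, last_window (global window indices, inclusive),
    n_windows (retained windows in the segment), seg_mean.
    """
    params = params or SegmentationParams()
    log2_ratio = np.asarray(log2_ratio, dtype=float)
    if log2_ratio.shape != (tiling.n_windows,):
        raise ValueError("log2_ratio not aligned to tiling")
    rows = []
    starts, ends = tiling.starts, tiling.ends
    # per-chromosome seeds drawn deterministically from the root seed
    root = np.random.default_rng(params.seed)
    for chrom, _ in tiling.chromosomes:
        sl = tiling.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        keep = np.isfinite(log2_ratio[sl])
        ridx = idx[keep]
        if ridx.size == 0:
            continue
        sub = SegmentationParams(params.alpha, params.undo_sd,
                                 params.n_permutations,
                                 int(root.integers(0, 2**31 - 1)))
        for a, b, mean in segment_values(log2_ratio[ridx], sub):
            first, last = int(ridx[a]), int(ridx[b - 1])
            rows.append({
                "sample": sample_id,
                "chrom": chrom,
                "start": int(starts[first]),
                "end": int(ends[last]),
                "first_window": first,
                "last_window": last,
                "n_windows": b - a,
                "seg_mean": mean,
            })
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "first_window", "last_window",
                                       "n_windows", "seg_mean"])


def amplitude(segment_mean: float, chromosome_log2: np.ndarray) -> float:
    """Segment amplitude relative to the chromosome baseline.

    Defined as the segment mean log2 minus the median log2 of all retained
    windows on that chromosome for the sample.
    """
    vals = np.asarray(chromosome_log2, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(segment_mean - np.median(vals))


def sweep_parameters(region_profiles: Mapping[str, np.ndarray],
                     alpha_grid: Sequence[float], sd_grid: Sequence[float],
                     reference_calls: Mapping[str, bool],
                     n_permutations: int = 1000, seed: int | None = None,
                     min_amplitude: float = 0.18) -> pd.DataFrame:
    """Segmentation parameter sweep scored against reference loss calls.

    Each profile (finite log2 ratios over the target region) is segmented
    at every (alpha, undo_sd) pair; a sample is "called" when any segment
    mean sits >= ``min_amplitude`` below the region median.  The grid of
    sensitivity / specificity / call rate is returned for inspection.
    """
    rows = []
    for alpha in alpha_grid:
        for sd in sd_grid:
            calls = {}
            for sample, vals in region_profiles.items():
                vals = np.asarray(vals, dtype=float)
                vals = vals[np.isfinite(vals)]
                segs = segment_values(vals, SegmentationParams(alpha, sd,
                                                               n_permutations, seed))
                base = np.median(vals)
                calls[sample] = any(m - base <= -min_amplitude for _, _, m in segs)
            tp = sum(calls[s] and reference_calls[s] for s in calls)
            fp = sum(calls[s] and not reference_calls[s] for s in calls)
            fn = sum((not calls[s]) and reference_calls[s] for s in calls)
            tn = sum((not calls[s]) and (not reference_calls[s]) for s in calls)
            rows.append({
                "alpha": alpha,
                "undo_sd": sd,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "call_rate": (tp + fp) / len(calls) if calls else np.nan,
            })
    return pd.DataFrame(rows)


def write_seg(segments: pd.DataFrame, path: str, header_meta: dict | None = None) -> None:
    """Write segments as a SEG-style TSV."""
    import json

    cols = ["sample", "chrom", "start", "end", "n_windows", "seg_mean"]
    with open(path, "w") as fh:
        fh.write(f"# cnvseq segments {json.dumps(header_meta or {}, sort_keys=True)}\n")
        segments[cols].to_csv(fh, sep="\t", index=False)
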