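"""GC/mappability bias correction and copy-number log2 ratios.

Window read counts carry smooth technical biases in GC content and
mappability.  Each chromosome is corrected independently with a robust
local quadratic regression (LOESS with Tukey-biweight reweighting):
the adjusted count is the raw count divided by the fitted bias curve and
rescaled so the per-chromosome median count is preserved.  Correction is
multiplicative, keeping counts non-negative.

A composite normal — the element-wise sum of the pooled normal samples'
raw counts, corrected the same way — serves as the denominator of the
per-window copy-number ratio.  Sample and composite are scaled to equal
totals over retained windows before taking log2, so a diploid genome sits
near log2 ratio 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "loess_fit",
    "loess_correct",
    "correct_sample",
    "CompositeNormal",
    "build_composite_normal",
    "cn_log2_ratio",
    "CNProfile",
]

MIN_INFORMATIVE_WINDOWS = 30


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3, degree: int = 2,
              robust_iters: int = 4, n_grid: int = 100) -> np.ndarray:
    """Robust LOESS fit of y on x, evaluated at every x.

    Local polynomial (default quadratic) with tricube distance weights over
    the ``span`` fraction of nearest neighbours, iteratively reweighted with
    Tukey's biweight on scaled residuals (re-descending M estimation).  The
    fit is evaluated on a quantile grid and linearly interpolated, which is
    accurate for the smooth bias curves targeted here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < degree + 2:
        raise ValueError("too few points for LOESS")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    grid_idx = np.unique(np.linspace(0, n - 1, min(n_grid, n)).round().astype(int))
    robust_w = np.ones(n)
    fitted_s = np.empty(n)
    for iteration in range(robust_iters + 1):
        grid_fit = np.empty(grid_idx.size)
        for gi, idx in enumerate(grid_idx):
            x0 = xs[idx]
            # k nearest neighbours in covariate distance (contiguous in xs)
            lo, hi = idx, idx + 1
            while hi - lo < k:
                if lo > 0 and (hi == n or x0 - xs[lo - 1] <= xs[hi] - x0):
                    lo -= 1
                else:
                    hi += 1
            xl, yl, wl = xs[lo:hi], ys[lo:hi], robust_w[lo:hi]
            h = max(np.abs(xl - x0).max(), 1e-12)
            w = _tricube((xl - x0) / h) * wl
            if w.sum() <= 0 or (w > 0).sum() <= degree:
                grid_fit[gi] = np.average(yl, weights=np.maximum(w, 1e-12))
                continue
            # weighted polynomial fit centred at x0
            X = np.vander(xl - x0, degree + 1, increasing=True)
            WX = X * w[:, None]
            beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yl, rcond=None)
            grid_fit[gi] = beta[0]
        fitted_s = np.interp(xs, xs[grid_idx], grid_fit)
        if iteration == robust_iters:
            break
        resid = ys - fitted_s
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)  # Tukey biweight on MAD-scaled residuals
        robust_w = np.clip(1.0 - u ** 2, 0.0, None) ** 2
    fitted = np.empty(n)
    fitted[order] = fitted_s
    return fitted


def loess_correct(counts: np.ndarray, covariate: np.ndarray,
                  chromosome_labels: Sequence[str], span: float = 0.3,
                  degree: int = 2, robust: bool = True) -> np.ndarray:
    """Remove a smooth covariate bias from counts, per chromosome.

    adjusted = count * reference / fitted, with the reference level chosen
    so the per-chromosome median adjusted count equals the median raw
    count.  Windows with a missing covariate pass through unadjusted;
    fitted values <= 0 flag the window missing (NaN).  Chromosomes with
    fewer than MIN_INFORMATIVE_WINDOWS informative windows pass through
    unadjusted with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    labels = np.asarray(chromosome_labels)
    adjusted = counts.astype(float).copy()
    iters = 4 if robust else 0
    for chrom in pd.unique(labels):
        sel = labels == chrom
        cov = covariate[sel]
        cnt = counts[sel]
        ok = np.isfinite(cov) & np.isfinite(cnt)
        if ok.sum() < MIN_INFORMATIVE_WINDOWS:
            warnings.warn(
                f"chromosome {chrom}: only {int(ok.sum())} informative windows; "
                "passed through unadjusted"
            )
            continue
        fitted = np.full(cnt.size, np.nan)
        fitted[ok] = loess_fit(cov[ok], cnt[ok], span=span, degree=degree,
                               robust_iters=iters)
        adj = cnt.copy()
        bad = ok & (fitted <= 0)
        good = ok & (fitted > 0)
        ratio = np.full(cnt.size, np.nan)
        ratio[good] = cnt[good] / fitted[good]
        med_raw = np.median(cnt[good])
        med_ratio = np.median(ratio[good])
        ref = med_raw / med_ratio if med_ratio > 0 else 1.0
        adj[good] = ratio[good] * ref
        adj[bad] = np.nan
        adjusted[sel] = adj
    return adjusted


def correct_sample(counts: np.ndarray, annotation: pd.DataFrame,
                   chromosome_labels: Sequence[str], span: float = 0.3) -> np.ndarray:
    """Bias-correct one sample: LOESS on GC first, then on mappability.

    The order is fixed (GC, then mappability).  Either covariate column may
    be absent or all-NaN, in which case that pass is skipped.
    """
    adjusted = np.asarray(counts, dtype=float)
    for col in ("gc", "mappability"):
        if col in annotation.columns and np.isfinite(annotation[col]).any():
            adjusted = loess_correct(adjusted, np.asarray(annotation[col], dtype=float),
                                     chromosome_labels, span=span)
    return adjusted


@dataclass
class CompositeNormal:
    """Pooled-normal reference: raw sum of normal count vectors + corrected form."""

    raw: np.ndarray
    adjusted: np.ndarray
    n_samples: int


def build_composite_normal(normal_count_vectors: Sequence[np.ndarray],
                           annotation: pd.DataFrame,
                           chromosome_labels: Sequence[str],
                           span: float = 0.3) -> CompositeNormal:
    """Sum the normal samples' raw counts and correct the sum like a sample."""
    vs = [np.asarray(v) for v in normal_count_vectors]
    if not vs:
        raise ValueError("no normal samples supplied")
    raw = np.sum(vs, axis=0)
    adjusted = correct_sample(raw, annotation, chromosome_labels, span=span)
    return CompositeNormal(raw=raw, adjusted=adjusted, n_samples=len(vs))


def cn_log2_ratio(sample_adjusted: np.ndarray, composite_adjusted: np.ndarray,
                  blacklist: np.ndarray | None = None,
                  pseudocount: float | None = None) -> np.ndarray:
    """Per-window log2 copy-number ratio of a sample against the composite.

    Both vectors are scaled to equal totals over retained (non-blacklisted,
    jointly finite) windows, then log2(sample/composite) per window.
    Windows that are blacklisted, have composite <= 0, or have sample
    count 0 (when no pseudocount is used) are NaN.  A pseudocount, when
    given, is added to both scaled vectors so homozygous-deletion windows
    stay defined.
    """
    s = np.asarray(sample_adjusted, dtype=float)
    c = np.asarray(composite_adjusted, dtype=float)
    if s.shape != c.shape:
        raise ValueError("sample and composite vectors are not aligned")
    retained = np.isfinite(s) & np.isfinite(c)
    if blacklist is not None:
        retained &= ~np.asarray(blacklist, dtype=bool)
    ts = s[retained].sum()
    tc = c[retained].sum()
    if ts <= 0 or tc <= 0:
        raise ValueError("non-positive total over retained windows")
    scale = tc / ts  # bring sample onto composite scale
    out = np.full(s.shape, np.nan)
    pc = 0.0 if pseudocount is None else float(pseudocount)
    num = s * scale + pc
    den = c + pc
    ok = retained & (c > 0) & (num > 0)
    out[ok] = np.log2(num[ok] / den[ok])
    return out


@dataclass
class CNProfile:
    """One sample's corrected counts and log2 ratios on a tiling."""

    sample_id: str
    adjusted_counts: np.ndarray
    log2_ratio: np.ndarray

    def __post_init__(self):
        self.adjusted_counts = np.asarray(self.adjusted_counts, dtype=float)
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if self.adjusted_counts.shape != self.log2_ratio.shape:
            raise ValueError("adjusted_counts and log2_ratio are not aligned")
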