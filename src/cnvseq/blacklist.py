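"""Window exclusion mask: external problem regions, signal-dropout rule, run propagation.

Some genomic regions yield spurious copy-number peaks (alignment
artefacts, gaps, low-complexity sequence).  Three rules build the mask:

* windows overlapping externally supplied problem regions;
* windows with zero reads in more than a threshold fraction of samples
  (strictly greater, default 5%);
* short runs (< 150 windows, strict) of retained windows flanked on both
  sides by blacklisted windows within a chromosome, applied to fixpoint.
  Runs touching a chromosome end are not flanked and are kept.

Rules only ever add windows to the mask (monotone).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .tiling import WindowTiling, normalize_chrom

__all__ = [
    "apply_external_regions",
    "zero_count_rule",
    "propagate_runs",
    "build_blacklist",
    "read_bed_regions",
    "mask_to_bed",
]

PROV_EXTERNAL = "external"
PROV_ZERO = "zero_rule"
PROV_RUN = "run_rule"


def read_bed_regions(path: str) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def apply_external_regions(tiling: WindowTiling,
                           regions: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Blacklist every window overlapping any region by >= 1 bp (half-open)."""
    mask = np.zeros(tiling.n_windows, dtype=bool)
    known = {normalize_chrom(c) for c, _ in tiling.chromosomes}
    for chrom, start, end in regions:
        if normalize_chrom(chrom) not in known or end <= start:
            continue
        sl = tiling.chrom_slice(chrom)
        starts, ends = tiling.starts[sl], tiling.ends[sl]
        hit = (starts < end) & (ends > start)
        mask[sl.start:sl.stop][hit] = True
    return mask


def zero_count_rule(counts: np.ndarray, threshold_fraction: float = 0.05) -> np.ndarray:
    """Blacklist windows with zero reads in > threshold_fraction of samples (strict)."""
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("counts must be 2-D with at least one sample")
    zero_frac = (counts == 0).mean(axis=0)
    return zero_frac > threshold_fraction


def propagate_runs(mask: np.ndarray, chromosome_labels: Sequence[str],
                   min_run: int = 150) -> np.ndarray:
    """Blacklist short retained runs flanked by blacklisted windows, to fixpoint.

    Within each chromosome, a maximal run of retained windows bounded on
    BOTH sides by blacklisted windows and shorter than ``min_run`` (strict)
    is blacklisted.  Runs touching a chromosome end are kept regardless of
    length.  Iterated until nothing changes.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    labels = np.asarray(chromosome_labels)
    if mask.shape != labels.shape:
        raise ValueError("mask and chromosome labels are not aligned")
    for chrom in pd.unique(labels):
        sel = np.flatnonzero(labels == chrom)
        m = mask[sel]
        while True:
            changed = False
            n = m.size
            i = 0
            while i < n:
                if m[i]:
                    i += 1
                    continue
                j = i
                while j < n and not m[j]:
                    j += 1
                flanked = i > 0 and j < n
                if flanked and (j - i) < min_run:
                    m[i:j] = True
                    changed = True
                i = j
            if not changed:
                break
        mask[sel] = m
    return mask


def build_blacklist(tiling: WindowTiling, counts: np.ndarray | None = None,
                    regions: Sequence[tuple[str, int, int]] = (),
                    threshold_fraction: float = 0.05,
                    min_run: int = 150) -> pd.DataFrame:
    """Compose the full mask; returns per-window flag plus provenance.

    External and zero-count rules are a union (order-free); run propagation
    is applied last.  Provenance records which rule first blacklisted each
    window ("external", "zero_rule", "run_rule", or "" if retained).
    """
    ext = apply_external_regions(tiling, regions)
    zero = (zero_count_rule(counts, threshold_fraction)
            if counts is not None and len(counts) else np.zeros(tiling.n_windows, bool))
    base = ext | zero
    final = propagate_runs(base, tiling.chrom_labels, min_run=min_run)
    provenance = np.where(ext, PROV_EXTERNAL,
                          np.where(zero, PROV_ZERO,
                                   np.where(final, PROV_RUN, "")))
    return pd.DataFrame({"blacklisted": final, "provenance": provenance})


def mask_to_bed(mask: np.ndarray, tiling: WindowTiling, path: str) -> None:
    """Write blacklisted spans as a merged BED file."""
    mask = np.asarray(mask, dtype=bool)
    lines = []
    labels = tiling.chrom_labels
    starts, ends = tiling.starts, tiling.ends
    i = 0
    n = mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1] and labels[j + 1] == labels[i] \
                and starts[j + 1] == ends[j]:
            j += 1
        lines.append(f"{labels[i]}\t{starts[i]}\t{ends[j]}")
        i = j + 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
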