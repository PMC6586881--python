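"""Per-window GC content and mappability from the reference sequence.

Read depth in shallow sequencing is biased by local base composition
(library-prep GC bias) and by how uniquely reads can be placed
(mappability).  Both covariates are computed per window here and removed
downstream by robust LOESS.

Mappability follows the gem-mappability convention: the score at a
position is the reciprocal of the number of genomic locations (both
strands) whose k-mer matches the k-mer starting there within a mismatch
budget.  The exhaustive all-pairs search used here is only intended for
desk-scale references; genome-scale tracks are read from a precomputed
BED-graph instead.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .tiling import WindowTiling, normalize_chrom

__all__ = [
    "gc_content",
    "window_gc",
    "position_mappability",
    "window_mappability",
    "read_mappability_track",
    "annotate_windows",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base codes: A=0 C=1 G=2 T=3, N (or other ambiguity) = -1
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#non-N bases), case-insensitive; NaN if all bases are N."""
    code = _encode(sequence)
    informative = code >= 0
    n_inf = int(informative.sum())
    if n_inf == 0:
        return float("nan")
    gc = int(((code == 1) | (code == 2)).sum())
    return gc / n_inf


def window_gc(fasta_path: str, tiling: WindowTiling) -> np.ndarray:
    """Per-window GC fraction from a FASTA; NaN for all-N windows."""
    out = np.full(tiling.n_windows, np.nan)
    with Fasta(fasta_path, as_raw=True, sequence_always_upper=True) as fa:
        names = {normalize_chrom(n): n for n in fa.keys()}
        for i, (chrom, length) in enumerate(tiling.chromosomes):
            key = names.get(normalize_chrom(chrom))
            if key is None:
                raise KeyError(f"chromosome {chrom!r} not in FASTA {fasta_path}")
            seq = str(fa[key][:])
            if len(seq) != length:
                raise ValueError(
                    f"FASTA length {len(seq)} != tiling length {length} for {chrom}"
                )
            sl = tiling.chrom_slice(chrom)
            starts = tiling.starts[sl]
            ends = tiling.ends[sl]
            for j, (s, e) in enumerate(zip(starts, ends)):
                out[sl.start + j] = gc_content(seq[s:e])
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def position_mappability(sequence: str, k: int = 35, mismatches: int = 1) -> np.ndarray:
    """Exhaustive per-position mappability of a single sequence.

    score[p] = 1 / (number of k-mer start locations, forward plus reverse
    strand, matching the k-mer at p with <= ``mismatches`` differences).
    Positions whose k-mer contains an N, and the trailing k-1 positions
    with no full k-mer, are NaN.  O(L^2 * k): desk-scale references only.
    """
    L = len(sequence)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    fwd = _encode(sequence)
    rev = _encode(_revcomp(sequence))
    n_kmers = L - k + 1
    # k-mer matrices via sliding windows
    fw = np.lib.stride_tricks.sliding_window_view(fwd, k)
    rv = np.lib.stride_tricks.sliding_window_view(rev, k)
    valid_f = (fw >= 0).all(axis=1)
    valid_r = (rv >= 0).all(axis=1)
    scores = np.full(L, np.nan)
    for p in range(n_kmers):
        if not valid_f[p]:
            continue
        q = fw[p]
        # N positions in candidates never match (codes differ from 0..3)
        d_f = (fw != q).sum(axis=1)
        d_r = (rv != q).sum(axis=1)
        hits = int((d_f[valid_f] <= mismatches).sum()) + int((d_r[valid_r] <= mismatches).sum())
        scores[p] = 1.0 / hits  # self-match guarantees hits >= 1
    return scores


def window_mappability(position_scores: np.ndarray, tiling: WindowTiling,
                       chrom: str | None = None) -> np.ndarray:
    """Median of defined per-position scores within each window.

    ``position_scores`` is a concatenated per-base array over the tiling's
    chromosomes (or one chromosome if ``chrom`` is given); a sliding k-mer
    score is attributed to the window of its start position.
    """
    if chrom is not None:
        sl = tiling.chrom_slice(chrom)
        starts, ends = tiling.starts[sl], tiling.ends[sl]
        base = starts[0]
        out = np.full(sl.stop - sl.start, np.nan)
        for j, (s, e) in enumerate(zip(starts, ends)):
            seg = position_scores[s - base:e - base]
            seg = seg[~np.isnan(seg)]
            if seg.size:
                out[j] = float(np.median(seg))
        return out
    # whole-genome: per-chromosome recursion over a concatenated array
    out = np.full(tiling.n_windows, np.nan)
    offset = 0
    for chrom_name, length in tiling.chromosomes:
        sl = tiling.chrom_slice(chrom_name)
        out[sl] = window_mappability(position_scores[offset:offset + length], tiling, chrom_name)
        offset += length
    return out


def read_mappability_track(path: str, tiling: WindowTiling) -> np.ndarray:
    """Project a BED-graph-style track (chrom, start, end, score) onto windows.

    Per-window score is the coverage-weighted median of overlapping interval
    scores; windows with no overlap are NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "score"])
    out = np.full(tiling.n_windows, np.nan)
    chrom_norm = df["chrom"].astype(str).map(normalize_chrom)
    for chrom, length in tiling.chromosomes:
        sub = df[chrom_norm == normalize_chrom(chrom)]
        if sub.empty:
            continue
        sl = tiling.chrom_slice(chrom)
        starts, ends = tiling.starts[sl], tiling.ends[sl]
        iv_s = sub["start"].to_numpy()
        iv_e = sub["end"].to_numpy()
        iv_v = sub["score"].to_numpy(dtype=float)
        order = np.argsort(iv_s)
        iv_s, iv_e, iv_v = iv_s[order], iv_e[order], iv_v[order]
        for j, (ws, we) in enumerate(zip(starts, ends)):
            lo = np.searchsorted(iv_e, ws, side="right")
            hi = np.searchsorted(iv_s, we, side="left")
            if lo >= hi:
                continue
            ov = np.minimum(iv_e[lo:hi], we) - np.maximum(iv_s[lo:hi], ws)
            keep = ov > 0
            if not keep.any():
                continue
            out[sl.start + j] = _weighted_median(iv_v[lo:hi][keep], ov[keep])
    return out


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order].astype(float)
    cw = np.cumsum(w)
    cut = 0.5 * cw[-1]
    i = int(np.searchsorted(cw, cut))
    if cw[i] == cut and i + 1 < len(v):  # midpoint between the straddling values
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def annotate_windows(fasta_path: str, tiling: WindowTiling,
                     k: int = 35, mismatches: int = 1,
                     mappability_track: str | None = None) -> pd.DataFrame:
    """GC + mappability annotation table for a tiling.

    Mappability comes from ``mappability_track`` when given, otherwise from
    the exhaustive in-package search over the FASTA.
    """
    gc = window_gc(fasta_path, tiling)
    if mappability_track is not None:
        mapp = read_mappability_track(mappability_track, tiling)
    else:
        with Fasta(fasta_path, as_raw=True, sequence_always_upper=True) as fa:
            names = {normalize_chrom(n): n for n in fa.keys()}
            pieces = []
            for chrom, _ in tiling.chromosomes:
                seq = str(fa[names[normalize_chrom(chrom)]][:])
                pieces.append(position_mappability(seq, k=k, mismatches=mismatches))
        mapp = window_mappability(np.concatenate(pieces), tiling)
    return pd.DataFrame({"gc": gc, "mappability": mapp})
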