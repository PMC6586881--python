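"""Fixed genome tiling and windowed read counting.

Shallow whole-genome copy-number analysis estimates DNA dosage from the
density of aligned reads in fixed, non-overlapping genomic windows.  This
module defines the window grid and turns filtered alignments into
per-window read counts.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "WindowTiling",
    "CountMatrix",
    "build_tiling",
    "assign_window",
    "read_midpoint",
    "count_alignments",
    "read_fai",
    "normalize_chrom",
]


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` so that ``chr9`` and ``9`` compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


class WindowTiling:
    """Non-overlapping fixed-size windows covering every chromosome.

    Windows are anchored at coordinate 0 of each chromosome; the terminal
    window is truncated to the chromosome end.  Window indices are global
    (running over chromosomes in the order given) and stable for a given
    (chromosome list, window size) pair.
    """

    def __init__(self, chromosomes: Sequence[tuple[str, int]], window_size: int):
        if window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {window_size}")
        chromosomes = [(str(c), int(l)) for c, l in chromosomes]
        if not chromosomes:
            raise ValueError("chromosome list is empty")
        for name, length in chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.window_size = int(window_size)
        self.chromosomes: list[tuple[str, int]] = chromosomes
        # windows per chromosome = ceil(length / size)
        counts = [-(-l // window_size) for _, l in chromosomes]
        self._n_per_chrom = np.asarray(counts, dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(self._n_per_chrom)])
        self._chrom_index = {normalize_chrom(name): i for i, (name, _) in enumerate(chromosomes)}
        if len(self._chrom_index) != len(chromosomes):
            raise ValueError("duplicate chromosome names after normalisation")

    # -- basic queries ---------------------------------------------------
    @property
    def n_windows(self) -> int:
        return int(self._offsets[-1])

    def chrom_slice(self, chrom: str) -> slice:
        i = self._chrom_of(chrom)
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def _chrom_of(self, chrom: str) -> int:
        key = normalize_chrom(chrom)
        if key not in self._chrom_index:
            raise KeyError(f"chromosome {chrom!r} not in tiling")
        return self._chrom_index[key]

    @property
    def chrom_labels(self) -> np.ndarray:
        """Per-window chromosome name (array of str)."""
        return np.repeat([c for c, _ in self.chromosomes], self._n_per_chrom)

    @property
    def starts(self) -> np.ndarray:
        parts = []
        for (name, length), n in zip(self.chromosomes, self._n_per_chrom):
            parts.append(np.arange(n, dtype=np.int64) * self.window_size)
        return np.concatenate(parts)

    @property
    def ends(self) -> np.ndarray:
        parts = []
        for (name, length), n in zip(self.chromosomes, self._n_per_chrom):
            e = (np.arange(n, dtype=np.int64) + 1) * self.window_size
            e[-1] = length
            parts.append(e)
        return np.concatenate(parts)

    def window(self, index: int) -> tuple[str, int, int]:
        """Return (chromosome, start, end) of a global window index."""
        if index < 0 or index >= self.n_windows:
            raise IndexError(f"window index {index} out of range")
        ci = int(np.searchsorted(self._offsets, index, side="right")) - 1
        name, length = self.chromosomes[ci]
        local = index - int(self._offsets[ci])
        start = local * self.window_size
        return name, start, min(start + self.window_size, length)

    def locate(self, chrom: str, position: int) -> int:
        """Global window index containing a 0-based position."""
        ci = self._chrom_of(chrom)
        name, length = self.chromosomes[ci]
        if position < 0 or position >= length:
            raise ValueError(f"position {position} outside {name} (length {length})")
        return int(self._offsets[ci]) + position // self.window_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom_labels,
                "start": self.starts,
                "end": self.ends,
                "window_index": np.arange(self.n_windows, dtype=np.int64),
            }
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WindowTiling)
            and self.window_size == other.window_size
            and self.chromosomes == other.chromosomes
        )

    def __repr__(self) -> str:
        return (
            f"WindowTiling({len(self.chromosomes)} chromosomes, "
            f"window_size={self.window_size}, n_windows={self.n_windows})"
        )


def build_tiling(chromosome_lengths: Sequence[tuple[str, int]] | Mapping[str, int],
                 window_size: int) -> WindowTiling:
    """Build the fixed window grid over a genome.

    ``chromosome_lengths`` is an ordered (name, length) sequence or mapping;
    ``window_size`` is the bin width in bp.
    """
    if isinstance(chromosome_lengths, Mapping):
        chromosome_lengths = list(chromosome_lengths.items())
    return WindowTiling(chromosome_lengths, window_size)


def read_fai(path: str) -> list[tuple[str, int]]:
    """Read chromosome names/lengths from a .fai-style TSV (first two columns)."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1])))
    if not out:
        raise ValueError(f"no chromosomes found in {path}")
    return out


def read_midpoint(aligned_start: int, aligned_end: int) -> int:
    """Midpoint of an aligned (clip-excluded) span, left-of-centre for even spans."""
    if aligned_start >= aligned_end:
        raise ValueError("aligned_start must be < aligned_end")
    return (aligned_start + aligned_end - 1) // 2


def assign_window(chrom: str, aligned_start: int, aligned_end: int,
                  tiling: WindowTiling) -> int:
    """Window index of an alignment, by the midpoint of its aligned span.

    Clipped bases must already be excluded from the span (pysam reference
    coordinates do this).  Each usable record maps to exactly one window.
    """
    return tiling.locate(chrom, read_midpoint(aligned_start, aligned_end))


def _keep_record(rec: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
        or rec.is_qcfail
        or rec.mapping_quality < min_mapq
    )


def count_alignments(alignment_file: str, tiling: WindowTiling,
                     min_mapq: int = 20) -> np.ndarray:
    """Count filtered alignments per window.

    Records that are unmapped, secondary, supplementary, duplicate, QC-fail
    or below ``min_mapq`` are excluded; every surviving record increments
    exactly one window (by aligned-span midpoint), so the vector sums to the
    number of surviving records.  Reads on chromosomes absent from the
    tiling raise an error rather than being silently dropped.
    """
    counts = np.zeros(tiling.n_windows, dtype=np.int64)
    unknown: set[str] = set()
    with pysam.AlignmentFile(alignment_file, check_sq=False) as fh:
        for rec in fh:
            if not _keep_record(rec, min_mapq):
                continue
            chrom = rec.reference_name
            try:
                idx = assign_window(chrom, rec.reference_start, rec.reference_end, tiling)
            except KeyError:
                unknown.add(chrom)
                continue
            counts[idx] += 1
    if unknown:
        raise ValueError(
            "alignments on chromosomes absent from the tiling: "
            + ", ".join(sorted(unknown))
        )
    return counts


@dataclass
class CountMatrix:
    """samples x windows read counts plus per-window annotation.

    ``counts`` has shape (n_samples, n_windows).  Annotation columns
    (``gc``, ``mappability``, ``blacklisted``) are filled in by the
    annotate/blacklist stages; missing values are NaN.
    """

    tiling: WindowTiling
    sample_ids: list[str]
    counts: np.ndarray
    annotation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x windows)")
        if self.counts.shape != (len(self.sample_ids), self.tiling.n_windows):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.tiling.n_windows} windows"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.annotation.empty:
            self.annotation = pd.DataFrame(index=np.arange(self.tiling.n_windows))

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    # -- TSV round trip --------------------------------------------------
    _ANNOT_COLS = ("gc", "mappability", "blacklisted")

    def to_tsv(self, path: str, header_meta: dict | None = None) -> None:
        df = self.tiling.to_frame()
        for col in self._ANNOT_COLS:
            if col in self.annotation.columns:
                df[col] = np.asarray(self.annotation[col])
        for sid, row in zip(self.sample_ids, self.counts):
            df[sid] = row
        with open(path, "w") as fh:
            meta = dict(header_meta or {})
            meta.setdefault("window_size", self.tiling.window_size)
            fh.write(f"# cnvseq counts {json.dumps(meta, sort_keys=True)}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "CountMatrix":
        with open(path) as fh:
            text = fh.read()
        body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
        df = pd.read_csv(io.StringIO(body), sep="\t")
        required = {"chrom", "start", "end", "window_index"}
        if not required.issubset(df.columns):
            raise ValueError(f"counts TSV missing columns {required - set(df.columns)}")
        df = df.sort_values("window_index").reset_index(drop=True)
        # reconstruct tiling from per-chromosome maxima
        chroms: list[tuple[str, int]] = []
        for chrom in df["chrom"].astype(str).unique():
            sub = df[df["chrom"].astype(str) == chrom]
            chroms.append((chrom, int(sub["end"].max())))
        wsize = int((df["end"] - df["start"]).max())
        tiling = build_tiling(chroms, wsize)
        if tiling.n_windows != len(df):
            raise ValueError("counts TSV does not describe a contiguous tiling")
        annot_cols = [c for c in cls._ANNOT_COLS if c in df.columns]
        sample_cols = [
            c for c in df.columns
            if c not in {"chrom", "start", "end", "window_index", *annot_cols}
        ]
        counts = df[sample_cols].to_numpy(dtype=np.int64).T if sample_cols else \
            np.zeros((0, tiling.n_windows), dtype=np.int64)
        annotation = df[annot_cols].copy() if annot_cols else pd.DataFrame()
        return cls(tiling, list(sample_cols), counts, annotation)
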