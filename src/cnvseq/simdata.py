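"""Synthetic references, cohorts and alignment fixtures with ground truth.

The generator emulates the statistical structure the pipeline assumes:
per-window read counts that are negative-binomially dispersed around
depth x copy-ratio, modulated by a smooth GC bias (unimodal, peaking near
GC 0.45, the usual library-prep shape) and by mappability; a pooled-normal
cohort; focal (2-window) to multi-Mb deletions and amplifications; and a
biallelic germline deletion segregating under Hardy-Weinberg proportions.
Every generator is driven by an explicit seed and emits a truth manifest
sufficient to score the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .tiling import CountMatrix, WindowTiling, build_tiling

__all__ = [
    "CNEvent",
    "GermlineDeletionSpec",
    "GenomeSpec",
    "CohortSpec",
    "SimConfig",
    "gc_bias",
    "simulate_reference",
    "simulate_counts",
    "simulate_germline_cohort",
    "write_fixture_alignments",
    "nb_counts",
]


@dataclass(frozen=True)
class CNEvent:
    """A somatic copy-number event: windows overlapping [start, end) get copy_ratio."""

    chrom: str
    start: int
    end: int
    copy_ratio: float

    def __post_init__(self):
        if self.copy_ratio < 0:
            raise ValueError("copy_ratio must be >= 0")
        if self.end <= self.start:
            raise ValueError("empty event span")


@dataclass(frozen=True)
class GermlineDeletionSpec:
    """A biallelic deletion polymorphism; genotypes drawn under Hardy-Weinberg."""

    chrom: str
    start: int
    end: int
    allele_frequency: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele frequency must be in [0, 1]")


@dataclass
class GenomeSpec:
    """Synthetic genome: chromosome lengths, GC landscape, duplicated blocks.

    GC varies sinusoidally around ``gc_mean`` with the given amplitude and
    wavelength (bp); each duplication copies ``length`` bases from
    ``src_start`` to ``dest_start`` on the same chromosome, creating a
    mappability < 1 region.
    """

    chromosomes: Sequence[tuple[str, int]] = (("chr1", 1_000_000),)
    gc_mean: float = 0.45
    gc_amplitude: float = 0.10
    gc_wavelength: float = 200_000.0
    duplications: Sequence[tuple[str, int, int, int]] = ()  # (chrom, src_start, length, dest_start)


@dataclass
class CohortSpec:
    """Cohort shape and noise: sample counts, depth per window, NB dispersion.

    ``dispersion`` is the negative-binomial excess parameter phi in
    var = mu + phi mu^2 (0 gives Poisson); the 0.05 default emulates the
    overdispersion of degraded-DNA libraries.
    """

    n_tumours: int = 10
    n_normals: int = 7
    depth_per_window: float = 100.0
    dispersion: float = 0.05


@dataclass
class SimConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    window_size: int = 10_000
    events: Mapping[str, Sequence[CNEvent]] | Sequence[CNEvent] = ()
    germline: GermlineDeletionSpec | None = None
    gc_bias_strength: float = 2.0
    mappability_exponent: float = 1.0
    seed: int = 0


def gc_bias(gc: np.ndarray, strength: float = 2.0, peak: float = 0.45) -> np.ndarray:
    """Unimodal quadratic depth bias in GC, peaking at ``peak``; floor 0.1."""
    return np.maximum(0.1, 1.0 - strength * (np.asarray(gc, dtype=float) - peak) ** 2)


def nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _gc_landscape(spec: GenomeSpec, positions: np.ndarray,
                  phase: float = 0.0) -> np.ndarray:
    g = spec.gc_mean + spec.gc_amplitude * np.sin(
        2 * np.pi * positions / spec.gc_wavelength + phase)
    return np.clip(g, 0.05, 0.95)


def simulate_reference(spec: GenomeSpec, seed: int = 0) -> tuple[dict[str, str], pd.DataFrame]:
    """Random sequences with the spec's GC landscape and exact duplications.

    Returns (sequences, truth) where truth has per-chromosome-position GC
    targets summarised per kilobase.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    truth_rows = []
    bases_at = np.array(list("ATGC"))  # AT = indices 0,1; GC = 2,3
    for chrom, length in spec.chromosomes:
        pos = np.arange(length)
        g = _gc_landscape(spec, pos)
        is_gc = rng.random(length) < g
        pick = rng.integers(0, 2, size=length)
        codes = np.where(is_gc, 2 + pick, pick)
        seq = np.array(bases_at)[codes]
        seqs[chrom] = "".join(seq)
        truth_rows.append(pd.DataFrame({
            "chrom": chrom,
            "kb": np.arange(length // 1000),
            "gc_target": [g[i * 1000:(i + 1) * 1000].mean() for i in range(length // 1000)],
        }))
    for chrom, src, length, dest in spec.duplications:
        s = seqs[chrom]
        block = s[src:src + length]
        seqs[chrom] = s[:dest] + block + s[dest + length:]
    return seqs, pd.concat(truth_rows, ignore_index=True)


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _copy_ratio_vector(tiling: WindowTiling, events: Sequence[CNEvent]) -> np.ndarray:
    ratio = np.ones(tiling.n_windows)
    for ev in events:
        sl = tiling.chrom_slice(ev.chrom)
        ws, we = tiling.starts[sl], tiling.ends[sl]
        hit = (ws < ev.end) & (we > ev.start)
        ratio[sl.start:sl.stop][hit] = ev.copy_ratio
    return ratio


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, dict]:
    """Simulate a cohort count matrix plus a truth manifest.

    Window mean = depth x copy_ratio x gc_bias(gc_w) x mappability^e, with
    negative-binomial noise.  Tumour samples carry the configured events;
    normal samples are flat except for the germline deletion genotype,
    which all samples draw under Hardy-Weinberg at the spec's allele
    frequency.  Truth manifest: per-sample copy-ratio matrix, germline
    genotypes, GC and mappability used.
    """
    rng = np.random.default_rng(config.seed)
    tiling = build_tiling(list(config.genome.chromosomes), config.window_size)
    mid = (tiling.starts + tiling.ends) / 2.0
    phase = rng.uniform(0, 2 * np.pi)
    gc = np.empty(tiling.n_windows)
    for chrom, _ in config.genome.chromosomes:
        sl = tiling.chrom_slice(chrom)
        gc[sl] = _gc_landscape(config.genome, mid[sl], phase)
    mapp = np.ones(tiling.n_windows)
    for chrom, src, length, dest in config.genome.duplications:
        for s in (src, dest):
            sl = tiling.chrom_slice(chrom)
            ws, we = tiling.starts[sl], tiling.ends[sl]
            hit = (ws < s + length) & (we > s)
            mapp[sl.start:sl.stop][hit] = 0.5

    tumour_ids = [f"tumour{i + 1:02d}" for i in range(config.cohort.n_tumours)]
    normal_ids = [f"normal{i + 1:02d}" for i in range(config.cohort.n_normals)]
    if isinstance(config.events, Mapping):
        events_by_sample = {s: list(config.events.get(s, ())) for s in tumour_ids}
    else:
        events_by_sample = {s: list(config.events) for s in tumour_ids}

    genotypes = pd.Series(0, index=tumour_ids + normal_ids, name="n_deleted_alleles")
    germline_ratio = np.ones(tiling.n_windows)
    if config.germline is not None:
        q = config.germline.allele_frequency
        genotypes[:] = rng.binomial(2, q, size=genotypes.size)
        sl = tiling.chrom_slice(config.germline.chrom)
        ws, we = tiling.starts[sl], tiling.ends[sl]
        hit = np.zeros(tiling.n_windows, bool)
        hit[sl.start:sl.stop] = (ws < config.germline.end) & (we > config.germline.start)

    bias = gc_bias(gc, config.gc_bias_strength) * mapp ** config.mappability_exponent
    depth = config.cohort.depth_per_window
    counts = np.zeros((len(tumour_ids) + len(normal_ids), tiling.n_windows), dtype=np.int64)
    ratio_truth = np.ones_like(counts, dtype=float)
    for si, sample in enumerate(tumour_ids + normal_ids):
        ratio = (_copy_ratio_vector(tiling, events_by_sample[sample])
                 if sample in events_by_sample else np.ones(tiling.n_windows))
        if config.germline is not None:
            g = int(genotypes[sample])
            ratio = ratio.copy()
            ratio[hit] *= (2 - g) / 2.0
        ratio_truth[si] = ratio
        counts[si] = nb_counts(depth * ratio * bias, config.cohort.dispersion, rng)

    annotation = pd.DataFrame({"gc": gc, "mappability": mapp})
    cm = CountMatrix(tiling, tumour_ids + normal_ids, counts, annotation)
    truth = {
        "copy_ratio": pd.DataFrame(ratio_truth, index=tumour_ids + normal_ids),
        "genotypes": genotypes,
        "events_by_sample": events_by_sample,
        "gc": gc,
        "mappability": mapp,
        "normal_ids": normal_ids,
        "tumour_ids": tumour_ids,
    }
    return cm, truth


def simulate_germline_cohort(n_samples: int = 300, allele_frequency: float = 0.4,
                             depth: float = 100.0, dispersion: float = 0.05,
                             n_locus: int = 2, n_flank: int = 10,
                             window_size: int = 10_000, seed: int = 0
                             ) -> tuple[pd.DataFrame, pd.Series, "np.ndarray"]:
    """Cohort of locus+flank corrected counts segregating a germline deletion.

    Returns (adjusted-count table samples x windows, true genotypes,
    locus window indices).  The locus occupies ``n_locus`` central windows
    with copy ratio {1, 0.5, 0} by genotype; flanks are diploid.
    """
    rng = np.random.default_rng(seed)
    n_windows = n_locus + 2 * n_flank
    locus_idx = np.arange(n_flank, n_flank + n_locus)
    genotypes = pd.Series(rng.binomial(2, allele_frequency, size=n_samples),
                          index=[f"s{i + 1:03d}" for i in range(n_samples)],
                          name="n_deleted_alleles")
    ratio = np.ones((n_samples, n_windows))
    for si, g in enumerate(genotypes):
        ratio[si, locus_idx] = (2 - g) / 2.0
    counts = nb_counts(depth * ratio, dispersion, rng)
    table = pd.DataFrame(counts.T, columns=genotypes.index)
    return table, genotypes, locus_idx


def write_fixture_alignments(window_counts: np.ndarray, tiling: WindowTiling,
                             path: str, read_length: int = 100, mapq: int = 60,
                             decoys: bool = False, seed: int = 0) -> None:
    """Write a SAM file whose filtered window counts reproduce ``window_counts``.

    Reads are placed so their aligned-span midpoints fall in the intended
    window.  With ``decoys``, extra records exercising every exclusion
    filter (unmapped, secondary, supplementary, duplicate, QC-fail, low
    MAPQ) are interleaved; they must not change the counts.
    """
    window_counts = np.asarray(window_counts)
    if window_counts.shape != (tiling.n_windows,):
        raise ValueError("window_counts not aligned to tiling")
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in tiling.chromosomes],
    })
    ref_ids = {name: i for i, (name, _) in enumerate(tiling.chromosomes)}
    half = (read_length - 1) // 2

    def _record(chrom, start, name, flag=0, q=mapq):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = flag
        a.reference_id = ref_ids[chrom]
        a.reference_start = start
        a.mapping_quality = q
        a.cigarstring = f"{read_length}M"
        a.query_sequence = "A" * read_length
        a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
        return a

    with pysam.AlignmentFile(path, "w", header=header) as out:
        serial = 0
        for w in range(tiling.n_windows):
            c = int(window_counts[w])
            if c == 0:
                continue
            chrom, ws, we = tiling.window(w)
            chrom_len = dict(tiling.chromosomes)[chrom]
            mids = ws + rng.integers(0, we - ws, size=c)
            for m in mids:
                start = int(np.clip(m - half, 0, chrom_len - read_length))
                # re-centre if clamping moved the midpoint out of the window
                mid = start + half
                if mid < ws:
                    start += ws - mid
                elif mid >= we:
                    start -= mid - (we - 1)
                serial += 1
                out.write(_record(chrom, start, f"read{serial}"))
        if decoys:
            chrom, ws, we = tiling.window(0)
            mid0 = ws + (we - ws) // 2
            start0 = max(mid0 - half, 0)
            flags = {"secondary": 0x100, "supplementary": 0x800,
                     "duplicate": 0x400, "qcfail": 0x200}
            for name, flag in flags.items():
                out.write(_record(chrom, start0, f"decoy_{name}", flag=flag))
            out.write(_record(chrom, start0, "decoy_lowmapq", q=5))
            un = _record(chrom, start0, "decoy_unmapped", flag=0x4)
            un.reference_id = -1
            un.reference_start = -1
            un.cigarstring = None
            un.mapping_quality = 0
            out.write(un)
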