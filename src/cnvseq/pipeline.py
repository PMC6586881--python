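"""End-to-end orchestration: counts -> annotate -> normalize -> blacklist ->
segment -> call, with one validated config and per-stage provenance.

The pipeline consumes a CountMatrix (from alignments, a TSV, or the
simulator), masks unreliable windows, corrects GC/mappability bias,
expresses every sample against the corrected composite normal, segments
the log2 ratios and classifies the segments.  All randomness flows from
one root seed, split deterministically per stage and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import blacklist as bl
from .calls import CNCall, DEFAULT_MIN_AMPLITUDE, GeneRegion, call_segments
from .normalize import (CNProfile, build_composite_normal, cn_log2_ratio,
                        correct_sample)
from .segment import SegmentationParams, cbs_segment
from .tiling import CountMatrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with their working defaults.

    window_size 10 kb and min_mapq 20 govern counting; mappability k=35
    with 1 mismatch governs annotation; LOESS span 0.3; the blacklist uses
    the >5% zero-sample rule and <150-window run rule; segmentation runs
    CBS at alpha 0.03 with SD-undo 3; calls use the 0.18 minimum
    chromosome-relative amplitude.
    """

    window_size: int = 10_000
    min_mapq: int = 20
    mappability_k: int = 35
    mappability_mismatches: int = 1
    loess_span: float = 0.3
    zero_fraction: float = 0.05
    min_run: int = 150
    alpha: float = 0.03
    undo_sd: float = 3.0
    n_permutations: int = 10_000
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE
    pseudocount: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.window_size < 1:
            raise ValueError("window_size must be positive")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must be in [0, 1]")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    blacklist: pd.DataFrame
    profiles: dict[str, CNProfile]
    composite_adjusted: np.ndarray
    segments: pd.DataFrame
    calls: dict[str, list[CNCall]]
    report: dict = field(default_factory=dict)


def run_pipeline(cm: CountMatrix, normal_ids: Sequence[str],
                 config: PipelineConfig | None = None,
                 external_regions: Sequence[tuple[str, int, int]] = (),
                 genes: Sequence[GeneRegion] = (),
                 samples: Sequence[str] | None = None) -> PipelineResult:
    """Run normalisation, blacklisting, segmentation and calling on a cohort.

    ``normal_ids`` name the samples pooled into the composite normal;
    ``samples`` (default: all non-normal samples) are profiled against it.
    """
    config = config or PipelineConfig()
    missing = [s for s in normal_ids if s not in cm.sample_ids]
    if missing:
        raise ValueError(f"normal samples not in count matrix: {missing}")
    tumours = list(samples) if samples is not None else \
        [s for s in cm.sample_ids if s not in set(normal_ids)]

    labels = cm.tiling.chrom_labels
    black = bl.build_blacklist(cm.tiling, cm.counts, external_regions,
                               threshold_fraction=config.zero_fraction,
                               min_run=config.min_run)
    mask = black["blacklisted"].to_numpy()

    normals = [cm.sample(s) for s in normal_ids]
    composite = build_composite_normal(normals, cm.annotation, labels,
                                       span=config.loess_span)

    root = np.random.default_rng(config.seed)
    profiles: dict[str, CNProfile] = {}
    seg_frames = []
    calls: dict[str, list[CNCall]] = {}
    for sample in tumours:
        adj = correct_sample(cm.sample(sample), cm.annotation, labels,
                             span=config.loess_span)
        log2 = cn_log2_ratio(adj, composite.adjusted, blacklist=mask,
                             pseudocount=config.pseudocount)
        profiles[sample] = CNProfile(sample, adj, log2)
        params = SegmentationParams(config.alpha, config.undo_sd,
                                    config.n_permutations,
                                    int(root.integers(0, 2**31 - 1)))
        segs = cbs_segment(log2, cm.tiling, params, sample_id=sample)
        seg_frames.append(segs)
        calls[sample] = call_segments(segs, log2, cm.tiling, genes,
                                      min_amplitude=config.min_amplitude,
                                      sample_id=sample)
    segments = pd.concat(seg_frames, ignore_index=True) if seg_frames \
        else pd.DataFrame()
    report = {
        "config": config.to_dict(),
        "n_windows": cm.tiling.n_windows,
        "n_blacklisted": int(mask.sum()),
        "n_samples": len(tumours),
        "n_normals": len(normal_ids),
        "n_segments": int(len(segments)),
        "counts_per_sample": {s: int(cm.sample(s).sum()) for s in cm.sample_ids},
    }
    return PipelineResult(config, black, profiles, composite.adjusted,
                          segments, calls, report)
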