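"""Classify segments into copy-number events and region-level patterns.

A segment becomes a loss or gain call when its amplitude — the segment
mean log2 ratio minus the sample's chromosome median — clears a minimum
magnitude; its size is the genomic span in nucleotides.  Within a target
region (e.g. the 9p21 tumour-suppressor cluster around CDKN2A), per-sample
call patterns are classified into a small taxonomy: single loss of the
anchor gene, double loss (two disjoint losses both hitting the gene),
loss plus an extra loss elsewhere in the region, a focal (<= 2 window)
gain over the gene, a loss in the region sparing the gene's coding span,
or no event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segment import amplitude
from .tiling import WindowTiling, normalize_chrom

__all__ = [
    "GeneRegion",
    "CNCall",
    "call_segments",
    "classify_region_pattern",
    "summarize_cohort",
    "DEFAULT_MIN_AMPLITUDE",
]

# Smallest loss amplitude the pipeline treats as a call; guards against
# hairline segments whose amplitude is indistinguishable from baseline.
DEFAULT_MIN_AMPLITUDE = 0.18


@dataclass(frozen=True)
class GeneRegion:
    """A gene span as printed in browser style (1-based, inclusive)."""

    name: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")

    @property
    def half_open(self) -> tuple[int, int]:
        """(start, end) as 0-based half-open."""
        return self.start - 1, self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Half-open overlap against a 0-based half-open interval."""
        if normalize_chrom(chrom) != normalize_chrom(self.chromosome):
            return False
        s, e = self.half_open
        return start < e and s < end


# Printed coordinates of the recurrently altered melanoma loci (GRCh38).
MELANOMA_GENES = {
    "CDKN2A": GeneRegion("CDKN2A", "chr9", 21_967_753, 21_995_301),
    "MTAP": GeneRegion("MTAP", "chr9", 21_802_636, 21_865_971),
    "CDKN2B": GeneRegion("CDKN2B", "chr9", 22_002_903, 22_009_363),
    "NOTCH2": GeneRegion("NOTCH2", "chr1", 119_911_553, 120_069_626),
    "PTEN": GeneRegion("PTEN", "chr10", 87_863_113, 87_971_930),
    "CDK4": GeneRegion("CDK4", "chr12", 57_747_727, 57_756_013),
    "MDM2": GeneRegion("MDM2", "chr12", 68_808_176, 68_850_686),
    "KIT": GeneRegion("KIT", "chr4", 54_657_918, 54_740_715),
}


@dataclass
class CNCall:
    """A classified copy-number event for one segment of one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_windows: int
    direction: str  # "loss" | "gain" | "none"
    size_bp: int
    amplitude: float
    overlapped_genes: tuple[str, ...] = ()


def call_segments(segments: pd.DataFrame, log2_ratio: np.ndarray,
                  tiling: WindowTiling,
                  genes: Iterable[GeneRegion] = (),
                  min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
                  sample_id: str | None = None) -> list[CNCall]:
    """Turn one sample's segments into direction/size/amplitude calls.

    ``log2_ratio`` is the sample's per-window vector (used for chromosome
    medians); amplitude is chromosome-relative, so a whole-chromosome
    segment has amplitude 0 and direction "none" by construction.
    """
    genes = list(genes)
    calls: list[CNCall] = []
    for _, row in segments.iterrows():
        chrom = row["chrom"]
        sl = tiling.chrom_slice(chrom)
        amp = amplitude(row["seg_mean"], log2_ratio[sl])
        if np.isfinite(amp) and abs(amp) >= min_amplitude:
            direction = "loss" if amp < 0 else "gain"
        else:
            direction = "none"
        start, end = int(row["start"]), int(row["end"])
        hit = tuple(g.name for g in genes if g.overlaps(chrom, start, end))
        calls.append(CNCall(
            sample_id=sample_id or str(row.get("sample", "sample")),
            chrom=chrom, start=start, end=end,
            n_windows=int(row["n_windows"]),
            direction=direction, size_bp=end - start,
            amplitude=float(amp), overlapped_genes=hit,
        ))
    return calls


PATTERN_CLASSES = ("single_loss", "double_loss", "loss_plus_extra",
                   "focal_gain", "non_coding_loss", "none")


def classify_region_pattern(calls_for_sample: Sequence[CNCall],
                            anchor: GeneRegion,
                            region: tuple[str, int, int],
                            coding_spans: Sequence[tuple[int, int]] | None = None,
                            max_gain_windows: int = 2) -> str:
    """Assign one pattern class to a sample within a target region.

    ``region`` is (chrom, start, end), 0-based half-open.  ``coding_spans``
    optionally refines the anchor gene's coding extent (0-based half-open
    intervals); by default the printed gene span stands in for its exons.
    Every sample maps to exactly one class.
    """
    chrom, rstart, rend = region
    if coding_spans is None:
        coding_spans = [anchor.half_open]
    in_region = [
        c for c in calls_for_sample
        if normalize_chrom(c.chrom) == normalize_chrom(chrom)
        and c.start < rend and rstart < c.end
    ]
    losses = [c for c in in_region if c.direction == "loss"]
    gains = [c for c in in_region if c.direction == "gain"]

    def _hits_coding(c: CNCall) -> bool:
        return any(c.start < ce and cs < c.end for cs, ce in coding_spans)

    anchor_losses = [c for c in losses if _hits_coding(c)]
    other_losses = [c for c in losses if not _hits_coding(c)]
    if len(anchor_losses) >= 2:
        return "double_loss"
    if len(anchor_losses) == 1 and other_losses:
        return "loss_plus_extra"
    if len(anchor_losses) == 1:
        return "single_loss"
    if any(g.n_windows <= max_gain_windows
           and anchor.overlaps(g.chrom, g.start, g.end) for g in gains):
        return "focal_gain"
    if losses:
        return "non_coding_loss"
    return "none"


def summarize_cohort(calls_by_sample: Mapping[str, Sequence[CNCall]],
                     anchor: GeneRegion,
                     region: tuple[str, int, int],
                     coding_spans: Sequence[tuple[int, int]] | None = None) -> dict:
    """Cohort summary for one region: pattern counts plus loss size/amplitude stats."""
    patterns = {
        sample: classify_region_pattern(calls, anchor, region, coding_spans)
        for sample, calls in calls_by_sample.items()
    }
    counts = {cls: 0 for cls in PATTERN_CLASSES}
    for cls in patterns.values():
        counts[cls] += 1
    chrom, rstart, rend = region
    loss_sizes, loss_amps = [], []
    for calls in calls_by_sample.values():
        for c in calls:
            if (c.direction == "loss"
                    and normalize_chrom(c.chrom) == normalize_chrom(chrom)
                    and c.start < rend and rstart < c.end):
                loss_sizes.append(c.size_bp)
                loss_amps.append(c.amplitude)

    def _stats(v):
        if not v:
            return {"n": 0, "median": np.nan, "min": np.nan, "max": np.nan, "sd": np.nan}
        a = np.asarray(v, dtype=float)
        return {"n": a.size, "median": float(np.median(a)),
                "min": float(a.min()), "max": float(a.max()),
                "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0}

    return {
        "n_samples": len(calls_by_sample),
        "pattern_counts": counts,
        "patterns": patterns,
        "loss_size_bp": _stats(loss_sizes),
        "loss_amplitude": _stats(loss_amps),
    }


def calls_to_frame(calls: Iterable[CNCall]) -> pd.DataFrame:
    rows = [{
        "sample": c.sample_id, "chrom": c.chrom, "start": c.start, "end": c.end,
        "direction": c.direction, "size_bp": c.size_bp,
        "amplitude": c.amplitude, "genes": ",".join(c.overlapped_genes),
    } for c in calls]
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "direction", "size_bp", "amplitude", "genes"])
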