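"""Stage 2: RNA polymerase II ChIP-seq evidence filtering.

Active antisense transcription should leave POLR2A footprints at or just
upstream of the antisense unit across many ChIP-seq samples.  For each
candidate locus we count the samples with at least one narrowPeak
overlapping the locus blocks or the strand-aware upstream promoter window.
Background loci (no antisense enrichment) give an empirical null for that
count; candidates at least one interquartile range above the background
median (count >= median + IQR) pass the filter.

Quantiles use numpy's linear interpolation between order statistics; the
IQR convention matters and is documented here.  A degenerate null
(IQR = 0) passes everything at or above the median and is flagged loudly
rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from iris.genomic_io import PeakSet, str_to_blocks

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_BP = 2000


@dataclass
class ChipNull:
    """Background distribution of supporting-sample counts."""

    background_counts: np.ndarray = field(repr=False)
    median: float = 0.0
    iqr: float = 0.0
    threshold: float = 0.0

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "ChipNull":
        counts = np.asarray(counts)
        if counts.size == 0:
            raise ValueError("background counts must be nonempty")
        q1, med, q3 = np.percentile(counts, [25, 50, 75])  # linear interpolation
        iqr = float(q3 - q1)
        null = cls(
            background_counts=counts,
            median=float(med),
            iqr=iqr,
            threshold=float(med) + iqr,
        )
        if iqr == 0:
            logger.warning(
                "degenerate ChIP null: IQR = 0, threshold = median = %g "
                "(every locus with count >= median will pass)", med,
            )
        return null

    def to_dict(self) -> dict:
        return {
            "n_background": int(self.background_counts.size),
            "median": self.median,
            "iqr": self.iqr,
            "threshold": self.threshold,
        }


def upstream_interval(
    blocks: Sequence[tuple[int, int]], genome_strand: str, upstream_bp: int
) -> tuple[int, int]:
    """Promoter-proximal window 5' of the antisense unit, on its own strand.

    For a "+" antisense unit the window sits left of the leftmost block; for
    a "-" unit it sits right of the rightmost block.  Clipped at 0.
    """
    blocks = sorted(blocks)
    if genome_strand == "+":
        start = blocks[0][0]
        return (max(0, start - upstream_bp), start)
    end = blocks[-1][1]
    return (end, end + upstream_bp)


def _normalise_blocks(blocks) -> list[tuple[int, int]]:
    if isinstance(blocks, str):
        return str_to_blocks(blocks)
    return [tuple(b) for b in blocks]


def count_supporting_samples(
    chrom: str,
    blocks,
    genome_strand: str,
    peak_sets: Sequence[PeakSet],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> int:
    """Number of samples with >= 1 bp peak overlap of the locus or its
    upstream window.  Peaks are unstranded; overlap is on the genome."""
    if not peak_sets:
        raise ValueError("peak_sets must be nonempty")
    blocks = _normalise_blocks(blocks)
    queries = blocks + [upstream_interval(blocks, genome_strand, upstream_bp)]
    count = 0
    for ps in peak_sets:
        if not len(ps.peaks):
            logger.warning("sample %s has an empty peak set", ps.sample_id)
            continue
        on_chrom = ps.peaks[ps.peaks["chrom"] == chrom]
        if not len(on_chrom):
            continue
        starts = on_chrom["start"].to_numpy()
        ends = on_chrom["end"].to_numpy()
        if any(((starts < qe) & (ends > qs)).any() for qs, qe in queries):
            count += 1
    return count


def count_all_loci(
    loci: pd.DataFrame,
    peak_sets: Sequence[PeakSet],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> pd.DataFrame:
    """Add ``n_supporting_samples`` to a loci frame with genomic columns
    (chrom / blocks / genome_strand)."""
    loci = loci.copy()
    loci["n_supporting_samples"] = [
        count_supporting_samples(
            str(row["chrom"]), row["blocks"], str(row["genome_strand"]), peak_sets, upstream_bp
        )
        for _, row in loci.iterrows()
    ]
    return loci


def build_null(
    background_loci: pd.DataFrame,
    peak_sets: Sequence[PeakSet],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> ChipNull:
    """Supporting-sample null from background loci (requires >= 5)."""
    if len(background_loci) < 5:
        raise ValueError(
            f"need >= 5 background loci to build a null, got {len(background_loci)}"
        )
    counts = count_all_loci(background_loci, peak_sets, upstream_bp)[
        "n_supporting_samples"
    ].to_numpy()
    return ChipNull.from_counts(counts)


def filter_by_chip(loci: pd.DataFrame, null: ChipNull) -> pd.DataFrame:
    """Set ``chip_pass`` = (n_supporting_samples >= null.threshold)."""
    loci = loci.copy()
    loci["chip_threshold"] = null.threshold
    loci["chip_pass"] = loci["n_supporting_samples"] >= null.threshold
    return loci
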