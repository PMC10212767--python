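"""Stage 1: sliding-window antisense enrichment scan on stranded alignments.

Each representative transcript is tiled with 500-nt windows advanced in
250-nt steps.  Reads are assigned to windows by their biological 5' end
(alignment start for sense reads, alignment end - 1 for antisense reads),
so every read contributes to exactly one side of the window/rest split per
strand.  Window enrichment is scored with logASR and a Wald p-value
(:mod:`iris.stats`), q-values are Benjamini-Hochberg across all windows of
the run, significant neighbouring windows are merged, locus ends are
refined to the outermost antisense reads, and the merged loci are re-scored
as a fresh multiple-testing family.  Windows with no enrichment at all
(logASR <= 0, q > 0.5) supply the background loci used by the ChIP filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from iris.genomic_io import TranscriptModel, blocks_to_str
from iris.stats import adjust_fdr, table_stats

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 500
WINDOW_STEP = 250


@dataclass(frozen=True)
class WindowCounts:
    """The 2x2 strand-by-region table behind logASR."""

    a_w: int  # antisense reads in window
    a_r: int  # antisense reads in rest of transcript
    s_w: int  # sense reads in window
    s_r: int  # sense reads in rest of transcript

    def __post_init__(self) -> None:
        if min(self.a_w, self.a_r, self.s_w, self.s_r) < 0:
            raise ValueError("counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a_w, self.a_r, self.s_w, self.s_r)


def make_windows(
    length: int, width: int = WINDOW_WIDTH, step: int = WINDOW_STEP
) -> list[tuple[int, int]]:
    """Tile [0, length) with sliding windows.

    Starts at 0, step, 2*step, ...; each window ends at
    min(start + width, length).  Tiling stops at the first window that
    reaches the transcript end; a terminal window narrower than ``step`` is
    dropped.  Transcripts shorter than ``width`` get one full-length window.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if not 0 < step <= width:
        raise ValueError("require 0 < step <= width")
    if length < width:
        return [(0, length)]
    windows: list[tuple[int, int]] = []
    start = 0
    while True:
        end = min(start + width, length)
        if end - start >= step or not windows:
            windows.append((start, end))
        if end == length:
            break
        start += step
    return windows


def five_prime(starts: np.ndarray, ends: np.ndarray, antisense: np.ndarray) -> np.ndarray:
    """Biological 5' position of each read: start for sense alignments,
    end - 1 for antisense (the 5' end on the opposite strand)."""
    return np.where(antisense, ends - 1, starts)


def count_window(reads: pd.DataFrame, window: tuple[int, int]) -> WindowCounts:
    """Count one transcript's reads into the window/rest 2x2 table.

    ``reads`` is a read table (transcript_id/start/end/strand) holding the
    reads of a single transcript.
    """
    if len(reads) and reads["transcript_id"].nunique() > 1:
        raise ValueError("count_window expects reads from a single transcript")
    start, end = window
    anti = (reads["strand"] == "antisense").to_numpy()
    pos = five_prime(reads["start"].to_numpy(), reads["end"].to_numpy(), anti)
    in_win = (pos >= start) & (pos < end)
    return WindowCounts(
        a_w=int((anti & in_win).sum()),
        a_r=int((anti & ~in_win).sum()),
        s_w=int((~anti & in_win).sum()),
        s_r=int((~anti & ~in_win).sum()),
    )


def _interval_counts(
    a5: np.ndarray, s5: np.ndarray, intervals: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Counts for many intervals of one transcript from sorted 5' arrays."""
    a_w = np.searchsorted(a5, intervals[:, 1]) - np.searchsorted(a5, intervals[:, 0])
    s_w = np.searchsorted(s5, intervals[:, 1]) - np.searchsorted(s5, intervals[:, 0])
    return a_w, len(a5) - a_w, s_w, len(s5) - s_w


def _split_by_transcript(reads: pd.DataFrame):
    """Sorted 5'-position arrays per transcript: tid -> (anti5, sense5)."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid, group in reads.groupby("transcript_id", sort=False):
        anti = (group["strand"] == "antisense").to_numpy()
        pos = five_prime(group["start"].to_numpy(), group["end"].to_numpy(), anti)
        out[str(tid)] = (np.sort(pos[anti]), np.sort(pos[~anti]))
    return out


def _lengths(models: Mapping[str, TranscriptModel] | Mapping[str, int]) -> dict[str, int]:
    return {
        tid: (m.length if isinstance(m, TranscriptModel) else int(m))
        for tid, m in models.items()
    }


def scan_windows(
    reads: pd.DataFrame,
    models: Mapping[str, TranscriptModel] | Mapping[str, int],
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Score every sliding window of every transcript.

    Returns one row per window with the 2x2 counts, logASR, Wald p and
    BH q-value computed across all tested windows of the run.
    """
    lengths = _lengths(models)
    per_tx = _split_by_transcript(reads)
    empty = (np.array([], dtype=np.int64),) * 2
    rows: list[tuple] = []
    for tid, length in lengths.items():
        a5, s5 = per_tx.get(tid, empty)
        intervals = np.array(make_windows(length, width, step), dtype=np.int64)
        a_w, a_r, s_w, s_r = _interval_counts(a5, s5, intervals)
        for i, (ws, we) in enumerate(intervals):
            rows.append((tid, int(ws), int(we), int(a_w[i]), int(a_r[i]), int(s_w[i]), int(s_r[i])))
    frame = pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "a_w", "a_r", "s_w", "s_r"]
    )
    if len(frame):
        la, _, _, _, p = table_stats(
            frame["a_w"], frame["a_r"], frame["s_w"], frame["s_r"], pseudocount
        )
        frame["log_asr"] = la
        frame["p"] = p
        frame["q"] = adjust_fdr(p)
    else:
        frame["log_asr"] = frame["p"] = frame["q"] = np.nan
    return frame


def call_significant_windows(
    windows: pd.DataFrame, logasr_min: float = 0.5, q_max: float = 0.01
) -> pd.DataFrame:
    """Windows with logASR strictly above ``logasr_min`` and q strictly
    below ``q_max``."""
    keep = (windows["log_asr"] > logasr_min) & (windows["q"] < q_max)
    return windows.loc[keep].reset_index(drop=True)


def merge_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended windows per transcript into maximal
    intervals; never merges across transcripts.  Output sorted."""
    loci: list[tuple[str, int, int]] = []
    for tid, group in windows.groupby("transcript_id", sort=True):
        ivals = group[["start", "end"]].sort_values("start").to_numpy()
        cur_s, cur_e = int(ivals[0, 0]), int(ivals[0, 1])
        for s, e in ivals[1:]:
            if s <= cur_e:  # overlap or book-ended (gap 0)
                cur_e = max(cur_e, int(e))
            else:
                loci.append((str(tid), cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        loci.append((str(tid), cur_s, cur_e))
    return pd.DataFrame(loci, columns=["transcript_id", "start", "end"])


def refine_bounds(
    interval: tuple[int, int],
    anti_starts: np.ndarray,
    anti_ends: np.ndarray,
    length: int,
) -> tuple[int, int] | None:
    """Refine a merged interval to the span of overlapping antisense reads.

    Refined start/end are the minimum start and maximum end over antisense
    reads overlapping the interval (refinement may extend beyond the merged
    bounds; clipped to [0, length)).  Returns None when no antisense read
    overlaps, in which case the locus is discarded.
    """
    ms, me = interval
    overlap = (np.asarray(anti_starts) < me) & (np.asarray(anti_ends) > ms)
    if not overlap.any():
        return None
    start = max(0, int(np.asarray(anti_starts)[overlap].min()))
    end = min(int(length), int(np.asarray(anti_ends)[overlap].max()))
    return start, end


def rescore_loci(
    merged: pd.DataFrame,
    reads: pd.DataFrame,
    models: Mapping[str, TranscriptModel] | Mapping[str, int],
    pseudocount: float = 0.5,
    logasr_min: float = 0.5,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Refine merged locus bounds with antisense reads and re-score.

    Each locus's counts, logASR and p are recomputed with the refined
    interval as the "window"; q-values are computed within the refined-locus
    set (a fresh multiple-testing family) and the scan thresholds are
    re-applied: survivors carry ``groseq_pass`` True.  Loci with no
    overlapping antisense read are dropped with a logged reason.
    """
    lengths = _lengths(models)
    per_tx_raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid, group in reads.groupby("transcript_id", sort=False):
        anti = group["strand"] == "antisense"
        per_tx_raw[str(tid)] = (
            group.loc[anti, "start"].to_numpy(),
            group.loc[anti, "end"].to_numpy(),
        )
    per_tx_5p = _split_by_transcript(reads)
    empty = (np.array([], dtype=np.int64),) * 2

    rows: list[dict] = []
    n_discarded = 0
    for _, locus in merged.iterrows():
        tid = str(locus["transcript_id"])
        length = lengths[tid]
        astarts, aends = per_tx_raw.get(tid, empty)
        refined = refine_bounds((int(locus["start"]), int(locus["end"])), astarts, aends, length)
        if refined is None:
            n_discarded += 1
            logger.info(
                "locus %s:[%d,%d) discarded: no overlapping antisense reads",
                tid, locus["start"], locus["end"],
            )
            continue
        a5, s5 = per_tx_5p.get(tid, empty)
        a_w, a_r, s_w, s_r = _interval_counts(a5, s5, np.array([refined]))
        rows.append(
            {
                "transcript_id": tid,
                "merged_start": int(locus["start"]),
                "merged_end": int(locus["end"]),
                "start": refined[0],
                "end": refined[1],
                "a_w": int(a_w[0]),
                "a_r": int(a_r[0]),
                "s_w": int(s_w[0]),
                "s_r": int(s_r[0]),
            }
        )
    if n_discarded:
        logger.warning("%d merged loci discarded (no antisense reads)", n_discarded)

    frame = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "merged_start", "merged_end", "start", "end",
            "a_w", "a_r", "s_w", "s_r",
        ],
    )
    if len(frame):
        la, _, _, _, p = table_stats(
            frame["a_w"], frame["a_r"], frame["s_w"], frame["s_r"], pseudocount
        )
        frame["log_asr"] = la
        frame["p"] = p
        frame["q"] = adjust_fdr(p)
        frame["groseq_pass"] = (frame["log_asr"] > logasr_min) & (frame["q"] < q_max)
    else:
        frame["log_asr"] = frame["p"] = frame["q"] = np.nan
        frame["groseq_pass"] = pd.Series([], dtype=bool)
    frame["locus_id"] = [
        f"{t}:{s}-{e}" for t, s, e in zip(frame["transcript_id"], frame["start"], frame["end"])
    ]
    return frame


def select_background_loci(
    windows: pd.DataFrame,
    logasr_abs_max: float = 0.0,
    q_min: float = 0.5,
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Background loci: merged windows with no antisense enrichment.

    Eligible windows have logASR <= ``logasr_abs_max`` and q > ``q_min``;
    they are merged per transcript exactly like significant windows, then
    optionally down-sampled to ``n`` loci with a seeded uniform draw.
    """
    eligible = windows.loc[
        (windows["log_asr"] <= logasr_abs_max) & (windows["q"] > q_min)
    ]
    if not len(eligible):
        return pd.DataFrame(columns=["transcript_id", "start", "end"])
    merged = merge_windows(eligible)
    if n is not None and n < len(merged):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(merged), size=n, replace=False))
        merged = merged.iloc[idx].reset_index(drop=True)
    elif n is not None and n > len(merged):
        logger.warning(
            "requested %d background loci but only %d are available", n, len(merged)
        )
    return merged


def attach_genomic_blocks(
    loci: pd.DataFrame, models: Mapping[str, TranscriptModel]
) -> pd.DataFrame:
    """Project transcript-space loci to the genome.

    Adds chrom, genomic blocks (serialised), the genomic strand of the
    antisense unit (opposite of the host transcript) and a ``name`` column
    for BED output.
    """
    loci = loci.copy()
    chroms, blocks, strands, names = [], [], [], []
    for _, row in loci.iterrows():
        model = models[str(row["transcript_id"])]
        blk = model.project_to_genome(int(row["start"]), int(row["end"]))
        chroms.append(model.chrom)
        blocks.append(blocks_to_str(blk))
        strands.append(model.antisense_strand)
        names.append(f"{model.transcript_id}:{int(row['start'])}-{int(row['end'])}")
    loci["chrom"] = chroms
    loci["blocks"] = blocks
    loci["genome_strand"] = strands
    loci["name"] = names
    return loci
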