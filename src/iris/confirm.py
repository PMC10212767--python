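"""Stage 3: stranded RNA-seq confirmation and final annotation.

ChIP-passing loci are re-scored on a stranded RNA-seq library with exactly
the same logASR/Wald machinery used for the nascent-transcription scan,
with the whole locus interval as the "window" and q-values computed within
the ChIP-passing set.  Survivors of strict thresholds (logASR > 1,
q < 1e-5) form the final antisense annotation, which is then classified
against a reference annotation (novel / annotated_other /
antisense_or_pseudogene) by same-strand genomic overlap.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from iris.genomic_io import TranscriptModel, str_to_blocks
from iris.scan import _interval_counts, _lengths, _split_by_transcript
from iris.stats import adjust_fdr, table_stats

logger = logging.getLogger(__name__)

CATEGORY_NOVEL = "novel"
CATEGORY_OTHER = "annotated_other"
CATEGORY_AS_PSEUDO = "antisense_or_pseudogene"


def score_rnaseq(
    loci: pd.DataFrame,
    rnaseq_reads: pd.DataFrame,
    models: Mapping[str, TranscriptModel] | Mapping[str, int],
    pseudocount: float = 0.5,
    prefix: str = "rnaseq_",
) -> pd.DataFrame:
    """logASR / p / q of each locus on an independent stranded library.

    Shares the scan's counting and statistic code path; a transcript with
    zero reads yields logASR 0 and p 1 through the pseudocount.  q-values
    are BH across exactly the loci given (the ChIP-passing family).
    """
    lengths = _lengths(models)
    per_tx = _split_by_transcript(rnaseq_reads)
    empty = (np.array([], dtype=np.int64),) * 2
    cols = {k: [] for k in ("a_w", "a_r", "s_w", "s_r")}
    for _, row in loci.iterrows():
        a5, s5 = per_tx.get(str(row["transcript_id"]), empty)
        a_w, a_r, s_w, s_r = _interval_counts(
            a5, s5, np.array([[int(row["start"]), int(row["end"])]])
        )
        for key, val in zip(cols, (a_w[0], a_r[0], s_w[0], s_r[0])):
            cols[key].append(int(val))
    loci = loci.copy()
    for key, vals in cols.items():
        loci[prefix + key] = vals
    if len(loci):
        la, _, _, _, p = table_stats(
            loci[prefix + "a_w"], loci[prefix + "a_r"],
            loci[prefix + "s_w"], loci[prefix + "s_r"], pseudocount,
        )
        loci[prefix + "log_asr"] = la
        loci[prefix + "p"] = p
        loci[prefix + "q"] = adjust_fdr(p)
    else:
        loci[prefix + "log_asr"] = loci[prefix + "p"] = loci[prefix + "q"] = np.nan
    return loci


def finalize(
    loci: pd.DataFrame,
    logasr_min: float = 1.0,
    q_max: float = 1e-5,
    prefix: str = "rnaseq_",
) -> pd.DataFrame:
    """Apply the final-annotation thresholds (strict inequalities) and set
    ``rnaseq_pass``; returns the frame with the flag, final set =
    ``loci[loci.rnaseq_pass]``."""
    loci = loci.copy()
    loci["rnaseq_pass"] = (loci[prefix + "log_asr"] > logasr_min) & (
        loci[prefix + "q"] < q_max
    )
    return loci


def classify_overlap(loci: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Classify final loci against a reference annotation.

    A locus is annotated iff >= 1 bp of same-strand genomic overlap exists
    between its blocks and a reference transcript span (the locus's own
    strand is the antisense strand).  Overlaps whose biotype contains
    "antisense" or "pseudogene" take precedence; other overlaps are
    ``annotated_other``; no overlap is ``novel``.
    """
    loci = loci.copy()
    categories = []
    for _, row in loci.iterrows():
        blocks = row["blocks"]
        if isinstance(blocks, str):
            blocks = str_to_blocks(blocks)
        same = reference[
            (reference["chrom"] == row["chrom"])
            & (reference["strand"] == row["genome_strand"])
        ]
        category = CATEGORY_NOVEL
        if len(same):
            rs = same["start"].to_numpy()
            re_ = same["end"].to_numpy()
            hit = np.zeros(len(same), dtype=bool)
            for bs, be in blocks:
                hit |= (rs < be) & (re_ > bs)
            if hit.any():
                biotypes = same.loc[hit, "biotype"].astype(str).str.lower()
                if biotypes.str.contains("antisense|pseudogene", regex=True).any():
                    category = CATEGORY_AS_PSEUDO
                else:
                    category = CATEGORY_OTHER
        categories.append(category)
    loci["category"] = categories
    return loci


def compare_conditions(
    loci: pd.DataFrame,
    reads_a: pd.DataFrame,
    reads_b: pd.DataFrame,
    models: Mapping[str, TranscriptModel] | Mapping[str, int],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Screen-grade two-condition comparison of antisense read density.

    For each locus, forms the 2x2 table (antisense reads in locus vs the
    transcript's remaining reads) x (condition A vs B) and reports the
    pseudocounted log2 odds ratio (positive = more antisense in B) with a
    Wald p and BH q.  This is a self-contained screen, not a replacement
    for a dispersion-aware differential-expression model; outputs carry a
    ``method`` label saying so.
    """
    lengths = _lengths(models)
    per_a = _split_by_transcript(reads_a)
    per_b = _split_by_transcript(reads_b)
    empty = (np.array([], dtype=np.int64),) * 2
    rows = []
    for _, row in loci.iterrows():
        tid = str(row["transcript_id"])
        interval = np.array([[int(row["start"]), int(row["end"])]])
        cells = {}
        for label, per in (("a", per_a), ("b", per_b)):
            a5, s5 = per.get(tid, empty)
            in_locus = int(
                np.searchsorted(a5, interval[0, 1]) - np.searchsorted(a5, interval[0, 0])
            )
            total = len(a5) + len(s5)
            cells[label] = (in_locus, total - in_locus)
        rows.append(cells["b"] + cells["a"])
    arr = np.array(rows, dtype=float).reshape(-1, 4)
    loci = loci.copy()
    if len(loci):
        l2fc, _, _, _, p = table_stats(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], pseudocount)
        loci["log2fc"] = l2fc
        loci["de_p"] = p
        loci["de_q"] = adjust_fdr(p)
    else:
        loci["log2fc"] = loci["de_p"] = loci["de_q"] = np.nan
    loci.attrs["method"] = "screen-grade 2x2 odds-ratio test, not a DESeq2 replacement"
    return loci
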