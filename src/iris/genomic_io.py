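"""Readers, writers and coordinate machinery for the pipeline's file formats.

Everything downstream works in *transcript space*: a representative isoform
per gene defines a 1-D coordinate system (0-based, half-open) in which
stranded reads are either ``sense`` (same strand as the transcript) or
``antisense``.  This module owns the conversion between that space and the
genome, plus parsers for GTF/GFF annotations, BAM/SAM or tab-delimited read
tables, ENCODE narrowPeak files and BED output.

All genomic coordinates are 0-based half-open internally; GTF/GFF 1-based
closed coordinates are converted on read.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signal_value",
    "p_value",
    "q_value",
    "summit",
]

READ_TABLE_COLUMNS = ["transcript_id", "start", "end", "strand"]


class FormatError(ValueError):
    """A file does not follow the expected format."""


class ReadRecord(NamedTuple):
    """One stranded alignment in transcript coordinates (0-based half-open)."""

    transcript_id: str
    start: int
    end: int
    strand: str  # "sense" or "antisense", relative to the transcript


@dataclass(frozen=True)
class TranscriptModel:
    """A representative isoform with its exon structure.

    ``exons`` are genomic intervals (0-based half-open), sorted and
    non-overlapping.  Transcript coordinate 0 is the 5' end of the mature
    transcript: the leftmost exonic base for a "+" gene, the rightmost for
    a "-" gene.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    genome_strand: str
    exons: tuple[tuple[int, int], ...]
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.genome_strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.genome_strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon [{start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end
        if not 0 <= self.cds_length <= self.length:
            raise ValueError(
                f"{self.transcript_id}: cds_length {self.cds_length} outside [0,{self.length}]"
            )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def antisense_strand(self) -> str:
        """Genomic strand of any antisense unit hosted by this transcript."""
        return "-" if self.genome_strand == "+" else "+"

    def _ordered_exons(self) -> list[tuple[int, int]]:
        # exons in transcript (5'->3') order
        if self.genome_strand == "+":
            return list(self.exons)
        return list(self.exons)[::-1]

    def project_to_genome(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map a transcript interval to its exonic genomic blocks.

        Returns genomic blocks sorted by start whose total width equals
        ``end - start``.  On a "-" transcript, coordinate 0 maps to the
        rightmost genomic base.
        """
        if not 0 <= start < end <= self.length:
            raise ValueError(
                f"interval [{start},{end}) outside transcript [0,{self.length})"
            )
        blocks: list[tuple[int, int]] = []
        offset = 0
        for gstart, gend in self._ordered_exons():
            width = gend - gstart
            lo = max(start, offset)
            hi = min(end, offset + width)
            if hi > lo:
                if self.genome_strand == "+":
                    blocks.append((gstart + (lo - offset), gstart + (hi - offset)))
                else:
                    blocks.append((gend - (hi - offset), gend - (lo - offset)))
            offset += width
        blocks.sort()
        return blocks

    def project_to_transcript(self, blocks: Sequence[tuple[int, int]]) -> tuple[int, int]:
        """Inverse of :meth:`project_to_genome` for fully exonic blocks.

        Returns the transcript interval covering exactly the given genomic
        blocks; raises if any base is intronic/outside the transcript or if
        the blocks are not contiguous in transcript space.
        """
        coords: list[int] = []
        for bstart, bend in blocks:
            for g in (bstart, bend - 1):
                t = self.genome_to_transcript(g)
                if t is None:
                    raise ValueError(f"genomic position {g} is not exonic in {self.transcript_id}")
            t0 = self.genome_to_transcript(bstart)
            t1 = self.genome_to_transcript(bend - 1)
            assert t0 is not None and t1 is not None
            coords.extend(sorted((t0, t1)))
        lo, hi = min(coords), max(coords) + 1
        width = sum(e - s for s, e in blocks)
        if hi - lo != width:
            raise ValueError("blocks are not contiguous in transcript space")
        return lo, hi

    def genome_to_transcript(self, gpos: int) -> int | None:
        """Transcript coordinate of a genomic base, or None if intronic."""
        offset = 0
        for gstart, gend in self._ordered_exons():
            if gstart <= gpos < gend:
                if self.genome_strand == "+":
                    return offset + (gpos - gstart)
                return offset + (gend - 1 - gpos)
            offset += gend - gstart
        return None


@dataclass
class PeakSet:
    """narrowPeak calls from one ChIP-seq sample."""

    sample_id: str
    peaks: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(NARROWPEAK_COLUMNS) - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if len(self.peaks) and not (self.peaks["start"] < self.peaks["end"]).all():
            raise FormatError(f"{self.sample_id}: peak with start >= end")

    def __len__(self) -> int:
        return len(self.peaks)


def _attr_first(feature, *keys: str) -> str | None:
    for key in keys:
        values = feature.attributes.get(key)
        if values:
            return values[0].split(":")[-1] if key == "Parent" else values[0]
    return None


def read_transcript_models(annotation_path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF 2.2 / GFF3 annotation into transcript models.

    ``exon`` features define the structure; ``CDS`` features (if any) define
    ``cds_length`` as the sum of CDS widths.  1-based closed coordinates are
    converted to 0-based half-open.  Unparsable lines and exons without a
    transcript identifier raise :class:`FormatError` naming the line number.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds: dict[str, int] = defaultdict(int)
    meta: dict[str, tuple[str, str]] = {}
    tx2gene: dict[str, str] = {}

    with open(annotation_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if len(line.split("\t")) != 9:
                    raise ValueError("expected 9 tab-separated fields")
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(
                    f"{annotation_path}: unparsable line {lineno}: {exc}"
                ) from exc
            ftype = feat.featuretype.lower()
            if ftype in ("mrna", "transcript"):
                tid = _attr_first(feat, "transcript_id", "ID")
                gid = _attr_first(feat, "gene_id", "Parent")
                if tid and gid:
                    tx2gene[tid] = gid
                continue
            if ftype not in ("exon", "cds"):
                continue
            tid = _attr_first(feat, "transcript_id", "Parent")
            if tid is None:
                raise FormatError(
                    f"{annotation_path}: line {lineno}: {feat.featuretype} without transcript_id"
                )
            start0, end = feat.start - 1, feat.end
            if ftype == "exon":
                exons[tid].append((start0, end))
                meta[tid] = (feat.seqid, feat.strand)
                gid = _attr_first(feat, "gene_id")
                if gid:
                    tx2gene[tid] = gid
            else:
                cds[tid] += end - start0

    models: dict[str, TranscriptModel] = {}
    for tid, tx_exons in exons.items():
        chrom, strand = meta[tid]
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=tx2gene.get(tid, tid),
            chrom=chrom,
            genome_strand=strand,
            exons=tuple(sorted(tx_exons)),
            cds_length=cds.get(tid, 0),
        )
    return models


def select_representative_isoforms(
    models: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick one isoform per gene: longest CDS, then longest transcript, then
    lexicographically smallest transcript_id."""
    models = list(models)
    if not models:
        raise ValueError("no transcript models given")
    best: dict[str, TranscriptModel] = {}
    for model in models:
        incumbent = best.get(model.gene_id)
        if incumbent is None:
            best[model.gene_id] = model
            continue
        key = (-model.cds_length, -model.length, model.transcript_id)
        inc_key = (-incumbent.cds_length, -incumbent.length, incumbent.transcript_id)
        if key < inc_key:
            best[model.gene_id] = model
    return best


def reads_to_frame(records: Iterable[ReadRecord]) -> pd.DataFrame:
    """Build the canonical read table (one row per stranded alignment)."""
    frame = pd.DataFrame(records, columns=READ_TABLE_COLUMNS)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame


def _validate_read_frame(frame: pd.DataFrame, path) -> None:
    if "strand_flag" in frame.columns and "strand" not in frame.columns:
        frame.rename(columns={"strand_flag": "strand"}, inplace=True)
    missing = set(READ_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: read table missing columns {sorted(missing)}")
    bad_strand = ~frame["strand"].isin(["sense", "antisense"])
    if bad_strand.any():
        value = frame.loc[bad_strand, "strand"].iloc[0]
        raise FormatError(f"{path}: invalid strand label {value!r}")
    for col in ("start", "end"):
        try:
            frame[col] = frame[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-integer value in column {col}") from exc
    if (frame["start"] < 0).any() or (frame["start"] >= frame["end"]).any():
        raise FormatError(f"{path}: read with start < 0 or start >= end")


def read_alignments(
    path: str | Path,
    models: Mapping[str, TranscriptModel] | Mapping[str, int],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Load stranded alignments against the representative transcriptome.

    Accepts a BAM/SAM aligned to transcript sequences, or a tab-delimited
    table with header columns transcript_id/start/end/strand.  Forward-strand
    alignments are ``sense``, reverse-complement ``antisense``.  Unmapped,
    secondary and supplementary records are skipped; reads on unknown
    transcripts are skipped with a warning.  Reads are clipped to
    [0, transcript length).

    Returns ``(read table, summary)`` where summary counts skipped records.
    """
    path = Path(path)
    lengths = {
        tid: (m.length if isinstance(m, TranscriptModel) else int(m))
        for tid, m in models.items()
    }
    summary = {"skipped_unaligned": 0, "skipped_unknown_transcript": 0}

    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for aln in bam.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    summary["skipped_unaligned"] += 1
                    continue
                tid = aln.reference_name
                if tid not in lengths:
                    summary["skipped_unknown_transcript"] += 1
                    continue
                strand = "antisense" if aln.is_reverse else "sense"
                rows.append((tid, aln.reference_start, aln.reference_end, strand))
        frame = pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
    else:
        try:
            frame = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse read table: {exc}") from exc
        _validate_read_frame(frame, path)
        known = frame["transcript_id"].isin(lengths)
        summary["skipped_unknown_transcript"] = int((~known).sum())
        frame = frame.loc[known, READ_TABLE_COLUMNS].reset_index(drop=True)

    if summary["skipped_unknown_transcript"]:
        logger.warning(
            "%s: skipped %d reads on unknown transcripts",
            path,
            summary["skipped_unknown_transcript"],
        )
    if len(frame):
        tx_len = frame["transcript_id"].map(lengths).to_numpy()
        frame["start"] = np.clip(frame["start"].to_numpy(), 0, tx_len - 1)
        frame["end"] = np.clip(frame["end"].to_numpy(), 1, tx_len)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame, summary


def read_narrowpeak(path: str | Path, sample_id: str | None = None) -> PeakSet:
    """Parse an ENCODE narrowPeak (BED6+4) file into a :class:`PeakSet`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=range(10))
    if frame.shape[1] != 10:
        raise FormatError(
            f"{path}: narrowPeak requires 10 columns, found {frame.shape[1]}"
        )
    frame.columns = NARROWPEAK_COLUMNS
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    if (frame["chrom"].astype(str).str.len() == 0).any():
        raise FormatError(f"{path}: empty chromosome name")
    return PeakSet(sample_id=sample_id or path.stem, peaks=frame)


def write_narrowpeak(peak_set: PeakSet, path: str | Path) -> None:
    peak_set.peaks[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def blocks_to_str(blocks: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def str_to_blocks(text: str) -> list[tuple[int, int]]:
    if not text:
        return []
    out = []
    for token in str(text).split(","):
        s, _, e = token.partition("-")
        out.append((int(s), int(e)))
    return out


def bed_score(log_asr_value: float) -> int:
    """Scale |logASR| to the 0-1000 BED score column (display only)."""
    return int(round(min(1000.0, 100.0 * abs(float(log_asr_value)))))


def write_bed(loci: pd.DataFrame, path: str | Path) -> None:
    """Write antisense loci as BED6 (single block) / BED12 (multi-block).

    Expects columns ``chrom``, ``blocks`` (list of genomic intervals or the
    string form produced by :func:`blocks_to_str`), ``genome_strand`` (strand
    of the antisense unit) and ``name``; optional ``log_asr`` feeds the score
    column.
    """
    with open(path, "w") as handle:
        for _, row in loci.iterrows():
            blocks = row["blocks"]
            if isinstance(blocks, str):
                blocks = str_to_blocks(blocks)
            blocks = sorted(blocks)
            start, end = blocks[0][0], blocks[-1][1]
            score = bed_score(row.get("log_asr", 0.0))
            base = [row["chrom"], start, end, row["name"], score, row["genome_strand"]]
            if len(blocks) == 1:
                fields = base
            else:
                sizes = ",".join(str(e - s) for s, e in blocks)
                offsets = ",".join(str(s - start) for s, _ in blocks)
                fields = base + [start, end, "0", len(blocks), sizes, offsets]
            handle.write("\t".join(str(f) for f in fields) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6/BED12 back into the loci-frame layout used by the writer."""
    rows = []
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (6, 12):
                raise FormatError(f"{path}: expected 6 or 12 BED columns, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if len(parts) == 12:
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                blocks = [(start + o, start + o + z) for o, z in zip(offsets, sizes)]
            else:
                blocks = [(start, end)]
            rows.append(
                {
                    "chrom": chrom,
                    "name": name,
                    "score": int(score),
                    "genome_strand": strand,
                    "blocks": blocks,
                }
            )
    return pd.DataFrame(rows)


def read_reference_features(path: str | Path) -> pd.DataFrame:
    """Reference transcripts with biotypes for overlap classification.

    Returns one row per transcript: chrom, start, end (genomic span),
    strand, transcript_id and biotype (empty string when the annotation
    carries no biotype attribute).
    """
    spans: dict[str, list[int]] = {}
    info: dict[str, tuple[str, str, str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}: unparsable line {lineno}: {exc}") from exc
            if feat.featuretype.lower() not in ("exon", "transcript", "mrna"):
                continue
            tid = _attr_first(feat, "transcript_id", "ID", "Parent")
            if tid is None:
                continue
            biotype = (
                _attr_first(
                    feat,
                    "transcript_type",
                    "transcript_biotype",
                    "gene_type",
                    "gene_biotype",
                    "biotype",
                )
                or ""
            )
            lo, hi = feat.start - 1, feat.end
            if tid in spans:
                spans[tid][0] = min(spans[tid][0], lo)
                spans[tid][1] = max(spans[tid][1], hi)
                if not info[tid][2] and biotype:
                    info[tid] = (info[tid][0], info[tid][1], biotype)
            else:
                spans[tid] = [lo, hi]
                info[tid] = (feat.seqid, feat.strand, biotype)
    rows = [
        {
            "transcript_id": tid,
            "chrom": info[tid][0],
            "strand": info[tid][1],
            "biotype": info[tid][2],
            "start": spans[tid][0],
            "end": spans[tid][1],
        }
        for tid in spans
    ]
    frame = pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "strand", "biotype", "start", "end"]
    )
    if len(frame) and (frame["biotype"] == "").all():
        logger.warning("%s: reference annotation carries no biotype attributes", path)
    return frame
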