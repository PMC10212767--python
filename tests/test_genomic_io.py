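"""Annotation parsing, representative-isoform choice, coordinate projection
and the format readers/writers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iris.genomic_io import (
    FormatError,
    TranscriptModel,
    read_alignments,
    read_bed,
    read_narrowpeak,
    read_reference_features,
    read_transcript_models,
    select_representative_isoforms,
    write_bed,
    write_narrowpeak,
)

GTF = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\tCDS\t101\t160\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
chr2\tsrc\texon\t501\t800\t.\t-\t.\tgene_id "G2"; transcript_id "T2";
"""


class TestAnnotationReader:
    def test_gtf_coordinates_lengths_and_cds(self, tmp_path):
        path = tmp_path / "anno.gtf"
        path.write_text(GTF)
        models = read_transcript_models(path)
        t1 = models["T1"]
        assert t1.exons == ((100, 200), (300, 400))  # 1-based closed -> 0-based half-open
        assert t1.length == 200
        assert t1.cds_length == 60
        assert t1.gene_id == "G1"
        t2 = models["T2"]
        assert t2.cds_length == 0  # no CDS features -> empty sum
        assert t2.genome_strand == "-"

    def test_single_base_exon(self, tmp_path):
        path = tmp_path / "anno.gtf"
        path.write_text('chr1\ts\texon\t101\t101\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        assert read_transcript_models(path)["T"].exons == ((100, 101),)

    def test_unparsable_line_names_line_number(self, tmp_path):
        path = tmp_path / "anno.gtf"
        path.write_text(GTF + "this is not a gtf line\n")
        with pytest.raises(FormatError, match="line 5"):
            read_transcript_models(path)

    def test_exon_without_transcript_id(self, tmp_path):
        path = tmp_path / "anno.gtf"
        path.write_text('chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "G1";\n')
        with pytest.raises(FormatError, match="transcript_id"):
            read_transcript_models(path)


def _model(tid, gene, cds, length):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom="chr1", genome_strand="+",
        exons=((0, length),), cds_length=cds,
    )


class TestRepresentativeIsoforms:
    @pytest.mark.parametrize(
        "models, expected",
        [
            # longest CDS wins
            ([_model("A", "G", 300, 900), _model("B", "G", 450, 900)], "B"),
            # singleton
            ([_model("A", "G", 100, 500)], "A"),
            # CDS tie -> longer transcript
            ([_model("A", "G", 300, 900), _model("B", "G", 300, 1100)], "B"),
            # full tie -> lexicographically smallest id
            ([_model("B", "G", 300, 900), _model("A", "G", 300, 900)], "A"),
        ],
    )
    def test_selection(self, models, expected):
        assert select_representative_isoforms(models)["G"].transcript_id == expected

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            select_representative_isoforms([])


class TestProjection:
    def test_two_exon_interval(self, two_exon_plus):
        assert two_exon_plus.project_to_genome(50, 150) == [(150, 200), (300, 350)]

    def test_single_exon_identity(self, two_exon_plus):
        assert two_exon_plus.project_to_genome(0, 100) == [(100, 200)]

    def test_minus_strand_reversal(self, single_exon_minus):
        # transcript coordinate 0 is the rightmost genomic base
        assert single_exon_minus.project_to_genome(0, 10) == [(190, 200)]

    def test_antisense_strand_is_opposite(self, two_exon_plus, single_exon_minus):
        assert two_exon_plus.antisense_strand == "-"
        assert single_exon_minus.antisense_strand == "+"

    def test_out_of_bounds_interval(self, two_exon_plus):
        with pytest.raises(ValueError):
            two_exon_plus.project_to_genome(100, 201)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            TranscriptModel("T", "G", "chr1", "+", ((100, 200), (150, 300)))
        with pytest.raises(ValueError):
            TranscriptModel("T", "G", "chr1", "+", ((100, 200),), cds_length=500)


@st.composite
def models_and_intervals(draw):
    n_exons = draw(st.integers(1, 4))
    pos = draw(st.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        width = draw(st.integers(1, 300))
        exons.append((pos, pos + width))
        pos += width + draw(st.integers(1, 500))
    strand = draw(st.sampled_from("+-"))
    model = TranscriptModel("T", "G", "chr1", strand, tuple(exons))
    start = draw(st.integers(0, model.length - 1))
    end = draw(st.integers(start + 1, model.length))
    return model, start, end


@settings(max_examples=100, derandomize=True, deadline=None)
@given(models_and_intervals())
def test_projection_round_trip_and_width(case):
    """Projecting to the genome and back recovers the interval; block widths
    sum to the interval width."""
    model, start, end = case
    blocks = model.project_to_genome(start, end)
    assert sum(e - s for s, e in blocks) == end - start
    assert model.project_to_transcript(blocks) == (start, end)


class TestAlignmentReaders:
    def test_tsv_reader(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text(
            "# comment\ntranscript_id\tstart\tend\tstrand\n"
            "T1\t10\t60\tsense\nT1\t5\t55\tantisense\nTX\t0\t50\tsense\n"
        )
        frame, summary = read_alignments(path, {"T1": 200})
        assert len(frame) == 2
        assert summary["skipped_unknown_transcript"] == 1
        assert list(frame.iloc[0]) == ["T1", 10, 60, "sense"]

    def test_tsv_bad_strand(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text("transcript_id\tstart\tend\tstrand\nT1\t10\t60\tfwd\n")
        with pytest.raises(FormatError, match="strand"):
            read_alignments(path, {"T1": 200})

    def test_tsv_malformed_coordinate(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text("transcript_id\tstart\tend\tstrand\nT1\tten\t60\tsense\n")
        with pytest.raises(FormatError):
            read_alignments(path, {"T1": 200})

    def test_sam_flag_semantics(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:T1\tLN:1000\n"
            "r1\t0\tT1\t11\t255\t50M\t*\t0\t0\t*\t*\n"     # forward -> sense
            "r2\t16\tT1\t11\t255\t50M\t*\t0\t0\t*\t*\n"    # reverse -> antisense
            "r3\t256\tT1\t11\t255\t50M\t*\t0\t0\t*\t*\n"   # secondary -> skipped
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"           # unmapped -> skipped
        )
        frame, summary = read_alignments(sam, {"T1": 1000})
        assert list(frame["strand"]) == ["sense", "antisense"]
        assert list(frame["start"]) == [10, 10]
        assert summary["skipped_unaligned"] == 2

    def test_reads_clipped_to_transcript(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text("transcript_id\tstart\tend\tstrand\nT1\t180\t260\tsense\n")
        frame, _ = read_alignments(path, {"T1": 200})
        assert frame.loc[0, "end"] == 200


class TestPeakAndBedIO:
    def test_narrowpeak_parse(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t600\tp1\t800\t.\t5.2\t10.1\t8.3\t250\n")
        ps = read_narrowpeak(path)
        assert (ps.peaks.loc[0, "start"], ps.peaks.loc[0, "end"]) == (100, 600)

    def test_narrowpeak_wrong_columns(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t600\tp1\t800\t.\n")
        with pytest.raises(FormatError, match="10 columns"):
            read_narrowpeak(path)

    def test_narrowpeak_round_trip(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t600\tp1\t800\t.\t5.2\t10.1\t8.3\t250\n")
        ps = read_narrowpeak(path)
        out = tmp_path / "q.narrowPeak"
        write_narrowpeak(ps, out)
        again = read_narrowpeak(out)
        pd.testing.assert_frame_equal(ps.peaks, again.peaks)

    def test_bed_round_trip_and_antisense_strand(self, tmp_path):
        loci = pd.DataFrame(
            [
                {"chrom": "chr1", "blocks": [(150, 200), (300, 350)],
                 "genome_strand": "-", "name": "L1", "log_asr": 2.0},
                {"chrom": "chr2", "blocks": [(10, 60)],
                 "genome_strand": "+", "name": "L2", "log_asr": 15.0},
            ]
        )
        path = tmp_path / "loci.bed"
        write_bed(loci, path)
        back = read_bed(path)
        assert back.loc[0, "blocks"] == [(150, 200), (300, 350)]  # BED12 blocks
        assert back.loc[1, "blocks"] == [(10, 60)]                # BED6
        assert list(back["genome_strand"]) == ["-", "+"]
        assert back.loc[0, "score"] == 200
        assert back.loc[1, "score"] == 1000  # capped

    def test_reference_features(self, tmp_path):
        path = tmp_path / "ref.gtf"
        path.write_text(
            'chr1\ts\ttranscript\t101\t500\t.\t-\t.\tgene_id "R1"; transcript_id "RT1"; '
            'gene_type "antisense";\n'
        )
        ref = read_reference_features(path)
        assert ref.loc[0, "biotype"] == "antisense"
        assert (ref.loc[0, "start"], ref.loc[0, "end"]) == (100, 500)
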