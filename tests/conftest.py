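import numpy as np
import pandas as pd
import pytest

from iris.genomic_io import TranscriptModel


@pytest.fixture
def two_exon_plus():
    """'+' transcript with exons [100,200) and [300,400): length 200."""
    return TranscriptModel(
        transcript_id="T1",
        gene_id="G1",
        chrom="chr1",
        genome_strand="+",
        exons=((100, 200), (300, 400)),
        cds_length=150,
    )


@pytest.fixture
def single_exon_minus():
    """'-' transcript with one exon [100,200): coordinate 0 is base 199."""
    return TranscriptModel(
        transcript_id="T2",
        gene_id="G2",
        chrom="chr1",
        genome_strand="-",
        exons=((100, 200),),
    )


def make_reads(rows):
    """Read table from (transcript_id, start, end, strand) tuples."""
    frame = pd.DataFrame(rows, columns=["transcript_id", "start", "end", "strand"])
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame


@pytest.fixture
def reads_factory():
    return make_reads
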