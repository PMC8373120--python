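import textwrap

import pytest

from spliceprio.events import TranscriptModel


@pytest.fixture
def cassette_gtf() -> str:
    """Three-exon inclusion transcript plus a skipping transcript, one gene."""
    return textwrap.dedent(
        """\
        chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
        chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
        chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
        chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
        chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
        """
    )


def make_transcript(gene, tid, exons, strand="+", chrom="chr1", cds=None):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_intervals=tuple(cds) if cds else None,
    )


@pytest.fixture
def cassette_transcripts():
    """E1-E2-E3 vs E1-E3 with full-exon CDS on the inclusion form."""
    e1, e2, e3 = (100, 200), (300, 400), (500, 600)
    return [
        make_transcript("g1", "t1", [e1, e2, e3], cds=[e1, e2, e3]),
        make_transcript("g1", "t2", [e1, e3]),
    ]
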