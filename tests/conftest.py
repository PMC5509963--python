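import pytest

from retrofinder.genome_model import GenomicInterval, TranscriptModel, GeneModel
from retrofinder.synthetic_fixtures import (
    FixtureSpec,
    generate_fixture,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic study conditions: 20 genes, 15 processed
    implants at 5% substitutions, 5 intron-retaining duplicates, 3
    single-exon fragments."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def expression_sim(default_fixture):
    return simulate_expression(default_fixture)


def make_transcript(tid, exon_lens_bp, seq_id="chrP", start=1_000_000, strand="+"):
    """A transcript with the given CDS exon lengths, 100 bp introns, and a
    placeholder protein of the right length."""
    exons = []
    pos = start
    for ln in exon_lens_bp:
        if strand == "+":
            exons.append(GenomicInterval(seq_id, pos, pos + ln, strand))
        else:
            exons.append(GenomicInterval(seq_id, pos, pos + ln, strand))
        pos += ln + 100
    if strand == "-":
        exons = exons[::-1]
        exons = [GenomicInterval(e.seq_id, e.start, e.end, e.strand) for e in exons]
    n_aa = sum(exon_lens_bp) // 3
    return TranscriptModel(tid, exons, "M" + "A" * (n_aa - 1))


def make_gene(gid, exon_lens_bp, description="", **kw):
    tx = make_transcript(f"{gid}.T1", exon_lens_bp, **kw)
    return GeneModel(gene_id=gid, transcripts=[tx], description=description)
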