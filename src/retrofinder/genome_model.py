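"""Gene models on a genome: CDS exon structures, introns and proteins.

The retrocopy caller needs, for every potential parental gene, the protein
sequence of a representative transcript and the positions of the introns
expressed in protein coordinates: an intron that interrupts the coding
sequence after ``k`` coding bases sits at amino-acid offset ``k // 3`` with
phase ``k mod 3``.  A retrocopy is recognised by the *absence* of those
introns in the genomic copy, so these positions are the reference against
which intron loss is measured.

Coordinates are 0-based half-open internally; GFF3 is read and written as
1-based inclusive, BED as 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio.Seq import Seq


class GffParseError(ValueError):
    """Raised when the GFF3 gene/mRNA/CDS hierarchy is malformed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.seq_id != other.seq_id:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ProteinIntronPosition:
    """An intron of the parental gene mapped onto its protein.

    ``aa_offset`` is the 0-based index of the first amino acid following
    the intron; ``phase`` is the number of coding bases of the interrupted
    codon that lie upstream of the intron (0 when the intron falls between
    codons).
    """

    index: int
    aa_offset: int
    phase: int


@dataclass
class TranscriptModel:
    transcript_id: str
    cds_exons: list[GenomicInterval]
    protein: str
    first_cds_phase: int = 0

    @property
    def seq_id(self) -> str:
        return self.cds_exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.cds_exons[0].strand

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.cds_exons) - self.first_cds_phase

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id,
            min(e.start for e in self.cds_exons),
            max(e.end for e in self.cds_exons),
            self.strand,
        )


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    biotype: str = "protein_coding"
    description: str = ""

    @property
    def seq_id(self) -> str:
        return self.transcripts[0].seq_id

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def span(self) -> GenomicInterval:
        spans = [t.span() for t in self.transcripts]
        return GenomicInterval(
            self.seq_id,
            min(s.start for s in spans),
            max(s.end for s in spans),
            self.strand,
        )

    def is_multi_exon(self) -> bool:
        return any(t.n_exons >= 2 for t in self.transcripts)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(exons: list[GenomicInterval], genome: dict[str, str],
                  first_phase: int = 0) -> str:
    """Translate concatenated CDS exons, strand- and phase-aware.

    Exons must be in transcription order.  A trailing stop is stripped.
    """
    parts = []
    for e in exons:
        s = genome[e.seq_id][e.start:e.end]
        parts.append(_revcomp(s) if e.strand == "-" else s)
    cds = "".join(parts)[first_phase:]
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3 after phase adjustment")
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def load_gene_models(gff3_source: str, genome_fasta) -> list[GeneModel]:
    """Load gene models from a GFF3 file and the matching genome FASTA.

    ``genome_fasta`` may be a path or an already-loaded ``{seq_id: sequence}``
    mapping.  Returns one :class:`GeneModel` per ``gene`` feature, with
    proteins translated from the genome.  Transcripts whose CDS length is
    not a codon multiple after phase adjustment are skipped with a warning;
    a broken gene/mRNA/CDS hierarchy raises :class:`GffParseError` naming
    the offending feature.
    """
    genome = genome_fasta if isinstance(genome_fasta, dict) else read_fasta(genome_fasta)
    try:
        db = gffutils.create_db(
            gff3_source,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            cds_feats = list(db.children(t, featuretype="CDS", order_by="start"))
            if not cds_feats:
                raise GffParseError(f"mRNA {t.id} has no CDS children")
            strand = cds_feats[0].strand
            if strand not in ("+", "-"):
                raise GffParseError(f"feature {t.id} has no usable strand")
            if strand == "-":
                cds_feats = cds_feats[::-1]  # transcription order
            exons = []
            for c in cds_feats:
                if c.seqid not in genome:
                    raise GffParseError(
                        f"CDS {c.id} on unknown sequence {c.seqid}"
                    )
                exons.append(
                    GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                )
            phase = cds_feats[0].frame
            first_phase = int(phase) if phase not in (None, ".", "") else 0
            try:
                protein = translate_cds(exons, genome, first_phase)
            except ValueError:
                warnings.warn(
                    f"transcript {t.id}: CDS length not divisible by 3; skipped"
                )
                continue
            transcripts.append(
                TranscriptModel(t.id, exons, protein, first_phase)
            )
        if not transcripts:
            continue
        genes.append(
            GeneModel(
                gene_id=g.id,
                transcripts=transcripts,
                biotype=g.attributes.get("biotype", ["protein_coding"])[0],
                description=g.attributes.get("description", [""])[0],
            )
        )
    return genes


def select_multi_exon(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Keep genes with at least one transcript having two or more CDS exons.

    Only such genes can serve as retrocopy parents: intron loss is
    undetectable without introns.
    """
    return [g for g in genes if g.is_multi_exon()]


def canonical_protein(gene: GeneModel) -> tuple[TranscriptModel, str]:
    """The representative transcript of a gene: longest protein.

    Ties break to the lexicographically smallest transcript id so the
    choice is deterministic.
    """
    candidates = [t for t in gene.transcripts if t.protein]
    if not candidates:
        raise ValueError(f"gene {gene.gene_id} has no translatable transcript")
    best = min(candidates, key=lambda t: (-len(t.protein), t.transcript_id))
    return best, best.protein


def protein_intron_positions(transcript: TranscriptModel) -> list[ProteinIntronPosition]:
    """Intron positions of a multi-exon transcript in protein coordinates.

    For the junction after exon ``i``, with ``k`` cumulative coding bases,
    the intron sits at ``aa_offset = k // 3`` with ``phase = k mod 3``.
    """
    if transcript.n_exons < 2:
        raise ValueError(
            f"transcript {transcript.transcript_id} is single-exon; no introns"
        )
    positions = []
    cum = -transcript.first_cds_phase
    for i, exon in enumerate(transcript.cds_exons[:-1]):
        cum += len(exon)
        positions.append(ProteinIntronPosition(i, cum // 3, cum % 3))
    return positions


# ---------------------------------------------------------------------------
# FASTA / GFF3 round-trip helpers

def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS; 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span()
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                "\t".join(
                    [g.seq_id, "retrofinder", "gene", str(span.start + 1),
                     str(span.end), ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            for t in g.transcripts:
                ts = t.span()
                fh.write(
                    "\t".join(
                        [t.seq_id, "retrofinder", "mRNA", str(ts.start + 1),
                         str(ts.end), ".", t.strand, ".",
                         f"ID={t.transcript_id};Parent={g.gene_id}"]
                    )
                    + "\n"
                )
                # CDS rows in genomic order; phase from cumulative coding bp
                cum = -t.first_cds_phase
                rows = []
                for e in t.cds_exons:
                    frame = (-cum) % 3
                    rows.append((e, frame))
                    cum += len(e)
                for e, frame in sorted(rows, key=lambda r: r[0].start):
                    fh.write(
                        "\t".join(
                            [e.seq_id, "retrofinder", "CDS", str(e.start + 1),
                             str(e.end), ".", e.strand, str(frame),
                             f"ID=cds-{t.transcript_id};Parent={t.transcript_id}"]
                        )
                        + "\n"
                    )
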