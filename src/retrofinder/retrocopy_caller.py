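"""Retrocopy calling: intron-loss detection, filtering, parent assignment.

The diagnostic signature of retroposition is intron loss: the parental
protein aligns contiguously to the genomic copy across positions where
the parental gene carries an intron.  A candidate locus is called a
retrocopy when the protein-to-genome alignment is at least 150 bp long,
has identity and coverage of at least 50% with the parental protein, and
lacks at least two parental introns.  Called loci overlapping annotated
pseudogenes by at least half their length are labelled KNOWN_PSEUDOGENE,
the rest NOVEL.  Parents accumulating implausibly many retrocopies while
annotated only as "protein unknown" are flagged for review (they are not
removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from retrofinder.alignment_io import AlignmentChain, AlignmentStats, compute_stats
from retrofinder.genome_model import (
    GeneModel,
    GenomicInterval,
    ProteinIntronPosition,
    protein_intron_positions,
)


@dataclass
class Thresholds:
    """Filter cut-offs for retrocopy calling.

    ``retained_intron_min_gap`` operationalizes "intron lost": the
    target-side gap between the alignment blocks flanking an intron
    position must be shorter than the shortest credible spliceosomal
    intron (about 30 bp) for the intron to count as lost.
    """

    min_aln_bp: int = 150
    min_identity: float = 0.50
    min_coverage: float = 0.50
    min_lost_introns: int = 2
    pseudo_overlap: float = 0.50
    retained_intron_min_gap: int = 30
    mammal_flag_count: int = 50
    other_flag_count: int = 5


@dataclass
class IntronLossReport:
    """Which parental introns the alignment spans, and which are missing.

    ``spanned`` introns have their protein position strictly inside the
    aligned query region; ``lost`` are the spanned introns where the
    genomic copy shows no inserted sequence (gap below the retained-intron
    cut-off); ``retained`` are the rest.
    """

    spanned: list[int]
    lost: list[int]
    retained: list[int]

    @property
    def n_lost(self) -> int:
        return len(self.lost)


@dataclass
class RetrocopyCall:
    retrocopy_id: str
    locus: GenomicInterval
    parental_gene_id: str
    stats: AlignmentStats
    loss: IntronLossReport
    status: str = "NOVEL"           # NOVEL | KNOWN_PSEUDOGENE
    flagged: bool = False
    chain: AlignmentChain | None = field(default=None, repr=False)


def detect_intron_loss(
    chain: AlignmentChain,
    introns: Sequence[ProteinIntronPosition],
    thresholds: Thresholds | None = None,
) -> IntronLossReport:
    """Measure which parental introns are absent from the aligned copy.

    An intron is *spanned* when its amino-acid offset lies strictly inside
    the aligned query span (a junction at the alignment edge is
    uninformative).  A spanned intron is *lost* when the target-coordinate
    gap between the flanking aligned blocks at that protein position is
    below ``retained_intron_min_gap``; alignment running contiguously
    through the position means gap 0, hence lost.
    """
    if not introns:
        raise ValueError("empty intron list; parent must be multi-exon")
    thresholds = thresholds or Thresholds()
    unit = chain.t_unit
    qlo, qhi = chain.q_span
    spanned, lost, retained = [], [], []
    for pos in introns:
        if not (qlo < pos.aa_offset < qhi):
            continue
        spanned.append(pos.index)
        gap = 0
        # find the inter-block interval containing aa_offset, if any
        for prev, nxt in zip(chain.blocks[:-1], chain.blocks[1:]):
            if prev.q_start + prev.length <= pos.aa_offset <= nxt.q_start:
                if chain.strand == "+":
                    gap = nxt.t_start - (prev.t_start + prev.length * unit)
                else:
                    gap = prev.t_start - (nxt.t_start + nxt.length * unit)
                break
        if gap < thresholds.retained_intron_min_gap:
            lost.append(pos.index)
        else:
            retained.append(pos.index)
    return IntronLossReport(spanned=spanned, lost=lost, retained=retained)


def assign_parental(candidates: Sequence[tuple[AlignmentChain, str]]) -> tuple[AlignmentChain, str]:
    """Resolve overlapping candidate chains at one locus to a single parent.

    The best-scoring alignment wins; ties break by identity, then
    coverage, then lexicographically smallest parental gene id, so the
    outcome is independent of input order.
    """
    if not candidates:
        raise ValueError("no candidate chains at locus")

    def key(item):
        chain, gene_id = item
        st = compute_stats(chain)
        return (-chain.score, -st.identity, -st.coverage, gene_id, chain.query_id)

    return min(candidates, key=key)


def _union_coverage(locus: GenomicInterval, features: Iterable[GenomicInterval]) -> int:
    """bp of locus covered by the union of features (strand-blind)."""
    segs = sorted(
        (max(locus.start, f.start), min(locus.end, f.end))
        for f in features
        if f.seq_id == locus.seq_id and f.start < locus.end and f.end > locus.start
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in segs:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def classify_status(
    call: RetrocopyCall,
    known_pseudogenes: Iterable[GenomicInterval],
    thresholds: Thresholds | None = None,
) -> str:
    """KNOWN_PSEUDOGENE when annotated pseudogenes cover at least half of
    the called locus, NOVEL otherwise.  The denominator is the retrocopy
    length, and the 50% boundary is inclusive."""
    thresholds = thresholds or Thresholds()
    covered = _union_coverage(call.locus, known_pseudogenes)
    frac = covered / len(call.locus)
    return "KNOWN_PSEUDOGENE" if frac >= thresholds.pseudo_overlap else "NOVEL"


def call_retrocopies(
    chains: Sequence[AlignmentChain],
    parental_genes: Sequence[GeneModel],
    known_pseudogenes: Sequence[GenomicInterval] = (),
    thresholds: Thresholds | None = None,
    species_prefix: str = "RC",
    clade: str | None = None,
) -> list[RetrocopyCall]:
    """Call retrocopies from protein-to-genome chains.

    Chains are matched to their parental gene through the query id (a
    transcript id of the parent).  A chain survives when it passes the
    length/identity/coverage filters, loses at least two parental introns,
    and does not overlap the parental gene's own annotated span.
    Surviving chains overlapping on the same strand compete; the
    best-scoring one per locus is kept.  Calls are sorted genomically and
    given deterministic ids ``{species_prefix}_{ordinal}``.
    """
    thresholds = thresholds or Thresholds()
    tx_to_gene: dict[str, GeneModel] = {}
    for g in parental_genes:
        for t in g.transcripts:
            tx_to_gene[t.transcript_id] = g

    surviving: list[tuple[AlignmentChain, str, AlignmentStats, IntronLossReport]] = []
    for chain in chains:
        gene = tx_to_gene.get(chain.query_id)
        if gene is None or not gene.is_multi_exon():
            continue
        transcript = next(
            t for t in gene.transcripts if t.transcript_id == chain.query_id
        )
        if transcript.n_exons < 2:
            # intron loss is only measurable against the query's own exons
            continue
        stats = compute_stats(chain, protein_query=True)
        if stats.aln_len_bp < thresholds.min_aln_bp:
            continue
        if stats.identity < thresholds.min_identity:
            continue
        if stats.coverage < thresholds.min_coverage:
            continue
        # a parent aligning back to its own locus is not a retrocopy
        if chain.target_interval().overlaps(gene.span()):
            continue
        loss = detect_intron_loss(
            chain, protein_intron_positions(transcript), thresholds
        )
        if loss.n_lost < thresholds.min_lost_introns:
            continue
        surviving.append((chain, gene.gene_id, stats, loss))

    # cluster surviving chains by >=1 bp overlap on the same seq and strand
    surviving.sort(key=lambda s: (s[0].target_id, s[0].strand, s[0].t_min, s[0].t_max))
    clusters: list[list[tuple]] = []
    for item in surviving:
        iv = item[0].target_interval()
        if clusters:
            last_iv = clusters[-1][-1][0].target_interval()
            cluster_end = max(x[0].t_max for x in clusters[-1])
            if (
                iv.seq_id == last_iv.seq_id
                and iv.strand == last_iv.strand
                and iv.start < cluster_end
            ):
                clusters[-1].append(item)
                continue
        clusters.append([item])

    calls: list[RetrocopyCall] = []
    for cluster in clusters:
        chain, gene_id = assign_parental([(c, g) for c, g, _, _ in cluster])
        stats, loss = next(
            (st, lo) for c, g, st, lo in cluster if c is chain and g == gene_id
        )
        calls.append(
            RetrocopyCall(
                retrocopy_id="",
                locus=chain.target_interval(),
                parental_gene_id=gene_id,
                stats=stats,
                loss=loss,
                chain=chain,
            )
        )

    calls.sort(key=lambda c: (c.locus.seq_id, c.locus.start, c.locus.end, c.locus.strand))
    for i, call in enumerate(calls, 1):
        call.retrocopy_id = f"{species_prefix}_{i:05d}"
        call.status = classify_status(call, known_pseudogenes, thresholds)

    if clade is not None:
        flag_suspicious_parents(calls, parental_genes, clade, thresholds)
    return calls


def flag_suspicious_parents(
    calls: Sequence[RetrocopyCall],
    parental_genes: Sequence[GeneModel],
    clade: str,
    thresholds: Thresholds | None = None,
) -> set[str]:
    """Flag parents with implausibly many retrocopies and no real annotation.

    A parent is suspicious when its retrocopy count exceeds 50 (mammals)
    or 5 (other organisms) *and* its description contains "protein
    unknown" (case-insensitive).  Matching calls get ``flagged=True`` but
    are retained for review.  Returns the flagged parent ids.
    """
    thresholds = thresholds or Thresholds()
    if clade == "mammal":
        cutoff = thresholds.mammal_flag_count
    elif clade == "other":
        cutoff = thresholds.other_flag_count
    else:
        raise ValueError(f"unknown clade {clade!r}; expected 'mammal' or 'other'")
    descriptions = {g.gene_id: g.description for g in parental_genes}
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.parental_gene_id] = counts.get(c.parental_gene_id, 0) + 1
    flagged = {
        gid
        for gid, n in counts.items()
        if n > cutoff and "protein unknown" in descriptions.get(gid, "").lower()
    }
    for c in calls:
        c.flagged = c.parental_gene_id in flagged
    return flagged


# ---------------------------------------------------------------------------
# Tabular output

TSV_COLUMNS = [
    "retrocopy_id", "chrom", "start", "end", "strand", "parental_gene",
    "identity", "coverage", "aln_len_bp", "introns_lost", "status", "flagged",
]


def calls_to_table(calls: Sequence[RetrocopyCall]):
    import pandas as pd

    rows = [
        {
            "retrocopy_id": c.retrocopy_id,
            "chrom": c.locus.seq_id,
            "start": c.locus.start,
            "end": c.locus.end,
            "strand": c.locus.strand,
            "parental_gene": c.parental_gene_id,
            "identity": round(c.stats.identity, 6),
            "coverage": round(c.stats.coverage, 6),
            "aln_len_bp": c.stats.aln_len_bp,
            "introns_lost": c.loss.n_lost,
            "status": c.status,
            "flagged": c.flagged,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def calls_to_bed12(calls: Sequence[RetrocopyCall], stream) -> None:
    """BED12 with one block per aligned alignment block."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            calls_to_bed12(calls, fh)
            return
    for c in calls:
        if c.chain is not None:
            blocks = sorted(c.chain.blocks, key=lambda b: b.t_start)
            unit = c.chain.t_unit
            starts = [b.t_start - c.locus.start for b in blocks]
            sizes = [b.length * unit for b in blocks]
        else:
            starts, sizes = [0], [len(c.locus)]
        stream.write(
            "\t".join(
                map(
                    str,
                    [
                        c.locus.seq_id, c.locus.start, c.locus.end,
                        c.retrocopy_id, 0, c.locus.strand,
                        c.locus.start, c.locus.end, "0,0,0", len(sizes),
                        ",".join(map(str, sizes)) + ",",
                        ",".join(map(str, starts)) + ",",
                    ],
                )
            )
            + "\n"
        )
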