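"""Retrogene identification from proteome self-alignments.

Some retrocopies are not pseudogenes at all: they are annotated,
protein-coding genes whose coding sequence is a single exon because the
gene arose by retroposition of a spliced mRNA.  Such genes are found by
aligning the proteome to itself, discarding alignments between isoforms
of the same gene, and asking whether a gene with a single-exon CDS in
every transcript aligns well to a multi-exon gene across at least two of
that gene's intron positions.  Qualifying genes are labelled
KNOWN_PROTEIN_CODING.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from retrofinder.alignment_io import AlignmentChain, AlignmentStats, compute_stats
from retrofinder.genome_model import (
    GeneModel,
    canonical_protein,
    protein_intron_positions,
)
from retrofinder.retrocopy_caller import Thresholds

TERMINAL_EXCLUSION_AA = 10


@dataclass
class RetrogeneCall:
    gene_id: str
    parental_gene_id: str
    stats: AlignmentStats
    introns_spanned: int
    query_transcript_id: str = ""
    parental_transcript_id: str = ""


def filter_self_alignments(
    chains: Sequence[AlignmentChain],
    protein_to_gene: Callable[[str], str] | dict[str, str],
) -> list[AlignmentChain]:
    """Drop alignments between proteins of the same gene.

    Isoforms of one gene trivially align to each other; these hits (and
    exact self-hits) carry no retroposition signal.
    """
    if isinstance(protein_to_gene, dict):
        mapping = protein_to_gene
        lookup = mapping.__getitem__
    else:
        lookup = protein_to_gene
    return [c for c in chains if lookup(c.query_id) != lookup(c.target_id)]


def select_candidate_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Genes whose CDS consists of one exon in *every* transcript.

    Any multi-exon transcript disqualifies the gene: an intron in any
    isoform is incompatible with a clean retropositional origin.
    """
    return [g for g in genes if all(t.n_exons == 1 for t in g.transcripts)]


def call_retrogenes(
    chains: Sequence[AlignmentChain],
    genes: Sequence[GeneModel],
    thresholds: Thresholds | None = None,
    terminal_exclusion_mode: str = "aligned_span",
) -> list[RetrogeneCall]:
    """Call KNOWN_PROTEIN_CODING retrogenes from protein-vs-protein chains.

    For each candidate gene (single-exon CDS throughout), the best-scoring
    chain to a multi-exon gene is examined.  The call requires an aligned
    coding length of at least 150 bp (50 aa), identity and coverage of at
    least 50%, and at least two parental introns whose protein positions
    fall inside the aligned span of the parental protein after 10 amino
    acids are trimmed from each end of that span (``aligned_span`` mode)
    or after excluding the parental protein's first and last 10 residues
    (``protein_ends`` mode).

    Chains must already be isoform-filtered; query and target ids are
    transcript ids.
    """
    thresholds = thresholds or Thresholds()
    if terminal_exclusion_mode not in ("aligned_span", "protein_ends"):
        raise ValueError(f"unknown terminal_exclusion_mode {terminal_exclusion_mode!r}")

    tx_to_gene: dict[str, GeneModel] = {}
    for g in genes:
        for t in g.transcripts:
            tx_to_gene[t.transcript_id] = g
    candidates = {g.gene_id: g for g in select_candidate_genes(genes)}

    best: dict[str, AlignmentChain] = {}
    for chain in chains:
        qgene = tx_to_gene.get(chain.query_id)
        tgene = tx_to_gene.get(chain.target_id)
        if qgene is None or tgene is None:
            continue
        if qgene.gene_id not in candidates:
            continue
        if not tgene.is_multi_exon():
            continue
        if qgene.gene_id == tgene.gene_id:
            continue
        cur = best.get(qgene.gene_id)
        if cur is None or _better(chain, cur, tx_to_gene):
            best[qgene.gene_id] = chain

    calls: list[RetrogeneCall] = []
    for gene_id in sorted(best):
        chain = best[gene_id]
        stats = compute_stats(chain, protein_query=False)
        if stats.aln_len_bp * 3 < thresholds.min_aln_bp:
            continue
        if stats.identity < thresholds.min_identity:
            continue
        if stats.coverage < thresholds.min_coverage:
            continue
        parent_gene = tx_to_gene[chain.target_id]
        parent_tx = next(
            t for t in parent_gene.transcripts
            if t.transcript_id == chain.target_id
        )
        if parent_tx.n_exons < 2:
            parent_tx, _ = canonical_protein(parent_gene)
            if parent_tx.n_exons < 2:
                continue
        introns = protein_intron_positions(parent_tx)
        t_lo = min(b.t_start for b in chain.blocks)
        t_hi = max(b.t_start + b.length for b in chain.blocks)
        if terminal_exclusion_mode == "aligned_span":
            lo = t_lo + TERMINAL_EXCLUSION_AA
            hi = t_hi - TERMINAL_EXCLUSION_AA
        else:
            lo = max(t_lo, TERMINAL_EXCLUSION_AA)
            hi = min(t_hi, len(parent_tx.protein) - TERMINAL_EXCLUSION_AA)
        spanned = sum(1 for p in introns if lo < p.aa_offset < hi)
        if spanned < 2:
            continue
        calls.append(
            RetrogeneCall(
                gene_id=gene_id,
                parental_gene_id=parent_gene.gene_id,
                stats=stats,
                introns_spanned=spanned,
                query_transcript_id=chain.query_id,
                parental_transcript_id=chain.target_id,
            )
        )
    return calls


def _better(a: AlignmentChain, b: AlignmentChain, tx_to_gene) -> bool:
    """Best-alignment ordering: score, identity, coverage, then target gene id."""
    sa, sb = compute_stats(a), compute_stats(b)
    ka = (-a.score, -sa.identity, -sa.coverage, tx_to_gene[a.target_id].gene_id, a.target_id)
    kb = (-b.score, -sb.identity, -sb.coverage, tx_to_gene[b.target_id].gene_id, b.target_id)
    return ka < kb


def retrogenes_to_table(calls: Sequence[RetrogeneCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "parental_gene_id": c.parental_gene_id,
                "identity": round(c.stats.identity, 6),
                "coverage": round(c.stats.coverage, 6),
                "aligned_aa": c.stats.aln_len_bp,
                "introns_spanned": c.introns_spanned,
            }
            for c in calls
        ],
        columns=[
            "gene_id", "parental_gene_id", "identity", "coverage",
            "aligned_aa", "introns_spanned",
        ],
    )
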