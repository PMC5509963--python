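"""Truth-annotated synthetic inputs for the whole pipeline.

The generator builds a toy genome with multi-exon protein-coding genes
(GT..AG introns, valid ORFs), implants processed retrocopies of known
provenance — spliced copies of parental coding sequences with
controllable substitutions, frameshift/stop injections and truncation —
plus negative controls (unspliced intron-retaining duplicates and
single-exon fragments), and emits the exact protein-to-genome alignment
chains implied by the construction, so every caller can be tested
without running an external aligner.  Expression inputs (uniquely and
multiply mapped reads, ESTs, Pol-II peaks, CAGE TSS) and a two-species
genome pair with a whole-genome-alignment MAF are simulated the same
way, each with a truth table of expected outcomes.

All randomness flows from a single seed; each generator component draws
from a substream derived from a stable label, so outputs are
bit-identical across runs and adding one component does not perturb the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from retrofinder.alignment_io import AlignmentBlock, AlignmentChain
from retrofinder.genome_model import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    translate_cds,
)
from retrofinder.retrocopy_caller import Thresholds

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_AA = sorted(_CODONS_BY_AA)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults give 20 multi-exon genes, 15 processed implants carrying 5%
    nucleotide substitutions, 5 intron-retaining duplicates and 3
    single-exon fragments — enough parents with two or more introns for
    every implant to be callable, and negative controls that fail the
    intron-loss or coverage filters by construction.
    """

    seed: int = 1
    chrom: str = "chr1"
    species: str = "speciesA"
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (2, 8)
    exon_len_range: tuple[int, int] = (90, 240)   # bp
    intron_len_range: tuple[int, int] = (60, 200)  # bp
    intergenic_len_range: tuple[int, int] = (300, 800)
    # retrocopies land in gene deserts; keep them far enough apart that
    # promoter-proximal association windows of neighbours cannot touch
    implant_spacing_range: tuple[int, int] = (2500, 4000)
    n_retrocopies: int = 15
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    truncation_fraction_range: tuple[float, float] = (0.0, 0.0)
    inject_frameshifts: int = 0      # per implant
    inject_stops: int = 0            # per implant
    n_intron_retaining: int = 5
    n_single_exon_fragments: int = 3
    n_known_pseudo: int = 4
    add_polya: bool = False
    # expression simulation
    library_name: str = "lib1"
    library_total: int = 1_000_000
    n_rnaseq_expressed: int = 5
    unique_reads_per_expressed: int = 3
    n_multimapped_loci: int = 2
    n_est_validated: int = 3
    n_est_rejected: int = 1
    n_polII: int = 3
    n_tss: int = 3
    read_length: int = 100
    # species-pair simulation
    divergence: float = 0.02
    maf_flank: int = 50

    def rng(self, label: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


@dataclass
class TruthRecord:
    implant_id: str
    kind: str                     # processed | intron_retaining | single_exon_fragment
    locus: GenomicInterval
    source_gene_id: str
    source_transcript_id: str
    introns_removed: int
    n_substitutions: int = 0
    n_frameshift_indels: int = 0
    n_stop_codons: int = 0
    truncation_fraction: float = 0.0
    expected_call: bool = True
    expected_orf_conserved: bool = True
    expected_status: str = "NOVEL"


@dataclass
class GenomeFixture:
    spec: FixtureSpec
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: list[TruthRecord] = field(default_factory=list)
    chains: list[AlignmentChain] = field(default_factory=list)
    known_pseudogenes: list[GenomicInterval] = field(default_factory=list)
    # per-implant mutated codon lists, used by the truth-alignment builder
    _implant_codons: dict[str, list[str]] = field(default_factory=dict, repr=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(rng.choice(_AA, size=n_aa - 1))
    return "M" + body


def _back_translate(rng: np.random.Generator, protein: str) -> list[str]:
    return [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    ]


def generate_genome(spec: FixtureSpec) -> GenomeFixture:
    """Toy genome: random intergenic background and multi-exon genes.

    Gene strands are random; exon lengths are drawn then padded so the
    CDS is a codon multiple; introns are GT..AG.  Deterministic under the
    spec's seed.
    """
    rng = spec.rng("genome")
    chrom_parts: list[str] = []
    pos = 0
    genes: list[GeneModel] = []

    def append(seq: str) -> int:
        nonlocal pos
        chrom_parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    for i in range(spec.n_genes):
        append(_random_seq(rng, int(rng.integers(*spec.intergenic_len_range))))
        n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        exon_lens = [
            int(rng.integers(*spec.exon_len_range)) for _ in range(n_exons)
        ]
        total = sum(exon_lens)
        exon_lens[-1] += (-total) % 3
        protein = _random_protein(rng, sum(exon_lens) // 3)
        cds = "".join(_back_translate(rng, protein))
        strand = "+" if rng.random() < 0.5 else "-"
        # assemble the gene region in coding orientation
        region_parts, offsets, off, cpos = [], [], 0, 0
        for k, elen in enumerate(exon_lens):
            region_parts.append(cds[cpos : cpos + elen])
            offsets.append((off, elen))
            off += elen
            cpos += elen
            if k < n_exons - 1:
                ilen = int(rng.integers(*spec.intron_len_range))
                region_parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
                off += ilen
        region = "".join(region_parts)
        if strand == "-":
            region_seq = str(Seq(region).reverse_complement())
        else:
            region_seq = region
        gene_start = append(region_seq)
        exons = []
        for o, l in offsets:
            if strand == "+":
                s = gene_start + o
            else:
                s = gene_start + len(region) - (o + l)
            exons.append(GenomicInterval(spec.chrom, s, s + l, strand))
        gid, tid = f"G{i:03d}", f"G{i:03d}.T1"
        genes.append(
            GeneModel(
                gene_id=gid,
                transcripts=[TranscriptModel(tid, exons, protein)],
                description=f"synthetic gene {gid}",
            )
        )
    append(_random_seq(rng, int(rng.integers(*spec.intergenic_len_range))))
    genome = {spec.chrom: "".join(chrom_parts)}
    fixture = GenomeFixture(spec=spec, genome=genome, genes=genes)
    # sanity: stored proteins match strand/phase-aware translation
    for g in fixture.genes:
        for t in g.transcripts:
            assert translate_cds(t.cds_exons, genome) == t.protein
    return fixture


@dataclass
class _ImplantPlan:
    codons: list[str]            # mutated codons of the kept CDS, query order
    blocks: list[tuple[int, int, int]]  # (q_aa, t_offset_in_implant, len_aa)
    seq: str                     # final implant sequence, coding orientation
    n_sub: int
    n_fs: int
    n_stop: int
    n_kept: int


def _mutate_cds(rng: np.random.Generator, codons: list[str],
                spec: FixtureSpec, truncation: float) -> _ImplantPlan:
    n = len(codons)
    n_kept = n - int(n * truncation)
    codons = list(codons[:n_kept])

    # substitutions that never create an in-frame stop
    n_sub = 0
    sub_mask = rng.random(3 * n_kept) < spec.substitution_rate
    for p in np.flatnonzero(sub_mask):
        ci, off = divmod(int(p), 3)
        codon = codons[ci]
        choices = [b for b in "ACGT" if b != codon[off]]
        for bi in rng.permutation(len(choices)):
            b = choices[int(bi)]
            cand = codon[:off] + b + codon[off + 1 :]
            if cand not in _STOPS:
                codons[ci] = cand
                n_sub += 1
                break

    # premature stop injections on interior codons
    interior = list(range(2, n_kept - 2))
    n_stop = min(spec.inject_stops, len(interior) // 3)
    stop_at: set[int] = set()
    if n_stop:
        stop_at = {
            int(j) for j in rng.choice(interior, size=n_stop, replace=False)
        }
        for j in stop_at:
            codons[j] = "TGA"

    # frameshift indels at interior codon boundaries, well separated
    n_fs_target = spec.inject_frameshifts
    if spec.indel_rate > 0:
        n_fs_target += int(rng.binomial(3 * n_kept, spec.indel_rate))
    candidates = [j for j in range(3, n_kept - 3) if j not in stop_at
                  and j - 1 not in stop_at and j + 1 not in stop_at]
    events: dict[int, str] = {}
    if n_fs_target:
        for ji in rng.permutation(len(candidates)):
            j = candidates[int(ji)]
            if all(abs(j - k) >= 3 for k in events):
                events[j] = "ins" if len(events) % 2 == 0 else "del"
                if len(events) == n_fs_target:
                    break
    n_fs = len(events)

    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    cur: list[int] | None = None
    t = 0
    for j in range(n_kept):
        ev = events.get(j)
        if ev == "ins":
            if cur:
                blocks.append(tuple(cur))
                cur = None
            parts.append(str(rng.choice(_BASES)))
            t += 1
        if ev == "del":
            if cur:
                blocks.append(tuple(cur))
                cur = None
            parts.append(codons[j][1:])  # 1-bp deletion destroys codon j
            t += 2
            continue
        if cur is None:
            cur = [j, t, 0]
        cur[2] += 1
        parts.append(codons[j])
        t += 3
    if cur:
        blocks.append(tuple(cur))
    return _ImplantPlan(codons, [tuple(b) for b in blocks],
                        "".join(parts), n_sub, n_fs, n_stop, n_kept)


def implant_retrocopies(fixture: GenomeFixture, spec: FixtureSpec | None = None) -> GenomeFixture:
    """Append processed implants and negative controls to the genome.

    Processed implants are spliced CDS copies with the spec's mutation
    load; intron-retaining duplicates copy the whole gene region
    (introns included); single-exon fragments copy only the first exon's
    coding sequence.  Expected outcomes are derived from the construction
    and the default :class:`Thresholds` arithmetic, not from running the
    caller.
    """
    spec = spec or fixture.spec
    rng = spec.rng("implants")
    thr = Thresholds()
    chrom = fixture.genome[spec.chrom]
    parts = [chrom]
    pos = len(chrom)

    def append(seq: str) -> int:
        nonlocal pos
        spacer = _random_seq(rng, int(rng.integers(*spec.implant_spacing_range)))
        parts.append(spacer)
        start = pos + len(spacer)
        parts.append(seq)
        pos = start + len(seq)
        return start

    sources = [g for g in fixture.genes if g.transcripts[0].n_exons >= 3]
    if not sources:
        raise ValueError("no genes with >=2 introns to serve as implant sources")

    n_implant = 0
    for i in range(spec.n_retrocopies):
        gene = sources[int(rng.integers(len(sources)))]
        tx = gene.transcripts[0]
        codons = _split_codons_from_tx(tx, fixture.genome)
        truncation = float(rng.uniform(*spec.truncation_fraction_range))
        plan = _mutate_cds(rng, codons, spec, truncation)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = plan.seq + ("A" * 20 if spec.add_polya else "")
        gseq = str(Seq(seq).reverse_complement()) if strand == "-" else seq
        start = append(gseq)
        locus = GenomicInterval(spec.chrom, start, start + len(seq), strand)
        if strand == "+":
            body = GenomicInterval(spec.chrom, start, start + len(plan.seq), strand)
        else:
            body = GenomicInterval(
                spec.chrom, start + len(seq) - len(plan.seq), start + len(seq), strand
            )
        implant_id = f"IMP_{n_implant:03d}"
        n_implant += 1
        aligned = sum(b[2] for b in plan.blocks)
        identity = _plan_matches(plan, tx.protein) / aligned
        coverage = aligned / len(tx.protein)
        introns = _intron_offsets(tx)
        qlo, qhi = plan.blocks[0][0], plan.blocks[-1][0] + plan.blocks[-1][2]
        lost = sum(1 for off in introns if qlo < off < qhi)
        expected_call = (
            aligned * 3 >= thr.min_aln_bp
            and identity >= thr.min_identity
            and coverage >= thr.min_coverage
            and lost >= thr.min_lost_introns
        )
        fixture.truth.append(
            TruthRecord(
                implant_id=implant_id,
                kind="processed",
                locus=body,
                source_gene_id=gene.gene_id,
                source_transcript_id=tx.transcript_id,
                introns_removed=tx.n_exons - 1,
                n_substitutions=plan.n_sub,
                n_frameshift_indels=plan.n_fs,
                n_stop_codons=plan.n_stop,
                truncation_fraction=truncation,
                expected_call=expected_call,
                expected_orf_conserved=plan.n_fs == 0 and plan.n_stop == 0,
            )
        )
        fixture._implant_codons[implant_id] = plan.codons
        fixture.chains.append(_plan_to_chain(plan, tx, locus, len(plan.seq)))

    for i in range(spec.n_intron_retaining):
        gene = sources[int(rng.integers(len(sources)))]
        tx = gene.transcripts[0]
        span = tx.span()
        region = fixture.genome[spec.chrom][span.start : span.end]
        start = append(region)
        fixture.truth.append(
            TruthRecord(
                implant_id=f"NEG_IR_{i:03d}",
                kind="intron_retaining",
                locus=GenomicInterval(spec.chrom, start, start + len(region), gene.strand),
                source_gene_id=gene.gene_id,
                source_transcript_id=tx.transcript_id,
                introns_removed=0,
                expected_call=False,
                expected_orf_conserved=True,
            )
        )
        fixture.chains.append(
            _exonic_chain(tx, GenomicInterval(spec.chrom, start, start + len(region), gene.strand))
        )

    for i in range(spec.n_single_exon_fragments):
        gene = sources[int(rng.integers(len(sources)))]
        tx = gene.transcripts[0]
        codons = _split_codons_from_tx(tx, fixture.genome)
        n_frag = len(tx.cds_exons[0]) // 3
        frag = "".join(codons[:n_frag])
        strand = "+" if rng.random() < 0.5 else "-"
        gseq = str(Seq(frag).reverse_complement()) if strand == "-" else frag
        start = append(gseq)
        locus = GenomicInterval(spec.chrom, start, start + len(frag), strand)
        fixture.truth.append(
            TruthRecord(
                implant_id=f"NEG_SE_{i:03d}",
                kind="single_exon_fragment",
                locus=locus,
                source_gene_id=gene.gene_id,
                source_transcript_id=tx.transcript_id,
                introns_removed=0,
                expected_call=False,
                expected_orf_conserved=True,
            )
        )
        blocks = [AlignmentBlock(0, _implant_block_start(locus, 0, n_frag), n_frag)]
        chain = AlignmentChain(
            query_id=tx.transcript_id,
            query_len=len(tx.protein),
            target_id=spec.chrom,
            target_len=0,
            strand=strand,
            blocks=blocks,
            matches=n_frag,
            score=n_frag,  # 2*matches - aligned
            protein_query=True,
        )
        fixture.chains.append(chain)

    # parent self-alignments: the parent protein aligned back to its own locus
    for gene in fixture.genes:
        tx = gene.transcripts[0]
        fixture.chains.append(_exonic_chain(tx, None))

    fixture.genome[spec.chrom] = "".join(parts)
    for c in fixture.chains:
        c.target_len = len(fixture.genome[spec.chrom])

    # known-pseudogene annotations covering some processed implants
    prng = spec.rng("pseudogenes")
    processed = [t for t in fixture.truth if t.kind == "processed"]
    chosen = prng.choice(len(processed), size=min(spec.n_known_pseudo, len(processed)),
                         replace=False)
    for idx in sorted(int(x) for x in chosen):
        rec = processed[idx]
        length = len(rec.locus)
        cover = int(length * 0.6)
        fixture.known_pseudogenes.append(
            GenomicInterval(rec.locus.seq_id, rec.locus.start, rec.locus.start + cover, "+")
        )
        if rec.expected_call:
            rec.expected_status = "KNOWN_PSEUDOGENE"
    return fixture


def _split_codons_from_tx(tx: TranscriptModel, genome: dict[str, str]) -> list[str]:
    parts = []
    for e in tx.cds_exons:
        s = genome[e.seq_id][e.start : e.end]
        if e.strand == "-":
            s = str(Seq(s).reverse_complement())
        parts.append(s)
    cds = "".join(parts)
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _intron_offsets(tx: TranscriptModel) -> list[int]:
    offs, cum = [], 0
    for e in tx.cds_exons[:-1]:
        cum += len(e)
        offs.append(cum // 3)
    return offs


def _plan_matches(plan: _ImplantPlan, protein: str) -> int:
    m = 0
    for q, _t, ln in plan.blocks:
        for j in range(q, q + ln):
            aa = str(Seq(plan.codons[j]).translate())
            if aa == protein[j]:
                m += 1
    return m


def _implant_block_start(locus: GenomicInterval, t_off: int, len_aa: int) -> int:
    if locus.strand == "+":
        return locus.start + t_off
    return locus.end - (t_off + 3 * len_aa)


def _plan_to_chain(plan: _ImplantPlan, tx: TranscriptModel,
                   locus: GenomicInterval, implant_len: int) -> AlignmentChain:
    blocks = [
        AlignmentBlock(q, _implant_block_start(locus, t, ln), ln)
        for q, t, ln in plan.blocks
    ]
    matches = _plan_matches(plan, tx.protein)
    aligned = sum(b.length for b in blocks)
    chain = AlignmentChain(
        query_id=tx.transcript_id,
        query_len=len(tx.protein),
        target_id=locus.seq_id,
        target_len=0,
        strand=locus.strand,
        blocks=blocks,
        matches=matches,
        score=2 * matches - aligned,
        protein_query=True,
    )
    return chain


def _exonic_chain(tx: TranscriptModel, locus: GenomicInterval | None) -> AlignmentChain:
    """Chain of a protein against an exon/intron-structured copy of its gene.

    With ``locus`` None the chain targets the gene's own annotated span
    (a self-alignment); otherwise the gene region was duplicated
    verbatim at ``locus`` and coordinates are shifted accordingly.  Only
    codons fully contained in one exon are aligned, so phase-1/2 introns
    shave the split codon off the flanking blocks; the inter-block gaps
    remain within a few bp of the true intron lengths.
    """
    span = tx.span()
    shift = 0 if locus is None else locus.start - span.start
    strand = tx.strand  # duplicates copy the region verbatim
    blocks = []
    cum = 0
    for e in tx.cds_exons:  # transcription order
        q_start = -(-cum // 3)                 # first full codon in this exon
        q_end = (cum + len(e)) // 3
        skip = q_start * 3 - cum               # bp into the exon before it
        n_aa = q_end - q_start
        if n_aa > 0:
            if strand == "+":
                t = e.start + skip + shift
            else:
                t = e.end - skip - 3 * n_aa + shift
            blocks.append(AlignmentBlock(q_start, t, n_aa))
        cum += len(e)
    aligned = sum(b.length for b in blocks)
    return AlignmentChain(
        query_id=tx.transcript_id,
        query_len=len(tx.protein),
        target_id=span.seq_id,
        target_len=0,
        strand=strand,
        blocks=blocks,
        matches=aligned,
        score=aligned,
        protein_query=True,
    )


# ---------------------------------------------------------------------------
# Expression-evidence simulation

@dataclass
class SimulatedExpression:
    """Simulated RNA-Seq/EST/peak/TSS inputs plus expected outcomes."""

    sam_text: str
    library_totals: dict[str, int]
    est_hits: dict[str, list[AlignmentChain]]     # est_id -> all genome hits
    polII_peaks: list[GenomicInterval]
    tss_sites: list[GenomicInterval]
    expected_rnaseq: dict[str, bool]              # implant_id -> expressed
    expected_est: dict[str, bool]
    expected_polII: dict[str, bool]
    expected_tss: dict[str, bool]


def _five_prime(locus: GenomicInterval) -> int:
    return locus.start if locus.strand == "+" else locus.end


def simulate_expression(fixture: GenomeFixture, spec: FixtureSpec | None = None) -> SimulatedExpression:
    """Plant reads, ESTs, Pol-II peaks and TSS on the implanted retrocopies.

    The first ``n_rnaseq_expressed`` processed implants receive enough
    uniquely mapped (NH:1) reads to clear 1 RPM at the configured library
    size; a few further loci receive only multi-mapped (NH:5) reads,
    which must not count.  ESTs are constructed so the retrocopy hit
    strictly beats the parental hit for validated cases and exactly ties
    it for rejected cases.  Peaks and TSS are placed inside / outside
    the association windows of chosen implants.
    """
    spec = spec or fixture.spec
    rng = spec.rng("expression")
    chrom = spec.chrom
    genome_seq = fixture.genome[chrom]
    processed = [t for t in fixture.truth if t.kind == "processed"]

    # --- RNA-Seq reads
    reads = []
    expected_rnaseq: dict[str, bool] = {}
    rpm_per_read = 1e6 / spec.library_total
    need = int(np.ceil(1.0 / rpm_per_read / max(spec.unique_reads_per_expressed, 1)))
    n_unique = spec.unique_reads_per_expressed * max(need, 1)
    for idx, rec in enumerate(processed):
        expressed = idx < spec.n_rnaseq_expressed
        expected_rnaseq[rec.implant_id] = expressed
        if expressed:
            for r in range(n_unique):
                p = rec.locus.start + int(rng.integers(0, max(1, len(rec.locus) - spec.read_length)))
                reads.append((p, rec.implant_id, r, 1))
        elif idx < spec.n_rnaseq_expressed + spec.n_multimapped_loci:
            for r in range(4):
                p = rec.locus.start + int(rng.integers(0, max(1, len(rec.locus) - spec.read_length)))
                reads.append((p, rec.implant_id, r, 5))
    reads.sort()
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{chrom}\tLN:{len(genome_seq)}",
    ]
    for p, rid, r, nh in reads:
        seq = genome_seq[p : p + spec.read_length]
        lines.append(
            "\t".join(
                [
                    f"read_{rid}_{r}_nh{nh}", "0", chrom, str(p + 1), "60",
                    f"{len(seq)}M", "*", "0", "0", seq, "*", f"NH:i:{nh}",
                ]
            )
        )
    sam_text = "\n".join(lines) + "\n"

    # --- ESTs
    est_hits: dict[str, list[AlignmentChain]] = {}
    expected_est = {rec.implant_id: False for rec in processed}
    tx_by_id = {
        t.transcript_id: (g, t) for g in fixture.genes for t in g.transcripts
    }
    n_val = min(spec.n_est_validated, len(processed))
    n_rej = min(spec.n_est_rejected, max(0, len(processed) - n_val))
    for k in range(n_val + n_rej):
        rec = processed[k]
        validated = k < n_val
        gene, tx = tx_by_id[rec.source_transcript_id]
        est_id = f"EST_{k:04d}"
        est_len = min(300, (len(rec.locus) // 2) * 2)
        retro_matches = int(est_len * 0.95)
        retro_hit = AlignmentChain(
            query_id=est_id, query_len=est_len, target_id=chrom,
            target_len=len(genome_seq), strand="+",
            blocks=[AlignmentBlock(0, rec.locus.start, est_len)],
            matches=retro_matches, score=2 * retro_matches - est_len,
        )
        exon1 = tx.cds_exons[0]
        if validated:
            par_len = min(150, len(exon1))
            par_matches = int(par_len * 0.85)
        else:
            par_len = est_len
            par_matches = retro_matches  # exact tie on score and identity
        parent_hit = AlignmentChain(
            query_id=est_id, query_len=est_len, target_id=chrom,
            target_len=len(genome_seq), strand="+",
            blocks=[AlignmentBlock(0, exon1.start, par_len)],
            matches=par_matches, score=2 * par_matches - par_len,
        )
        est_hits[est_id] = [retro_hit, parent_hit]
        if validated:
            expected_est[rec.implant_id] = True

    # --- Pol-II peaks and TSS
    from retrofinder.expression_evidence import EvidenceWindows, association_window

    ew = EvidenceWindows()
    all_windows = {
        rec.implant_id: association_window(
            rec.locus, max(ew.polII_upstream, ew.tss_upstream), ew.body_fraction
        )
        for rec in processed
    }

    def place(rec, offsets: list[int], width: int) -> GenomicInterval | None:
        """First upstream offset whose feature hits only this implant's window."""
        five = _five_prime(rec.locus)
        sgn = -1 if rec.locus.strand == "+" else 1
        for off in offsets:
            lo = min(five + sgn * off, five + sgn * off + sgn * -width)
            cand = GenomicInterval(chrom, lo, lo + width, "+")
            if all(
                not cand.overlaps(w)
                for iid, w in all_windows.items()
                if iid != rec.implant_id
            ):
                return cand
        return None

    polII_peaks: list[GenomicInterval] = []
    tss_sites: list[GenomicInterval] = []
    expected_polII = {rec.implant_id: False for rec in processed}
    expected_tss = {rec.implant_id: False for rec in processed}
    decoy = 2
    for k, rec in enumerate(processed):
        if k < spec.n_polII:
            peak = place(rec, [800, 500, 300, 150, -20, -60], 100)
            if peak is not None:
                polII_peaks.append(peak)
                expected_polII[rec.implant_id] = True
        elif k == spec.n_polII:
            # a decoy far from every association window stays unassociated
            polII_peaks.append(GenomicInterval(chrom, decoy, decoy + 10, "+"))
            decoy += 20
        if k < spec.n_tss:
            site = place(rec, [400, 250, 100, -10, -40], 10)
            if site is not None:
                tss_sites.append(site)
                expected_tss[rec.implant_id] = True
        elif k == spec.n_tss:
            tss_sites.append(GenomicInterval(chrom, decoy, decoy + 10, "+"))
            decoy += 20
    return SimulatedExpression(
        sam_text=sam_text,
        library_totals={spec.library_name: spec.library_total},
        est_hits=est_hits,
        polII_peaks=sorted(polII_peaks),
        tss_sites=sorted(tss_sites),
        expected_rnaseq=expected_rnaseq,
        expected_est=expected_est,
        expected_polII=expected_polII,
        expected_tss=expected_tss,
    )


# ---------------------------------------------------------------------------
# Two-species pair with whole-genome-alignment blocks

@dataclass
class SpeciesPair:
    fixture_a: GenomeFixture
    fixture_b: GenomeFixture
    maf_blocks: list
    shared_implants: list[str]      # implant ids present and callable in both
    a_only_implants: list[str]
    b_only_implants: list[str]


def generate_species_pair(spec: FixtureSpec) -> SpeciesPair:
    """Duplicate a fixture genome into a diverged second species.

    Background (intergenic) sequence diverges at ``spec.divergence``;
    genes and implants are copied intact so their truth alignments stay
    valid in both species.  One implant is ablated (sequence scrambled)
    in species B so its species-A copy stays a singleton, and one extra
    implant is appended to species B only.  The MAF holds one ungapped
    two-row block per surviving implant locus plus the ablated locus.
    """
    from retrofinder.orthology import WgaBlock, WgaRow

    fixture_a = implant_retrocopies(generate_genome(spec), spec)
    rng = spec.rng("species_pair")
    chrom = spec.chrom
    seq_a = fixture_a.genome[chrom]

    # mask of positions that must stay identical in B
    protected = np.zeros(len(seq_a), dtype=bool)
    for g in fixture_a.genes:
        s = g.span()
        protected[s.start : s.end] = True
    for rec in fixture_a.truth:
        protected[rec.locus.start : rec.locus.end] = True

    b = np.array(list(seq_a))
    mut = (np.asarray(rng.random(len(seq_a)) < spec.divergence)) & (~protected)
    for p in np.flatnonzero(mut):
        cur = b[p]
        alts = [x for x in "ACGT" if x != cur]
        b[p] = alts[int(rng.integers(3))]

    processed = [t for t in fixture_a.truth if t.kind == "processed" and t.expected_call]
    ablated = processed[-1].implant_id if processed else None
    for rec in fixture_a.truth:
        if rec.implant_id == ablated:
            scr = rng.permutation(list(seq_a[rec.locus.start : rec.locus.end]))
            b[rec.locus.start : rec.locus.end] = scr
    seq_b = "".join(b)

    spec_b = replace(spec, species=spec.species + "_b")
    fixture_b = GenomeFixture(
        spec=spec_b,
        genome={chrom: seq_b},
        genes=fixture_a.genes,
        truth=[t for t in fixture_a.truth if t.implant_id != ablated],
        chains=[c for c in fixture_a.chains
                if not _chain_at(c, fixture_a, ablated)],
        known_pseudogenes=list(fixture_a.known_pseudogenes),
    )

    # one extra implant only in B, appended at the chromosome end
    extra_spec = replace(spec, seed=spec.seed + 7, n_retrocopies=1,
                         n_intron_retaining=0, n_single_exon_fragments=0,
                         n_known_pseudo=0)
    tail = GenomeFixture(spec=extra_spec, genome={chrom: seq_b},
                         genes=fixture_a.genes)
    tail = implant_retrocopies(tail, extra_spec)
    extra = [t for t in tail.truth if t.kind == "processed"]
    fixture_b.genome[chrom] = tail.genome[chrom]
    for rec in extra:
        rec.implant_id = "B_" + rec.implant_id
        fixture_b.truth.append(rec)
    for c in tail.chains:
        if any(_chain_at(c, tail, rec.implant_id[2:]) for rec in extra):
            fixture_b.chains.append(c)
    for c in fixture_b.chains:
        c.target_len = len(fixture_b.genome[chrom])

    # MAF blocks over every species-A implant locus (incl. the ablated one)
    blocks = []
    sp_a, sp_b = spec.species, spec_b.species
    for i, rec in enumerate(fixture_a.truth):
        if rec.kind != "processed":
            continue
        lo = max(0, rec.locus.start - spec.maf_flank)
        hi = min(len(seq_a), rec.locus.end + spec.maf_flank)
        rows = {
            sp_a: WgaRow(sp_a, chrom, lo, hi - lo, "+", len(seq_a), seq_a[lo:hi]),
            sp_b: WgaRow(sp_b, chrom, lo, hi - lo, "+",
                         len(fixture_b.genome[chrom]), seq_b[lo:hi]),
        }
        blk = WgaBlock(f"mafblk{i}", rows)
        blk.validate()
        blocks.append(blk)

    shared = [t.implant_id for t in fixture_a.truth
              if t.kind == "processed" and t.expected_call and t.implant_id != ablated]
    return SpeciesPair(
        fixture_a=fixture_a,
        fixture_b=fixture_b,
        maf_blocks=blocks,
        shared_implants=shared,
        a_only_implants=[ablated] if ablated else [],
        b_only_implants=[r.implant_id for r in extra],
    )


def _chain_at(chain: AlignmentChain, fixture: GenomeFixture, implant_id: str) -> bool:
    rec = next((t for t in fixture.truth if t.implant_id == implant_id), None)
    if rec is None:
        return False
    return chain.target_interval().overlaps(rec.locus)


# ---------------------------------------------------------------------------
# Convenience front-ends

def generate_fixture(spec: FixtureSpec | None = None) -> GenomeFixture:
    """Genome + genes + implants + truth alignments, in one call."""
    spec = spec or FixtureSpec()
    return implant_retrocopies(generate_genome(spec), spec)


def truth_alignments(fixture: GenomeFixture) -> list[AlignmentChain]:
    """The exact protein-to-genome chains implied by the implant records."""
    return list(fixture.chains)


def write_fixture(fixture: GenomeFixture, outdir: str) -> dict[str, str]:
    """Write FASTA/GFF3/PSL/BED plus the truth table; returns file paths."""
    import os

    import pandas as pd

    from retrofinder.alignment_io import write_psl
    from retrofinder.genome_model import write_fasta, write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "proteins": os.path.join(outdir, "proteins.fa"),
        "psl": os.path.join(outdir, "alignments.psl"),
        "pseudo_bed": os.path.join(outdir, "pseudogenes.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(fixture.genome, paths["genome"])
    write_gff3(fixture.genes, paths["gff3"])
    write_fasta(
        {t.transcript_id: t.protein for g in fixture.genes for t in g.transcripts},
        paths["proteins"],
    )
    write_psl(fixture.chains, paths["psl"])
    with open(paths["pseudo_bed"], "w") as fh:
        for iv in fixture.known_pseudogenes:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\tpseudogene\t0\t{iv.strand}\n")
    pd.DataFrame(
        [
            {
                "implant_id": t.implant_id,
                "kind": t.kind,
                "chrom": t.locus.seq_id,
                "start": t.locus.start,
                "end": t.locus.end,
                "strand": t.locus.strand,
                "source_gene": t.source_gene_id,
                "source_transcript": t.source_transcript_id,
                "introns_removed": t.introns_removed,
                "n_substitutions": t.n_substitutions,
                "n_frameshift_indels": t.n_frameshift_indels,
                "n_stop_codons": t.n_stop_codons,
                "truncation_fraction": t.truncation_fraction,
                "expected_call": t.expected_call,
                "expected_orf_conserved": t.expected_orf_conserved,
                "expected_status": t.expected_status,
            }
            for t in fixture.truth
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
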