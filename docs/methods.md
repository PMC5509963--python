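# Methods

## The detection model

Retroposition copies a spliced mRNA back into the genome, so a
retrocopy aligns to its parental protein *contiguously across positions
where the parental gene carries an intron*. The caller therefore works
entirely from gapped protein-to-genome alignment chains (produced by
any local aligner; PSL and LAST tabular are read) and the parental gene
models:

1. Each intron of a parental transcript is mapped to protein
   coordinates: after `k` cumulative coding bases the intron sits at
   amino-acid offset `⌊k/3⌋` with phase `k mod 3`.
2. An intron is **spanned** by a chain when its offset lies strictly
   inside the aligned query span; a junction at the alignment edge is
   uninformative and never counts.
3. A spanned intron is **lost** when the target-side gap between the
   flanking aligned blocks at that protein position is smaller than
   `retained_intron_min_gap` (default 30 bp — about the shortest
   credible spliceosomal intron). Contiguous alignment through the
   position means a gap of 0, hence lost. Anything ≥ 30 bp is treated
   as a retained intron.
4. A chain is called a retrocopy when `aln_len_bp ≥ 150` (aligned
   residues × 3 for a protein query), `identity ≥ 0.50` (matches over
   aligned, gap-excluded query positions), `coverage ≥ 0.50` (aligned
   over total query length), and ≥ 2 introns are lost. Chains
   overlapping the parental gene's own annotated span are discarded
   (the parent trivially aligns to itself). All cut-offs are inclusive
   at the boundary and live in a single `Thresholds` dataclass.

Overlapping surviving chains on one strand compete for the locus; the
best-scoring chain wins, with ties broken by identity, then coverage,
then lexicographically smallest parental gene id, so output never
depends on input order. Call ids are assigned after a genomic sort.

Status: a call is KNOWN_PSEUDOGENE when the union of known-pseudogene
intervals covers ≥ 50% of the *call's* length (the call is the natural
denominator for "this call is already annotated"), else NOVEL. Parents
with > 50 (mammal) or > 5 (other clades) assigned retrocopies *and* a
description containing "protein unknown" are flagged for review but
their calls are retained — automated flagging reproduces a candidate
list for manual screening, it does not delete evidence.

## Retrogenes from proteome self-alignments

Annotated coding genes of retropositional origin are found separately:
candidates are genes whose CDS is a single exon in *every* transcript;
alignments between isoforms of one gene are removed; per candidate the
best-scoring chain to a multi-exon gene is tested for aligned CDS
≥ 150 bp (50 aa), identity/coverage ≥ 50%, and ≥ 2 parental introns
strictly inside the aligned span of the parental protein after trimming
10 aa from each end of that span. The trim guards against spurious
terminal alignment fuzz manufacturing intron "spans". The plausible
alternative reading — excluding the parent's absolute terminal 10
residues — is available as `terminal_exclusion_mode="protein_ends"`.
"Aligned CDS" (not whole-candidate CDS) is tested for the 150 bp rule,
consistent with the retrocopy filter; the alternative is a one-line
change.

## ORF assessment

Conservation is judged inside the aligned region, in the parental
reading frame as propagated through the chain: every inter-block gap on
the retrocopy side whose length is not a multiple of 3 counts as one
frameshift event (two compensating shifts are two events — frame
restoration does not undo the damage), and every aligned codon
translating to a stop counts as one premature stop, with the frame
re-anchored at each block. `orf_conserved` ⇔ both counts are zero.
This is deliberately a *within-alignment* criterion; longest-ORF-based
definitions are a different question and out of scope.

## Expression evidence

Retrocopies are nearly identical to their parents, so evidence must be
copy-specific:

- **RNA-Seq**: only uniquely mapped reads count (NH tag = 1; when the
  aligner writes no NH tag, MAPQ ≥ 30 stands in — configurable).
  RPM = unique reads overlapping the locus by ≥ 1 aligned base /
  total mapped reads × 10⁶; expressed at RPM ≥ 1.0, inclusive, in any
  library (per-library OR).
- **EST**: an EST supports a retrocopy only if its hit there is
  ≥ 100 nt at ≥ 90% identity *and* strictly beats every other hit of
  that EST genome-wide on both score and identity; ties reject. This
  is what prevents parent-gene transcription from bleeding through.
- **Pol-II / CAGE TSS**: a feature associates with a retrocopy when it
  overlaps the strand-aware window from 1000 bp (peaks) or 500 bp
  (TSS) upstream of the 5' end down to 30% of the retrocopy body;
  windows are clipped at contig bounds.

Evidence flags are tri-state — True/False/None — so "no data supplied"
(grey) is never conflated with "assessed and negative" (red).

## Orthology

Retroposition of one parent recurs independently in different lineages,
so orthology is positional: each retrocopy is projected onto the
alignment columns of the whole-genome-alignment blocks it overlaps
(gap columns of its own row skipped; columns accumulate across blocks,
keyed by block). Two retrocopies from different species are linked when
`|A∩B|/|A| ≥ 0.5` and `|A∩B|/|B| ≥ 0.5`; groups are connected
components (single linkage), singletons dropped, ids assigned from the
lexicographically smallest member. Column space is the default because
the overlap is anchored "within alignment blocks"; a `bp` mode instead
divides the shared (both-ungapped) columns by each retrocopy's genomic
length.

## The synthetic data generator

`synthetic_fixtures` emulates the full input set with known truth: toy
genomes (random intergenic background; genes of 2–8 CDS exons with
GT..AG introns of 60–200 bp and valid ORFs, on random strands),
processed implants (spliced CDS copies, both strands, with
substitutions that never create in-frame stops, optional 1-bp
frameshift indels at separated codon boundaries, stop-codon injections
on interior codons, and 3'-truncation), negative controls
(intron-retaining full-gene duplicates and first-exon-only fragments),
and the *exact* alignment chains implied by each construction —
including parental self-alignments, which exercise the self-locus
exclusion. Expected outcomes are derived from the construction
arithmetic against the default thresholds, not by running the caller.

Defaults are the standard study conditions used throughout the tests:
20 genes, 15 processed implants at 5% nucleotide substitutions, 5
intron-retaining duplicates, 3 single-exon fragments, 4 implants
covered 60% by known-pseudogene annotations. Implants are spaced
2500–4000 bp apart (genes 300–800 bp): retrocopies land in gene-poor
regions, and this spacing keeps the 1000-bp promoter-association
windows of neighbouring retrocopies disjoint so each simulated peak or
TSS has a unique owner. Expression simulation plants NH:1 reads on 5
implants (enough for ≥ 1 RPM at the configured library size of 10⁶),
NH:5 multi-mappers on 2 further loci (which must not count), 3
validated + 1 tied (rejected) ESTs, and 3 peaks/TSS placed inside the
association windows with decoys far outside. The two-species generator
diverges only intergenic sequence (2%), ablates one implant in species
B and appends one B-only implant, and writes ungapped two-row MAF
blocks over the implant loci.

What the generator does **not** emulate — and hence what green tests do
not certify on real data: alignment noise from a real aligner
(truth chains are exact, so recall here is an upper bound), LINE
machinery such as target-site duplications and polyA tails (a polyA
flag exists but is cosmetic), sequencing error models, paralogous
gene families with cross-mapping reads, and gapped/rearranged
whole-genome alignments. Single randomness stream: every component
draws from `default_rng([seed, crc32(label)])`, so outputs are
byte-identical under a seed and adding one generator does not perturb
the others.

## Numerical and I/O choices

- Coordinates are 0-based half-open internally; GFF3 1-based inclusive
  on disk, BED half-open. All thresholds inclusive at the boundary
  ("at least" semantics).
- Chain blocks are stored in query order with plus-strand coordinates;
  PSL is written in the BLAT convention (blocks ascending in target,
  minus-strand query coordinates reversed). PSL carries no score
  column, so scores are derived as matches − mismatches on read; the
  generator emits the same convention, making round-trips exact.
- LAST tabular input carries no match count; identity from that source
  is an upper bound and should be recounted from sequence where the
  identity filter matters.
- Fragmented local hits of one query on one target strand are merged
  by `chain_colinear` when the genomic gap is ≤ 1000 bp and query
  order is preserved (hard-masking fragments a single retrocopy into
  several hits); the gap is configurable.
- Degenerate inputs: empty GFF3 → empty gene set; transcripts whose
  CDS is not a codon multiple are skipped with a warning; zero-length
  libraries, empty intron lists, empty column sets and unknown clade
  labels raise.

## Problem sizes

Tests and the acceptance script run on ~75 kb genomes with 20 genes and
23 implants (orthology on two-species pairs of 8 implants; window
association checked against a brute-force oracle on 1000 random pairs;
group construction against union-find on graphs up to n = 200). The
full suite completes in seconds; these sizes exercise every rule and
boundary while keeping runs instant.

## Known limitations

- One call per locus: overlapping retrocopies of different parents at
  one locus are resolved to the single best-scoring chain, as are
  tandem copies that touch by ≥ 1 bp.
- The ORF-conservation rule is the package's own within-alignment
  definition; databases using longest-ORF criteria will differ on
  damaged copies.
- EST validation assumes all genome-wide hits of an EST are provided;
  with partial hit lists the strictly-better rule cannot reject
  parent-derived ESTs it never sees.
- Orthology assumes the WGA blocks are trustworthy; no attempt is made
  to detect misalignment, and clade partitioning is the caller's
  responsibility (pass per-clade species sets separately).
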