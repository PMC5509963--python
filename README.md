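# retrofinder

Annotation of **retrocopies** — gene copies created by reverse
transcription of a spliced mRNA and reinsertion into the genome — from
protein-to-genome alignments, for genome annotators and researchers
studying gene duplication by retroposition.

A retrocopy is intronless relative to its multi-exon **parental gene**,
and that intron loss is the diagnostic signature this package detects.
Given alignment chains of parental proteins against a genome,
`retrofinder`:

- calls retrocopies with the filters: alignment length ≥ 150 bp,
  identity ≥ 50% and coverage ≥ 50% of the parental protein, and loss of
  ≥ 2 parental introns (an intron at protein offset ⌊k/3⌋ counts as lost
  when the genomic copy shows < 30 bp of inserted sequence there);
- labels calls **KNOWN_PSEUDOGENE** when annotated pseudogenes cover
  ≥ 50% of the locus, otherwise **NOVEL**, and flags parents with
  implausibly many retrocopies (> 50 for mammals, > 5 otherwise) that are
  annotated only as "protein unknown";
- identifies annotated single-exon-CDS genes of retropositional origin
  (**KNOWN_PROTEIN_CODING**) from proteome self-alignments: the best
  alignment to a multi-exon gene must cover ≥ 150 bp of CDS at ≥ 50%
  identity/coverage and span ≥ 2 parental introns after excluding 10
  amino acids at each end of the aligned span;
- reports ORF conservation: frameshifts (inter-block gaps with length
  mod 3 ≠ 0) and premature stop codons read in the parental frame;
- attaches expression evidence: RNA-Seq RPM from uniquely mapped reads
  (expressed at ≥ 1 RPM, inclusive), EST validation (≥ 100 nt, ≥ 90%
  identity, strictly better than every other hit of that EST genome-wide
  including the parent), and RNA-Pol-II peak / CAGE TSS association in a
  strand-aware window from 1000 / 500 bp upstream of the 5' end down to
  30% of the retrocopy body;
- groups retrocopies across species into ortholog groups from
  whole-genome-alignment blocks, linking retrocopies with ≥ 50%
  reciprocal overlap in alignment-column space and taking connected
  components.

A fully truth-annotated synthetic data generator
(`retrofinder.synthetic_fixtures`) builds toy genomes with implanted
retrocopies of known provenance, their exact alignment chains, simulated
reads/ESTs/peaks/TSS and two-species genome pairs with a MAF, so the
whole pipeline is testable without external aligners.

## Worked example

Generate a synthetic dataset and run the pipeline:

```sh
retrofinder simulate --seed 2 --out simout
cat > cfg.yaml <<EOF
genome_fasta: simout/genome.fa
gff3: simout/genes.gff3
psl: simout/alignments.psl
pseudo_bed: simout/pseudogenes.bed
outdir: runout
clade: mammal
species_prefix: HSAP
EOF
retrofinder run --config cfg.yaml
```

which prints

```
stage call: 43 chains -> 15 calls
stage orf: 15 conserved ORFs
wrote runout/retrocopies.tsv, .bed, .fa
```

The 43 input chains comprise 15 processed implants, 8 negative controls
(intron-retaining duplicates and single-exon fragments) and 20 parental
self-alignments; exactly the 15 true retrocopies survive the filters.
The first lines of `runout/retrocopies.tsv`:

```
retrocopy_id  chrom  start  end    strand  parental_gene  identity  coverage  aln_len_bp  introns_lost  status            flagged  frameshifts  premature_stops  orf_conserved
HSAP_00001    chr1   43177  43882  +       G008           0.86383   1.0       705         3             NOVEL             False    0            0                True
HSAP_00002    chr1   46419  47124  -       G008           0.876596  1.0       705         3             KNOWN_PSEUDOGENE  False    0            0                True
```

Each row is one called retrocopy: its locus, assigned parent, alignment
statistics against the parental protein, the number of parental introns
absent from the copy, its status against the known-pseudogene
annotation, and the ORF report. `retrocopies.bed` (BED12, one block per
alignment block) and `retrocopies.fa` (strand-corrected sequences)
mirror the table.

Other subcommands: `genes` (extract parental proteins), `stats`
(per-chain alignment statistics), `call`, `retrogenes`, `orf`,
`express`, `orthology`, `simulate` — see `retrofinder --help`.

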