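"""Intron-loss detection, filter boundaries, parent assignment, status."""

import dataclasses
import random

import pytest

from conftest import make_gene
from retrofinder.alignment_io import AlignmentBlock, AlignmentChain
from retrofinder.genome_model import GenomicInterval, protein_intron_positions
from retrofinder.retrocopy_caller import (
    IntronLossReport,
    RetrocopyCall,
    Thresholds,
    assign_parental,
    call_retrocopies,
    classify_status,
    detect_intron_loss,
    flag_suspicious_parents,
)
from retrofinder.synthetic_fixtures import FixtureSpec, generate_fixture

from test_alignment_io import make_chain


def three_exon_gene(gid="gP", exon_lens=(99, 150, 51)):
    """Parent with introns at aa 33 and 83 (for the default exon lengths)."""
    return make_gene(gid, list(exon_lens))


class TestDetectIntronLoss:
    def test_contiguous_chain_loses_both_introns(self):
        gene = three_exon_gene()
        introns = protein_intron_positions(gene.transcripts[0])
        chain = make_chain([(0, 5000, 100)], query_len=100)
        rep = detect_intron_loss(chain, introns)
        assert (rep.spanned, rep.lost, rep.retained) == ([0, 1], [0, 1], [])

    def test_target_gap_at_intron_counts_as_retained(self):
        gene = three_exon_gene()
        introns = protein_intron_positions(gene.transcripts[0])
        # 500 bp genomic gap exactly at intron 0 (aa 33); contiguous at intron 1
        chain = make_chain([(0, 5000, 33), (33, 5000 + 99 + 500, 67)], query_len=100)
        rep = detect_intron_loss(chain, introns)
        assert rep.lost == [1] and rep.retained == [0]

    def test_minus_strand_gap_measurement(self):
        gene = three_exon_gene()
        introns = protein_intron_positions(gene.transcripts[0])
        # same alignment mirrored onto the minus strand
        chain = make_chain(
            [(0, 5000 + 500 + 201, 33), (33, 5000, 67)], query_len=100, strand="-"
        )
        rep = detect_intron_loss(chain, introns)
        assert rep.lost == [1] and rep.retained == [0]

    def test_alignment_covering_one_exon_spans_nothing(self):
        gene = three_exon_gene()
        introns = protein_intron_positions(gene.transcripts[0])
        chain = make_chain([(0, 5000, 33)], query_len=100)
        rep = detect_intron_loss(chain, introns)
        assert rep.spanned == []

    def test_small_gap_below_cutoff_is_lost(self):
        gene = three_exon_gene()
        introns = protein_intron_positions(gene.transcripts[0])
        chain = make_chain([(0, 5000, 33), (33, 5000 + 99 + 29, 67)], query_len=100)
        assert detect_intron_loss(chain, introns).lost == [0, 1]
        chain30 = make_chain([(0, 5000, 33), (33, 5000 + 99 + 30, 67)], query_len=100)
        assert detect_intron_loss(chain30, introns).lost == [1]

    def test_empty_intron_list_errors(self):
        with pytest.raises(ValueError):
            detect_intron_loss(make_chain([(0, 0, 10)]), [])


class TestFilterBoundaries:
    """The call flips exactly at 150 bp, 50% identity, 50% coverage and
    2 lost introns."""

    def _call(self, chain, gene):
        return call_retrocopies([chain], [gene])

    def test_alignment_length_150bp_cut(self):
        # protein 66 aa, introns at aa 20 and 40; chain aligned from aa 0
        gene = make_gene("gP", [60, 60, 78])
        short = make_chain([(0, 5000, 49)], query_len=66, query_id="gP.T1")
        exact = make_chain([(0, 5000, 50)], query_len=66, query_id="gP.T1")
        assert self._call(short, gene) == []
        assert len(self._call(exact, gene)) == 1

    def test_identity_50pct_cut(self):
        gene = make_gene("gP", [1000, 1000, 1000])  # introns at aa 333, 666
        below = make_chain([(0, 5000, 1000)], query_len=1000, matches=499,
                           query_id="gP.T1")
        at = make_chain([(0, 5000, 1000)], query_len=1000, matches=500,
                        query_id="gP.T1")
        assert self._call(below, gene) == []
        assert len(self._call(at, gene)) == 1

    def test_coverage_50pct_cut(self):
        gene = make_gene("gP", [1000, 1000, 1000])
        below = make_chain([(200, 5000, 499)], query_len=1000, query_id="gP.T1")
        at = make_chain([(200, 5000, 500)], query_len=1000, query_id="gP.T1")
        assert self._call(below, gene) == []
        assert len(self._call(at, gene)) == 1

    def test_two_lost_introns_required(self):
        gene = three_exon_gene("gP")
        one_lost = make_chain(
            [(0, 5000, 83), (83, 5000 + 3 * 83 + 500, 17)], query_len=100,
            query_id="gP.T1",
        )
        two_lost = make_chain([(0, 5000, 100)], query_len=100, query_id="gP.T1")
        assert self._call(one_lost, gene) == []
        assert len(self._call(two_lost, gene)) == 1

    def test_chain_over_parental_locus_is_discarded(self):
        gene = three_exon_gene("gP")
        span = gene.span()
        chain = make_chain(
            [(0, span.start, 100)], query_len=100, query_id="gP.T1",
            target_id=span.seq_id,
        )
        assert self._call(chain, gene) == []


class TestAssignParental:
    def test_higher_score_wins(self):
        a = make_chain([(0, 0, 100)], score=200)
        b = make_chain([(0, 0, 100)], score=180)
        assert assign_parental([(a, "gA"), (b, "gB")])[1] == "gA"

    def test_score_tie_breaks_by_identity_then_coverage_then_id(self):
        hi = make_chain([(0, 0, 100)], matches=90, score=100, query_len=100)
        lo = make_chain([(0, 0, 100)], matches=80, score=100, query_len=100)
        assert assign_parental([(lo, "gA"), (hi, "gB")])[1] == "gB"
        same1 = make_chain([(0, 0, 100)], matches=90, score=100, query_len=100)
        same2 = make_chain([(0, 0, 100)], matches=90, score=100, query_len=100)
        assert assign_parental([(same2, "gB"), (same1, "gA")])[1] == "gA"

    def test_choice_is_order_invariant(self):
        chains = [
            (make_chain([(0, 0, 100)], matches=90, score=100, query_len=100), g)
            for g in ("gC", "gA", "gB")
        ]
        winners = set()
        rng = random.Random(0)
        for _ in range(10):
            rng.shuffle(chains)
            winners.add(assign_parental(chains)[1])
        assert winners == {"gA"}


def make_call(start=10_000, end=11_000, strand="+"):
    return RetrocopyCall(
        retrocopy_id="RC_1",
        locus=GenomicInterval("chr1", start, end, strand),
        parental_gene_id="gP",
        stats=None,
        loss=IntronLossReport([0, 1], [0, 1], []),
    )


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "covered,expected",
        [(510, "KNOWN_PSEUDOGENE"), (490, "NOVEL"), (500, "KNOWN_PSEUDOGENE")],
    )
    def test_50pct_overlap_rule_inclusive(self, covered, expected):
        call = make_call(10_000, 11_000)
        pseudo = [GenomicInterval("chr1", 10_000, 10_000 + covered, "+")]
        assert classify_status(call, pseudo) == expected

    def test_union_of_overlapping_annotations(self):
        call = make_call(10_000, 11_000)
        pseudo = [
            GenomicInterval("chr1", 10_000, 10_300, "+"),
            GenomicInterval("chr1", 10_200, 10_500, "+"),  # union = 500
        ]
        assert classify_status(call, pseudo) == "KNOWN_PSEUDOGENE"


class TestFlagSuspiciousParents:
    def _calls(self, parent, n):
        return [
            dataclasses.replace(make_call(10_000 + 2000 * i, 11_000 + 2000 * i),
                                parental_gene_id=parent)
            for i in range(n)
        ]

    def test_mammal_51_unknown_flagged(self):
        gene = make_gene("gP", [99, 150, 51], description="protein unknown")
        calls = self._calls("gP", 51)
        assert flag_suspicious_parents(calls, [gene], "mammal") == {"gP"}
        assert all(c.flagged for c in calls)

    def test_described_protein_never_flagged(self):
        gene = make_gene("gP", [99, 150, 51], description="kinase, well studied")
        calls = self._calls("gP", 51)
        assert flag_suspicious_parents(calls, [gene], "mammal") == set()

    def test_non_mammal_cutoff_is_5(self):
        gene = make_gene("gP", [99, 150, 51], description="Protein Unknown")
        assert flag_suspicious_parents(self._calls("gP", 6), [gene], "other") == {"gP"}
        assert flag_suspicious_parents(self._calls("gP", 5), [gene], "other") == set()

    def test_unknown_clade_errors(self):
        with pytest.raises(ValueError):
            flag_suspicious_parents([], [], "fungal")


class TestOnSyntheticTruth:
    def test_recall_and_parent_assignment_complete(self, default_fixture):
        calls = call_retrocopies(
            default_fixture.chains,
            default_fixture.genes,
            default_fixture.known_pseudogenes,
        )
        expected = [t for t in default_fixture.truth if t.expected_call]
        assert len(calls) == len(expected)
        for call in calls:
            rec = [t for t in expected if t.locus.overlaps(call.locus)]
            assert len(rec) == 1
            assert rec[0].source_gene_id == call.parental_gene_id
            assert rec[0].expected_status == call.status

    def test_negative_controls_produce_no_calls(self, default_fixture):
        calls = call_retrocopies(
            default_fixture.chains, default_fixture.genes
        )
        negatives = [t for t in default_fixture.truth if not t.expected_call]
        assert negatives, "fixture must contain negative controls"
        for rec in negatives:
            assert not any(c.locus.overlaps(rec.locus) for c in calls)

    def test_raising_any_threshold_never_increases_calls(self, default_fixture):
        base = Thresholds()
        n_base = len(call_retrocopies(default_fixture.chains, default_fixture.genes,
                                      thresholds=base))
        tighter = [
            Thresholds(min_aln_bp=400),
            Thresholds(min_identity=0.9),
            Thresholds(min_coverage=0.95),
            Thresholds(min_lost_introns=4),
        ]
        for thr in tighter:
            n = len(call_retrocopies(default_fixture.chains, default_fixture.genes,
                                     thresholds=thr))
            assert n <= n_base

    def test_output_invariant_under_chain_permutation(self, default_fixture):
        ref = call_retrocopies(default_fixture.chains, default_fixture.genes,
                               default_fixture.known_pseudogenes)
        rng = random.Random(7)
        for _ in range(3):
            shuffled = list(default_fixture.chains)
            rng.shuffle(shuffled)
            alt = call_retrocopies(shuffled, default_fixture.genes,
                                   default_fixture.known_pseudogenes)
            assert [
                (c.retrocopy_id, c.locus, c.parental_gene_id, c.status)
                for c in alt
            ] == [
                (c.retrocopy_id, c.locus, c.parental_gene_id, c.status)
                for c in ref
            ]

    def test_truncated_copies_below_half_coverage_rejected(self):
        spec = FixtureSpec(seed=21, n_retrocopies=6,
                           truncation_fraction_range=(0.6, 0.6),
                           n_intron_retaining=0, n_single_exon_fragments=0)
        fx = generate_fixture(spec)
        processed = [t for t in fx.truth if t.kind == "processed"]
        assert all(not t.expected_call for t in processed)
        calls = call_retrocopies(fx.chains, fx.genes)
        assert calls == []
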