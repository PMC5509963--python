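"""Unique-read counting, RPM, EST best-hit validation, window association."""

import numpy as np
import pysam
import pytest

from retrofinder.alignment_io import AlignmentBlock, AlignmentChain
from retrofinder.expression_evidence import (
    EvidenceWindows,
    EstValidation,
    associate_signal,
    association_window,
    compute_rpm,
    count_unique_reads,
    is_expressed_rpm,
    merge_evidence,
    validate_est,
)
from retrofinder.genome_model import GenomicInterval


def make_bam(path, reads, ref_len=50_000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, pos, nh, mapq, flag in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = "A" * 100
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = "100M"
            a.flag = flag
            if nh is not None:
                a.set_tag("NH", nh)
            bam.write(a)
    pysam.index(str(path))


class TestCountUniqueReads:
    LOCUS = GenomicInterval("chr1", 10_000, 11_000, "+")

    def test_nh_tag_filters_multimappers(self, tmp_path):
        bam = tmp_path / "a.bam"
        reads = [(f"u{i}", 10_100 + i * 10, 1, 60, 0) for i in range(3)]
        reads += [(f"m{i}", 10_200 + i * 10, 5, 0, 0) for i in range(2)]
        make_bam(bam, reads)
        assert count_unique_reads(str(bam), self.LOCUS) == 3

    def test_read_abutting_half_open_end_not_counted(self, tmp_path):
        bam = tmp_path / "a.bam"
        make_bam(bam, [("edge", 11_000, 1, 60, 0), ("in", 10_999, 1, 60, 0)])
        assert count_unique_reads(str(bam), self.LOCUS) == 1

    def test_mapq_fallback_without_nh(self, tmp_path):
        bam = tmp_path / "a.bam"
        make_bam(bam, [("hi", 10_100, None, 60, 0), ("lo", 10_200, None, 5, 0)])
        assert count_unique_reads(str(bam), self.LOCUS) == 1

    def test_secondary_records_excluded(self, tmp_path):
        bam = tmp_path / "a.bam"
        make_bam(bam, [("p", 10_100, 1, 60, 0), ("s", 10_200, 1, 60, 256)])
        assert count_unique_reads(str(bam), self.LOCUS) == 1

    def test_count_matches_linear_scan_oracle(self, tmp_path):
        rng = np.random.default_rng(11)
        reads = []
        for i in range(200):
            pos = int(rng.integers(5_000, 15_000))
            nh = int(rng.choice([1, 1, 2, 5]))
            reads.append((f"r{i}", pos, nh, 60, 0))
        bam = tmp_path / "a.bam"
        make_bam(bam, reads)
        expected = sum(
            1 for _, pos, nh, _, _ in reads
            if nh == 1 and pos < 11_000 and pos + 100 > 10_000
        )
        assert count_unique_reads(str(bam), self.LOCUS) == expected

    def test_unindexed_input_errors(self, tmp_path):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 50_000}]}
        sam = tmp_path / "a.sam"
        with pysam.AlignmentFile(str(sam), "w", header=header):
            pass
        with pytest.raises(ValueError):
            count_unique_reads(str(sam), self.LOCUS)


class TestComputeRpm:
    @pytest.mark.parametrize(
        "count,total,rpm,expressed",
        [(10, 5_000_000, 2.0, True), (4, 5_000_000, 0.8, False),
         (5, 5_000_000, 1.0, True)],
    )
    def test_rpm_arithmetic_and_inclusive_threshold(self, count, total, rpm, expressed):
        value = compute_rpm(count, total)
        assert value == pytest.approx(rpm)
        assert is_expressed_rpm(value) is expressed

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            compute_rpm(5, 0)

    def test_linear_in_count_and_inverse_in_depth(self):
        assert compute_rpm(20, 1_000_000) == 2 * compute_rpm(10, 1_000_000)
        assert compute_rpm(10, 2_000_000) == compute_rpm(10, 1_000_000) / 2


def est_hit(target_start, length, matches, target_id="chr1", est="E1", qlen=300):
    return AlignmentChain(
        query_id=est, query_len=qlen, target_id=target_id, target_len=1_000_000,
        strand="+", blocks=[AlignmentBlock(0, target_start, length)],
        matches=matches, score=2 * matches - length, protein_query=False,
    )


class TestValidateEst:
    LOCUS = GenomicInterval("chr1", 10_000, 11_000, "+")

    def test_strictly_better_hit_accepted(self):
        retro = est_hit(10_100, 120, 114)      # 95% id, score 108
        parent = est_hit(50_000, 120, 108)     # 90% id, score 96
        assert validate_est([retro, parent], self.LOCUS).accepted

    def test_short_hit_rejected(self):
        retro = est_hit(10_100, 99, 95)
        assert not validate_est([retro], self.LOCUS).accepted

    def test_low_identity_rejected(self):
        retro = est_hit(10_100, 200, 178)  # 89%
        assert not validate_est([retro], self.LOCUS).accepted

    def test_score_tie_with_parent_rejected(self):
        retro = est_hit(10_100, 120, 114)
        parent = est_hit(50_000, 120, 114)
        res = validate_est([retro, parent], self.LOCUS)
        assert not res.accepted
        assert "better or equal" in res.reason

    def test_parent_outscores_rejected(self):
        retro = est_hit(10_100, 120, 114)
        parent = est_hit(50_000, 150, 148)
        assert not validate_est([retro, parent], self.LOCUS).accepted

    def test_no_hit_on_locus_rejected(self):
        assert not validate_est([est_hit(50_000, 120, 114)], self.LOCUS).accepted


class TestAssociateSignal:
    def test_tss_window_examples(self):
        locus = GenomicInterval("chr1", 10_000, 12_000, "+")
        inside = [GenomicInterval("chr1", 9_600, 9_610, "+")]
        outside = [GenomicInterval("chr1", 9_400, 9_410, "+")]
        past_body = [GenomicInterval("chr1", 10_700, 10_710, "+")]
        assert associate_signal(locus, inside, 500, 0.30)[0]
        assert not associate_signal(locus, outside, 500, 0.30)[0]
        assert not associate_signal(locus, past_body, 500, 0.30)[0]

    def test_boundary_at_499_vs_501_bp_upstream(self):
        locus = GenomicInterval("chr1", 10_000, 12_000, "+")
        at_499 = [GenomicInterval("chr1", 9_501, 9_502, "+")]
        at_501 = [GenomicInterval("chr1", 9_498, 9_499, "+")]
        assert associate_signal(locus, at_499, 500, 0.30)[0]
        assert not associate_signal(locus, at_501, 500, 0.30)[0]

    def test_minus_strand_window_mirrored(self):
        locus = GenomicInterval("chr1", 10_000, 12_000, "-")
        upstream = [GenomicInterval("chr1", 12_300, 12_310, "+")]
        wrong_side = [GenomicInterval("chr1", 9_600, 9_610, "+")]
        assert associate_signal(locus, upstream, 500, 0.30)[0]
        assert not associate_signal(locus, wrong_side, 500, 0.30)[0]

    @pytest.mark.parametrize("upstream", [1000, 500])
    def test_agrees_with_brute_force_overlap_oracle(self, upstream):
        rng = np.random.default_rng(23)
        n_hits = 0
        for _ in range(1000):
            start = int(rng.integers(2_000, 90_000))
            length = int(rng.integers(200, 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            locus = GenomicInterval("chr1", start, start + length, strand)
            fs = int(rng.integers(0, 95_000))
            feature = GenomicInterval("chr1", fs, fs + int(rng.integers(10, 400)), "+")
            got, _ = associate_signal(locus, [feature], upstream, 0.30)
            # oracle: explicit interval arithmetic, built independently
            body = int(length * 0.30)
            if strand == "+":
                wlo, whi = start - upstream, start + body
            else:
                wlo, whi = (start + length) - body, (start + length) + upstream
            wlo = max(0, wlo)
            expected = feature.start < whi and feature.end > wlo
            assert got == expected
            n_hits += got
        assert 0 < n_hits < 1000  # both outcomes exercised


class TestMergeEvidence:
    def test_missing_source_is_not_assessed(self):
        bundle = merge_evidence(rpm_by_library={"lib1": 2.0}, est_validations=None)
        assert bundle.rnaseq_expressed is True
        assert bundle.est_expressed is None

    def test_all_negative_sources(self):
        bundle = merge_evidence(
            rpm_by_library={"lib1": 0.2},
            est_validations=[EstValidation(False, "tie", "E1")],
            polII=False, tss=False,
        )
        assert bundle.rnaseq_expressed is False
        assert bundle.est_expressed is False
        assert bundle.polII is False and bundle.tss is False

    def test_flags_equal_recomputation_from_raw(self):
        rpms = {"a": 0.4, "b": 1.7}
        vals = [EstValidation(True, "best", "E1"), EstValidation(False, "x", "E2")]
        bundle = merge_evidence(rpm_by_library=rpms, est_validations=vals,
                                polII=True, tss=False)
        assert bundle.rnaseq_expressed == any(v >= 1.0 for v in rpms.values())
        assert bundle.est_ids == ["E1"]
        assert bundle.est_expressed is True

    def test_multi_library_or_semantics(self):
        assert merge_evidence({"a": 0.4, "b": 0.5}).rnaseq_expressed is False
        assert merge_evidence({"a": 0.4, "b": 1.0}).rnaseq_expressed is True


class TestOnSimulatedExpression:
    def test_simulated_reads_reproduce_expected_flags(
        self, default_fixture, expression_sim, tmp_path
    ):
        sam = tmp_path / "r.sam"
        bam = tmp_path / "r.bam"
        sam.write_text(expression_sim.sam_text)
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        total = next(iter(expression_sim.library_totals.values()))
        for rec in default_fixture.truth:
            if rec.kind != "processed":
                continue
            n = count_unique_reads(str(bam), rec.locus)
            assert is_expressed_rpm(compute_rpm(n, total)) == \
                expression_sim.expected_rnaseq[rec.implant_id]

    def test_simulated_est_and_windows_reproduce_expected_flags(
        self, default_fixture, expression_sim
    ):
        w = EvidenceWindows()
        for rec in default_fixture.truth:
            if rec.kind != "processed":
                continue
            est = any(
                validate_est(hits, rec.locus).accepted
                for hits in expression_sim.est_hits.values()
            )
            assert est == expression_sim.expected_est[rec.implant_id]
            pol, _ = associate_signal(rec.locus, expression_sim.polII_peaks,
                                      w.polII_upstream, w.body_fraction)
            tss, _ = associate_signal(rec.locus, expression_sim.tss_sites,
                                      w.tss_upstream, w.body_fraction)
            assert pol == expression_sim.expected_polII[rec.implant_id]
            assert tss == expression_sim.expected_tss[rec.implant_id]
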