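"""Arbitration semantics: evidence building, priority rules, partitioning."""

from __future__ import annotations

import itertools

import pytest

from homeoseq import synth
from homeoseq.assign import (
    AlignmentRecord,
    FragmentEvidence,
    Outcome,
    Rule,
    Status,
    arbitrate,
    assignment_accuracy,
    mapping_ratio,
    partition_library,
    summarize_fragment,
)


def rec(mate, sub, mapped=True, mapq=40, nh=1):
    if not mapped:
        return AlignmentRecord("r1", mate, sub, mapped=False)
    return AlignmentRecord(
        "r1", mate, sub, mapped=True, pos=10, mapq=mapq, n_best_hits=nh
    )


class TestSummarize:
    def test_pair_on_one_side_only(self):
        ev_a, ev_b = summarize_fragment(
            [rec(1, "A", mapq=40), rec(2, "A", mapq=35)], []
        )
        assert (ev_a.status, ev_a.mqs_sum) == (Status.PAIR, 75)
        assert (ev_b.status, ev_b.mqs_sum) == (Status.UNMAPPED, 0)

    def test_ambiguous_singleton(self):
        _, ev_b = summarize_fragment([], [rec(1, "B", mapq=30, nh=3)])
        assert ev_b.status is Status.SINGLETON
        assert ev_b.mqs_sum == 30
        assert not ev_b.unique

    def test_nothing_mapped_anywhere(self):
        ev_a, ev_b = summarize_fragment(
            [rec(1, "A", mapped=False)], [rec(1, "B", mapped=False)]
        )
        assert ev_a.status is Status.UNMAPPED
        assert ev_b.status is Status.UNMAPPED

    def test_mixed_read_ids_rejected(self):
        other = AlignmentRecord("r2", 1, "A", True, pos=1, mapq=9, n_best_hits=1)
        with pytest.raises(ValueError, match="read id"):
            summarize_fragment([rec(1, "A"), other], [])

    def test_duplicate_primary_for_mate_rejected(self):
        with pytest.raises(ValueError, match="duplicate primary"):
            summarize_fragment([rec(1, "A"), rec(1, "A")], [])


def ev(sub, status, mqs, unique=True):
    return FragmentEvidence("r1", sub, status, mqs, unique)


class TestArbitrate:
    def test_pair_beats_singleton_regardless_of_score(self):
        d = arbitrate(
            ev("A", Status.PAIR, 70), ev("B", Status.SINGLETON, 55)
        )
        assert (d.outcome, d.deciding_rule) == (Outcome.ASSIGN_A, Rule.PAIR_PRIORITY)

    def test_unique_beats_ambiguous_regardless_of_score(self):
        d = arbitrate(
            ev("A", Status.PAIR, 120, unique=False),
            ev("B", Status.PAIR, 80, unique=True),
        )
        assert (d.outcome, d.deciding_rule) == (Outcome.ASSIGN_B, Rule.UNIQUE_PRIORITY)

    def test_equal_evidence_is_discarded(self):
        d = arbitrate(ev("A", Status.PAIR, 80), ev("B", Status.PAIR, 80))
        assert d.outcome is Outcome.DISCARD_TIE

    def test_higher_mqs_wins_final_tiebreak(self):
        d = arbitrate(ev("A", Status.PAIR, 60), ev("B", Status.PAIR, 90))
        assert (d.outcome, d.deciding_rule) == (Outcome.ASSIGN_B, Rule.MQS)

    def test_one_side_only_is_assigned_by_presence(self):
        d = arbitrate(
            ev("A", Status.SINGLETON, 20, unique=False),
            ev("B", Status.UNMAPPED, 0, unique=False),
        )
        assert (d.outcome, d.deciding_rule) == (Outcome.ASSIGN_A, Rule.ONLY_ONE)

    def test_matches_exhaustive_rule_interpreter(self):
        """arbitrate agrees with a naive rule-by-rule oracle on all cases."""
        def oracle(a, b):
            # independent re-statement of the decision procedure
            if a.status is Status.UNMAPPED and b.status is Status.UNMAPPED:
                return Outcome.UNMAPPED
            if b.status is Status.UNMAPPED:
                return Outcome.ASSIGN_A
            if a.status is Status.UNMAPPED:
                return Outcome.ASSIGN_B
            ka = (int(a.status), int(a.unique), a.mqs_sum)
            kb = (int(b.status), int(b.unique), b.mqs_sum)
            if ka == kb:
                return Outcome.DISCARD_TIE
            return Outcome.ASSIGN_A if ka > kb else Outcome.ASSIGN_B

        statuses = [Status.PAIR, Status.SINGLETON, Status.UNMAPPED]
        n = 0
        for sa, ua, ma, sb, ub, mb in itertools.product(
            statuses, (True, False), (0, 30, 60), repeat=2
        ):
            ma_eff = 0 if sa is Status.UNMAPPED else ma
            mb_eff = 0 if sb is Status.UNMAPPED else mb
            a = ev("A", sa, ma_eff, ua)
            b = ev("B", sb, mb_eff, ub)
            assert arbitrate(a, b).outcome == oracle(a, b)
            n += 1
        assert n == 324

    def test_swapping_sides_swaps_assignments(self):
        statuses = [Status.PAIR, Status.SINGLETON, Status.UNMAPPED]
        swap = {Outcome.ASSIGN_A: Outcome.ASSIGN_B,
                Outcome.ASSIGN_B: Outcome.ASSIGN_A}
        for sa, ua, ma, sb, ub, mb in itertools.product(
            statuses, (True, False), (0, 30, 60), repeat=2
        ):
            ma_eff = 0 if sa is Status.UNMAPPED else ma
            mb_eff = 0 if sb is Status.UNMAPPED else mb
            fwd = arbitrate(ev("A", sa, ma_eff, ua), ev("B", sb, mb_eff, ub))
            rev = arbitrate(ev("A", sb, mb_eff, ub), ev("B", sa, ma_eff, ua))
            assert rev.outcome == swap.get(fwd.outcome, fwd.outcome)


class TestMappingRatio:
    @pytest.mark.parametrize(
        "mapped,clean,expected",
        [
            (17_586_172, 22_088_185, 79.6),
            (13_102_552, 22_088_185, 59.3),
            (0, 1000, 0.0),
        ],
    )
    def test_percent_rounding(self, mapped, clean, expected):
        assert mapping_ratio(mapped, clean) == expected

    def test_zero_clean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mapping_ratio(10, 0)


class TestPartition:
    def test_partition_is_exhaustive(self, small_partition):
        decisions, stats, _ = small_partition
        assert (
            stats.assigned_a + stats.assigned_b + stats.ties + stats.unmapped
            == stats.total_fragments
            == len(decisions)
        )

    def test_swapping_inputs_swaps_counts(self, small_sams):
        sam_a, sam_b, _ = small_sams
        _, fwd = partition_library(sam_a, sam_b)
        _, rev = partition_library(sam_b, sam_a)
        assert rev.assigned_a == fwd.assigned_b
        assert rev.assigned_b == fwd.assigned_a
        assert rev.ties == fwd.ties
        assert rev.unmapped == fwd.unmapped

    def test_assignments_track_truth_origin(self, small_partition):
        decisions, _, truth = small_partition
        acc, n_assigned = assignment_accuracy(decisions, truth.read_origin)
        assert n_assigned > 0.8 * len(decisions)
        assert acc >= 0.95

    def test_unique_only_never_assigns_on_ambiguous_evidence(self, tmp_path):
        # duplicated contig: every A-side hit is ambiguous (NH = 2)
        rng_seq = "ACGTTGCA" * 40
        ref_a = {"dupA1": rng_seq, "dupA2": rng_seq}
        ref_b = {"uniqB": "TTGACGTC" * 40}
        read = ("frag1", rng_seq[10:111], [35] * 101)
        aln_a = synth.fixture_align([read], ref_a)
        aln_b = synth.fixture_align([read], ref_b)
        sam_a, sam_b = tmp_path / "a.sam", tmp_path / "b.sam"
        synth.write_sam(aln_a, ref_a, sam_a)
        synth.write_sam(aln_b, ref_b, sam_b)
        decisions, _ = partition_library(sam_a, sam_b, unique_only=True)
        # the only evidence is ambiguous, so the fragment must not be assigned
        assert decisions["frag1"].outcome in (
            Outcome.UNMAPPED, Outcome.DISCARD_TIE
        )

    def test_empty_b_side_assigns_everything_to_a(self, small_sams, tmp_path):
        sam_a, _, _ = small_sams
        import pysam

        with pysam.AlignmentFile(str(sam_a), check_sq=False) as fh:
            header = fh.header
        empty_b = tmp_path / "empty_b.sam"
        pysam.AlignmentFile(str(empty_b), "w", header=header).close()
        decisions, stats = partition_library(sam_a, empty_b)
        assert stats.assigned_b == 0
        assert stats.ratio_b() == 0.0
        assert all(
            d.outcome in (Outcome.ASSIGN_A, Outcome.UNMAPPED)
            for d in decisions.values()
        )

    def test_identical_subgenomes_force_ties(self, tmp_path):
        cfg = synth.SimConfig(
            n_genes=20, reads_per_library=150, homoeolog_divergence=0.0,
            seq_error_rate=0.0, rng_seed=21,
        )
        (ref_a, ref_b), _, libraries, _, _, _, _ = synth.simulate_study(cfg)
        pairs = libraries["wild_1"]
        sam_a, sam_b = tmp_path / "a.sam", tmp_path / "b.sam"
        synth.write_sam(synth.fixture_align(pairs, ref_a), ref_a, sam_a)
        synth.write_sam(synth.fixture_align(pairs, ref_b), ref_b, sam_b)
        _, stats = partition_library(sam_a, sam_b)
        assert stats.ties == stats.total_fragments

    def test_unsorted_input_rejected(self, tmp_path):
        ref = {"t": "ACGTACGTAA" * 30}
        reads = [
            ("rA", ref["t"][0:101], [30] * 101),
            ("rB", ref["t"][50:151], [30] * 101),
        ]
        aln = synth.fixture_align(reads, ref)
        sam = tmp_path / "bad.sam"
        synth.write_sam(aln, ref, sam)
        # re-append the first record so rA reappears after rB
        lines = sam.read_text().splitlines()
        body = [ln for ln in lines if not ln.startswith("@")]
        sam.write_text("\n".join(lines + [body[0]]) + "\n")
        with pytest.raises(ValueError, match="name-grouped"):
            partition_library(sam, sam)
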