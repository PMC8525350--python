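import numpy as np
import pytest
from Bio import Align

from crispramp.calling import (
    Scoring, align_to_reference, apply_support_filter, call_reads,
    extract_events, filter_position, left_align_indels,
)
from crispramp.prep import MergedRead
from crispramp.simulate import (
    DELETION, DELIN, INSERTION, WT,
    EditOutcome, SimScenario, apply_edit, canonicalize_edit, simulate_run,
)

from _oracles import canonical_event_sets, optimal_score
from conftest import random_seq, toy_target


def chain_events(read: str, target) -> list[EditOutcome]:
    aln = left_align_indels(align_to_reference(read, target))
    return extract_events(aln)


def _biopython_score(read: str, ref: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -1
    return float(aligner.score(ref, read))


class TestAlignment:
    def test_identity_alignment(self, nco_target):
        aln = align_to_reference(nco_target.ref_seq, nco_target)
        assert aln.score == 2 * len(nco_target.ref_seq)
        assert aln.ops == [("M", 0, 283, 0, 283)]

    def test_single_deletion_yields_one_op(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 28)
        target = toy_target(ref)
        read = ref[:11] + ref[12:]
        aln = align_to_reference(read, target)
        dels = [op for op in aln.ops if op[0] == "D"]
        assert len(dels) == 1 and dels[0][2] - dels[0][1] == 1
        assert aln.score == optimal_score(read, ref)

    def test_two_base_insertion_yields_one_op(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 28)
        target = toy_target(ref)
        read = ref[:14] + "TT" + ref[14:]
        aln = align_to_reference(read, target)
        ins = [op for op in aln.ops if op[0] == "I"]
        assert len(ins) == 1 and ins[0][4] - ins[0][3] == 2
        assert aln.score == optimal_score(read, ref)

    def test_score_matches_exhaustive_dp_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            ref = random_seq(rng, int(rng.integers(8, 24)))
            read = random_seq(rng, int(rng.integers(5, 24)))
            aln = align_to_reference(read, toy_target(ref), Scoring())
            assert aln.score == optimal_score(read, ref)

    def test_score_matches_biopython_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            ref = random_seq(rng, int(rng.integers(20, 80)))
            read = random_seq(rng, int(rng.integers(15, 80)))
            aln = align_to_reference(read, toy_target(ref))
            assert aln.score == _biopython_score(read, ref)

    def test_ops_tile_reference_and_read(self):
        rng = np.random.default_rng(4)
        ref = random_seq(rng, 40)
        target = toy_target(ref)
        for _ in range(20):
            read = random_seq(rng, int(rng.integers(20, 50)))
            ops = align_to_reference(read, target).ops
            rpos = qpos = 0
            for op, rs, re_, qs, qe in ops:
                assert rs == rpos and qs == qpos
                rpos, qpos = re_, qe
            assert rpos == len(ref) and qpos == len(read)


class TestLeftAlign:
    def test_homopolymer_deletion_shifts_to_run_start(self):
        target = toy_target("GCAAATGG")
        read = "GCAATGG"  # one A of the run deleted
        aln = left_align_indels(align_to_reference(read, target))
        events = extract_events(aln)
        assert events == [EditOutcome(DELETION, 2, 3)]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        ref = random_seq(rng, 30)
        target = toy_target(ref)
        for _ in range(25):
            pos = int(rng.integers(1, 28))
            read = ref[:pos] + ref[pos + 1 :]
            once = left_align_indels(align_to_reference(read, target))
            twice = left_align_indels(once)
            assert (once.ref_row, once.read_row) == (twice.ref_row, twice.read_row)

    def test_equivalent_gap_placements_collapse(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ref = random_seq(rng, 20)
            target = toy_target(ref)
            pos = int(rng.integers(1, 19))
            read = ref[:pos] + ref[pos + 1 :]  # delete ref[pos]
            got = chain_events(read, target)
            expect = canonicalize_edit(ref, EditOutcome(DELETION, pos, pos + 1))
            assert got == [expect]


class TestExtractEvents:
    def test_all_match_is_wt(self, nco_target):
        assert chain_events(nco_target.ref_seq, nco_target) == []

    def test_mixed_run_is_delin(self):
        ref = "AACCGGTTACGTACGT"
        target = toy_target(ref)
        # delete 2 bases and insert 3 unrelated ones at the same spot
        read = ref[:6] + "AAA" + ref[8:]
        events = chain_events(read, target)
        assert [e.klass for e in events] == [DELIN]
        e = events[0]
        assert (e.ref_end - e.ref_start, len(e.ins_seq)) == (2, 3)

    def test_substitution_only_run_discarded(self, nco_target):
        read = list(nco_target.ref_seq)
        read[150] = "A" if read[150] != "A" else "C"
        assert chain_events("".join(read), nco_target) == []


class TestPositionFilter:
    def test_boundary_is_strict(self, nco_target):
        fwd_end = nco_target.fwd_primer[1]
        rev_start = nco_target.rev_primer[0]
        inside = EditOutcome(DELETION, fwd_end + 6, fwd_end + 7)
        assert filter_position(inside, nco_target)
        at_start_margin = EditOutcome(DELETION, fwd_end + 5, fwd_end + 6)
        assert not filter_position(at_start_margin, nco_target)
        at_end_margin = EditOutcome(DELETION, rev_start - 6, rev_start - 5)
        assert not filter_position(at_end_margin, nco_target)
        assert filter_position(
            EditOutcome(DELETION, rev_start - 7, rev_start - 6), nco_target
        )

    def test_cut_site_event_passes(self, nco_target):
        cut = nco_target.cut_pos
        assert filter_position(
            EditOutcome(INSERTION, cut, cut, "A"), nco_target
        )

    def test_rejects_wt(self, nco_target):
        with pytest.raises(ValueError):
            filter_position(EditOutcome(WT), nco_target)


class TestSupportFilter:
    del_sig = EditOutcome(DELETION, 100, 103)
    ins_sig = EditOutcome(INSERTION, 120, 120, "A")

    def test_singleton_removed_and_read_reverts_to_wt(self):
        events, calls = apply_support_filter({"r1": [self.del_sig]})
        assert events == []
        assert calls[0].klass == WT and calls[0].events == ()

    def test_pair_of_reads_retained(self):
        events, calls = apply_support_filter(
            {"r1": [self.del_sig], "r2": [self.del_sig]}
        )
        assert len(events) == 1 and events[0].support == 2
        assert all(c.klass == DELETION for c in calls)

    def test_shared_deletion_plus_unique_insertion(self):
        events, calls = apply_support_filter(
            {
                "r1": [self.del_sig],
                "r2": [self.del_sig],
                "r3": [self.del_sig],
                "r4": [self.ins_sig],
            }
        )
        assert len(events) == 1
        assert events[0].support == 3 and events[0].klass == DELETION
        klass = {c.pair_id: c.klass for c in calls}
        assert klass == {"r1": DELETION, "r2": DELETION, "r3": DELETION,
                         "r4": WT}

    def test_mixed_classes_on_one_read_become_delin(self):
        events, calls = apply_support_filter(
            {
                "r1": [self.del_sig, self.ins_sig],
                "r2": [self.del_sig, self.ins_sig],
            }
        )
        assert {c.klass for c in calls} == {DELIN}
        assert all(c.multi_event for c in calls)


class TestTruthRecovery:
    def test_error_free_calls_match_simulation_truth(self, nco_target):
        import collections

        sc = SimScenario(n_pairs=500, seed=21, substitution_errors=False)
        pairs = simulate_run(nco_target, sc)
        reads = []
        for p in pairs:
            template = apply_edit(nco_target, p.truth)
            reads.append(
                MergedRead(template, np.full(len(template), 1e-3), p.pair_id, 0)
            )
        result = call_reads(reads, nco_target)
        sig_count = collections.Counter(
            p.truth.signature for p in pairs if p.truth.klass != WT
        )
        called = {c.pair_id: c for c in result.calls}
        for p in pairs:
            expect = p.truth.klass
            if expect != WT and sig_count[p.truth.signature] < 2:
                expect = WT
            assert called[p.pair_id].klass == expect
        truth_sigs = {s for s, n in sig_count.items() if n >= 2}
        assert {c.signature for c in result.events} == truth_sigs

    def test_substitution_noise_changes_no_class(self, nco_target):
        rng = np.random.default_rng(30)
        reads = []
        for i in range(150):
            seq = list(nco_target.ref_seq)
            for pos in np.flatnonzero(rng.random(len(seq)) < 0.01):
                seq[pos] = rng.choice(
                    [b for b in "ACGT" if b != seq[pos]]
                )
            reads.append(
                MergedRead("".join(seq), np.full(len(seq), 1e-3), f"r{i}", 0)
            )
        result = call_reads(reads, nco_target)
        assert all(c.klass == WT for c in result.calls)
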