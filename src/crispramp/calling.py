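"""Alignment-based calling of editing events from merged amplicon reads.

Each merged read is globally aligned to the amplicon reference with affine
gap penalties, indels are shifted maximally leftward so that equivalent gap
placements collapse to one canonical signature, and events are extracted as
maximal runs of non-matching alignment columns.  The taxonomy follows the
amplicon analyzer this package reproduces: a run of pure insertions is an
Insertion, pure deletions a Deletion, a mixed run a Delin, and a run of
substitutions only is discarded (substitutions are not editing events).
Events must start and end more than ``margin`` bases away from the primer
annealing sites, and an event signature must be seen in at least
``min_support`` distinct reads to be kept; reads whose every event is
removed revert to WT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .prep import MergedRead
from .simulate import (
    DELETION, DELIN, INSERTION, WT, AmpliconTarget, EditOutcome,
)

__all__ = [
    "Scoring", "AlignedRead", "CalledEvent", "ReadCall",
    "align_to_reference", "left_align_indels", "extract_events",
    "filter_position", "apply_support_filter", "call_reads", "CallResult",
]

_NEG = -1.0e15


@dataclass(frozen=True)
class Scoring:
    """Affine-gap alignment scores: a gap of length L costs
    ``-(gap_open + gap_extend * L)`` (first gapped base pays open + extend)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -6
    gap_extend: int = -1


@dataclass
class AlignedRead:
    """A global alignment stored as two gap-padded rows of equal length."""

    pair_id: str
    ref_row: str
    read_row: str
    score: float

    @property
    def ops(self) -> list[tuple[str, int, int, int, int]]:
        """Compressed operations: (op, ref_start, ref_end, read_start,
        read_end) with op in {'M' match, 'X' substitution, 'D' deletion,
        'I' insertion}, tiling both sequences without gaps."""
        out: list[tuple[str, int, int, int, int]] = []
        ri = qi = 0
        for rc, qc in zip(self.ref_row, self.read_row):
            if rc == "-":
                op, dr, dq = "I", 0, 1
            elif qc == "-":
                op, dr, dq = "D", 1, 0
            elif rc == qc:
                op, dr, dq = "M", 1, 1
            else:
                op, dr, dq = "X", 1, 1
            if out and out[-1][0] == op and out[-1][2] == ri and out[-1][4] == qi:
                prev = out[-1]
                out[-1] = (op, prev[1], ri + dr, prev[3], qi + dq)
            else:
                out.append((op, ri, ri + dr, qi, qi + dq))
            ri += dr
            qi += dq
        return out


def _dp_matrices(read: str, ref: str, sc: Scoring):
    n, m = len(read), len(ref)
    ext, opn = float(sc.gap_extend), float(sc.gap_open)
    H = np.full((n + 1, m + 1), _NEG)
    I_ = np.full((n + 1, m + 1), _NEG)
    D_ = np.full((n + 1, m + 1), _NEG)
    js = np.arange(m + 1, dtype=float)
    H[0, 0] = 0.0
    D_[0, 1:] = opn + ext * js[1:]
    H[0, 1:] = D_[0, 1:]
    ref_u8 = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_u8 = np.frombuffer(read.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        I_[i] = np.maximum(H[i - 1] + opn + ext, I_[i - 1] + ext)
        sub = np.where(ref_u8 == read_u8[i - 1], float(sc.match), float(sc.mismatch))
        T = I_[i].copy()
        T[1:] = np.maximum(H[i - 1, :m] + sub, I_[i, 1:])
        B = T - ext * js
        run = np.maximum.accumulate(B)
        D_[i, 1:] = opn + ext * js[1:] + run[:-1]
        H[i, 0] = T[0]
        H[i, 1:] = np.maximum(T[1:], D_[i, 1:])
    return H, I_, D_


def _traceback(read: str, ref: str, sc: Scoring, H, I_, D_):
    ext, opn = float(sc.gap_extend), float(sc.gap_open)
    i, j = len(read), len(ref)
    state = "H"
    ref_row: list[str] = []
    read_row: list[str] = []
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                sub = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
                if H[i, j] == H[i - 1, j - 1] + sub:
                    ref_row.append(ref[j - 1])
                    read_row.append(read[i - 1])
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and H[i, j] == D_[i, j]:
                state = "D"
                continue
            if i > 0 and H[i, j] == I_[i, j]:
                state = "I"
                continue
            raise AssertionError("traceback failed")  # pragma: no cover
        if state == "Hx":
            # predecessor of a deletion opening: its path value is
            # max(diagonal, insertion), never the deletion state
            val_diag = _NEG
            if i > 0 and j > 0:
                sub = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
                val_diag = H[i - 1, j - 1] + sub
            val_ins = I_[i, j] if i > 0 else _NEG
            if val_diag >= val_ins:
                ref_row.append(ref[j - 1])
                read_row.append(read[i - 1])
                i -= 1
                j -= 1
                state = "H"
            else:
                state = "I"
            continue
        if state == "D":
            ref_row.append(ref[j - 1])
            read_row.append("-")
            if j > 1 and D_[i, j] == D_[i, j - 1] + ext:
                state = "D"
            else:
                state = "Hx"
            j -= 1
            continue
        # state == "I"
        ref_row.append("-")
        read_row.append(read[i - 1])
        if i > 1 and I_[i, j] == I_[i - 1, j] + ext:
            state = "I"
        else:
            state = "H"
        i -= 1
    return "".join(reversed(ref_row)), "".join(reversed(read_row))


def align_to_reference(
    read: MergedRead | str,
    target: AmpliconTarget,
    scoring: Optional[Scoring] = None,
) -> AlignedRead:
    """Globally align a merged read to the amplicon reference.

    Needleman-Wunsch/Gotoh with affine gaps; tie-breaking is deterministic
    (diagonal preferred, then deletion, then insertion; gap extension
    preferred over a fresh opening), and gaps are subsequently canonicalized
    by :func:`left_align_indels`.
    """
    sc = scoring or Scoring()
    if isinstance(read, MergedRead):
        seq, pair_id = read.seq, read.pair_id
    else:
        seq, pair_id = read, "read"
    if not seq:
        raise ValueError("empty read")
    ref = target.ref_seq
    if seq == ref:
        return AlignedRead(pair_id, ref, seq, float(sc.match * len(ref)))
    H, I_, D_ = _dp_matrices(seq, ref, sc)
    ref_row, read_row = _traceback(seq, ref, sc, H, I_, D_)
    return AlignedRead(pair_id, ref_row, read_row, float(H[len(seq), len(ref)]))


def left_align_indels(aln: AlignedRead, ref: Optional[str] = None) -> AlignedRead:
    """Shift every gap maximally leftward through matching context.

    A gap run moves one column left when the column before it is a match and
    the move preserves both sequences and the alignment score (homopolymer /
    tandem-repeat ambiguity).  Idempotent; the ``ref`` argument is accepted
    for interface symmetry but the row representation already carries it.
    """
    r = list(aln.ref_row)
    q = list(aln.read_row)
    ncol = len(r)
    changed = True
    while changed:
        changed = False
        col = 0
        while col < ncol:
            if q[col] == "-" and r[col] != "-":  # deletion run
                a = col
                while col < ncol and q[col] == "-" and r[col] != "-":
                    col += 1
                b = col
                while (
                    a > 0
                    and q[a - 1] != "-"
                    and r[a - 1] != "-"
                    and q[a - 1] == r[a - 1]
                    and r[a - 1] == r[b - 1]
                ):
                    q[b - 1] = q[a - 1]
                    q[a - 1] = "-"
                    a -= 1
                    b -= 1
                    changed = True
            elif r[col] == "-" and q[col] != "-":  # insertion run
                a = col
                while col < ncol and r[col] == "-" and q[col] != "-":
                    col += 1
                b = col
                while (
                    a > 0
                    and q[a - 1] != "-"
                    and r[a - 1] != "-"
                    and q[a - 1] == r[a - 1]
                    and q[a - 1] == q[b - 1]
                ):
                    r[b - 1] = r[a - 1]
                    r[a - 1] = "-"
                    a -= 1
                    b -= 1
                    changed = True
            else:
                col += 1
    return AlignedRead(aln.pair_id, "".join(r), "".join(q), aln.score)


def extract_events(aln: AlignedRead) -> list[EditOutcome]:
    """Editing events as maximal runs of non-match alignment columns.

    A run with only substitution columns is discarded; otherwise the run's
    consumed reference bases form the deleted interval and its read bases the
    inserted sequence, classifying it as Deletion, Insertion or Delin.
    """
    events: list[EditOutcome] = []
    ref_pos = 0
    run_start = None
    run_del = 0
    run_ins: list[str] = []
    run_gap = False

    def flush() -> None:
        nonlocal run_start, run_del, run_ins, run_gap
        if run_start is not None and run_gap:
            ins = "".join(run_ins)
            if run_del and ins:
                events.append(EditOutcome(DELIN, run_start, run_start + run_del, ins))
            elif run_del:
                events.append(EditOutcome(DELETION, run_start, run_start + run_del))
            elif ins:
                events.append(EditOutcome(INSERTION, run_start, run_start, ins))
        run_start, run_del, run_ins, run_gap = None, 0, [], False

    for rc, qc in zip(aln.ref_row, aln.read_row):
        is_match = rc != "-" and rc == qc
        if is_match:
            flush()
            ref_pos += 1
            continue
        if run_start is None:
            run_start = ref_pos
        if rc != "-":
            run_del += 1
            ref_pos += 1
        if qc != "-":
            run_ins.append(qc)
        if rc == "-" or qc == "-":
            run_gap = True
    flush()
    return events


def filter_position(
    event: EditOutcome, target: AmpliconTarget, margin: int = 5
) -> bool:
    """Keep the event iff it starts and ends strictly more than ``margin``
    bases inside the primer annealing sites."""
    if event.klass == WT:
        raise ValueError("position filter applies to non-WT events")
    return (
        event.ref_start > target.fwd_primer[1] + margin
        and event.ref_end < target.rev_primer[0] - margin
    )


@dataclass(frozen=True)
class CalledEvent:
    """A deduplicated event signature with its read support."""

    klass: str
    ref_start: int
    ref_end: int
    ins_seq: str
    support: int

    @property
    def signature(self) -> tuple[str, int, int, str]:
        return (self.klass, self.ref_start, self.ref_end, self.ins_seq)


@dataclass
class ReadCall:
    """Final per-read classification with its surviving events."""

    pair_id: str
    klass: str
    events: tuple[EditOutcome, ...] = ()
    multi_event: bool = False

    def __post_init__(self) -> None:
        if (self.klass == WT) != (len(self.events) == 0):
            raise ValueError("WT reads carry no events and vice versa")


def _read_klass(events: Iterable[EditOutcome]) -> str:
    classes = {e.klass for e in events}
    if not classes:
        return WT
    if len(classes) == 1:
        return classes.pop()
    return DELIN  # mixed event classes on one read


def apply_support_filter(
    events_by_read: Mapping[str, list[EditOutcome]], min_support: int = 2
) -> tuple[list[CalledEvent], list[ReadCall]]:
    """Drop event signatures seen in fewer than ``min_support`` distinct
    reads; reads whose every event is removed revert to WT."""
    support: dict[tuple[str, int, int, str], int] = {}
    for events in events_by_read.values():
        for sig in {e.signature for e in events}:
            support[sig] = support.get(sig, 0) + 1
    passing = {sig for sig, n in support.items() if n >= min_support}
    called = sorted(
        (
            CalledEvent(*sig, support=n)
            for sig, n in support.items()
            if sig in passing
        ),
        key=lambda c: (c.ref_start, c.ref_end, c.klass, c.ins_seq),
    )
    calls = []
    for pair_id, events in events_by_read.items():
        kept = tuple(e for e in events if e.signature in passing)
        calls.append(
            ReadCall(
                pair_id=pair_id,
                klass=_read_klass(kept),
                events=kept,
                multi_event=len({e.signature for e in kept}) > 1,
            )
        )
    return called, calls


@dataclass
class CallResult:
    events: list[CalledEvent]
    calls: list[ReadCall]
    alignments: dict[str, AlignedRead] = field(default_factory=dict)


def call_reads(
    reads: list[MergedRead],
    target: AmpliconTarget,
    scoring: Optional[Scoring] = None,
    margin: int = 5,
    min_support: int = 2,
    keep_alignments: bool = False,
) -> CallResult:
    """Full calling chain: align, left-align, extract, position- and
    support-filter.  Identical read sequences are aligned once."""
    sc = scoring or Scoring()
    cache: dict[str, list[EditOutcome]] = {}
    events_by_read: dict[str, list[EditOutcome]] = {}
    alignments: dict[str, AlignedRead] = {}
    for read in reads:
        if read.seq not in cache:
            aln = left_align_indels(align_to_reference(read.seq, target, sc))
            cache[read.seq] = [
                e for e in extract_events(aln) if filter_position(e, target, margin)
            ]
            if keep_alignments:
                alignments[read.pair_id] = aln
        events_by_read[read.pair_id] = cache[read.seq]
    events, calls = apply_support_filter(events_by_read, min_support)
    return CallResult(events=events, calls=calls, alignments=alignments)
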