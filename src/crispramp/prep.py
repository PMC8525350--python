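"""Mate-pair merging and read-level quality / primer-containment filters.

Mates are merged by an overlap-consensus scan (the same job PEAR performs for
real runs): R2 is reverse-complemented, every overlap length is scored, and
the overlap maximizing the number of matching bases is accepted if its
mismatch fraction is small enough.  Merged reads then pass two filters before
event calling: every base must have error probability <= 0.05, and the read
must contain part of both primer sequences near its ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .simulate import AmpliconTarget, ReadPair, revcomp

__all__ = [
    "MergedRead", "PrepStats", "merge_pair", "filter_error_prob",
    "check_primers", "prep_reads", "ERR_PROB_FLOOR",
]

#: Floor on the consensus error probability of agreeing overlap bases.
ERR_PROB_FLOOR = 1e-4 / 3


@dataclass
class MergedRead:
    """Consensus sequence with per-base error probabilities."""

    seq: str
    err_prob: np.ndarray
    pair_id: str
    overlap_len: int

    def __post_init__(self) -> None:
        self.err_prob = np.asarray(self.err_prob, dtype=float)
        if len(self.err_prob) != len(self.seq):
            raise ValueError("err_prob length differs from sequence length")
        if ((self.err_prob <= 0) | (self.err_prob > 1)).any():
            raise ValueError("error probabilities must lie in (0, 1]")


@dataclass
class PrepStats:
    """Read counts surviving each stage of the prep chain."""

    n_input_pairs: int = 0
    n_merged: int = 0
    n_pass_error: int = 0
    n_pass_primers: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(
            n_input_pairs=self.n_input_pairs,
            n_merged=self.n_merged,
            n_pass_error=self.n_pass_error,
            n_pass_primers=self.n_pass_primers,
        )


def _phred_to_prob(q: np.ndarray) -> np.ndarray:
    return 10.0 ** (-np.asarray(q, float) / 10.0)


def merge_pair(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.25
) -> Optional[MergedRead]:
    """Merge one mate pair into a consensus read, or return None on failure.

    All overlap lengths from ``min_overlap`` up to the shorter mate are
    scanned against the reverse-complemented R2; the overlap with the most
    matching bases wins (ties broken toward the longer overlap) and is
    accepted if its mismatch fraction is <= ``max_mismatch_frac``.  Consensus
    bases in the overlap come from the higher-quality mate.  Agreeing bases
    get the product of the two error probabilities (floored at 1e-4/3);
    disagreeing bases keep the winning base's error probability.
    """
    if not pair.r1_seq or not pair.r2_seq:
        raise ValueError("mates must be non-empty")
    r1 = np.frombuffer(pair.r1_seq.encode(), dtype=np.uint8)
    r2rc_str = revcomp(pair.r2_seq)
    r2 = np.frombuffer(r2rc_str.encode(), dtype=np.uint8)
    p1 = _phred_to_prob(pair.r1_qual)
    p2 = _phred_to_prob(pair.r2_qual)[::-1]
    n1, n2 = len(r1), len(r2)

    best_o, best_matches = 0, -1
    for o in range(min(n1, n2), min_overlap - 1, -1):
        matches = int((r1[n1 - o :] == r2[:o]).sum())
        if matches > best_matches:
            best_o, best_matches = o, matches
    if best_o == 0 or (best_o - best_matches) / best_o > max_mismatch_frac:
        return None

    o = best_o
    a, b = r1[n1 - o :], r2[:o]
    pa, pb = p1[n1 - o :], p2[:o]
    agree = a == b
    take_a = pa <= pb  # higher quality = lower error probability; R1 on ties
    cons = np.where(take_a, a, b)
    perr = np.where(agree, np.maximum(pa * pb, ERR_PROB_FLOOR),
                    np.where(take_a, pa, pb))
    seq = pair.r1_seq[: n1 - o] + cons.tobytes().decode() + r2rc_str[o:]
    err = np.concatenate([p1[: n1 - o], perr, p2[o:]])
    return MergedRead(seq=seq, err_prob=err, pair_id=pair.pair_id, overlap_len=o)


def filter_error_prob(read: MergedRead, threshold: float = 0.05) -> bool:
    """Keep the read iff its maximum per-base error probability is <=
    ``threshold`` (inclusive at the boundary)."""
    return bool(np.max(read.err_prob) <= threshold)


def check_primers(
    read: MergedRead, target: AmpliconTarget, k: int = 10, window: int = 30
) -> bool:
    """Keep the read iff it contains part of both primer sequences.

    "Part of" is operationalized as an exact ``k``-mer of the forward primer
    fully within the first ``window`` bases, and an exact ``k``-mer of the
    reverse-primer annealing region (reference orientation) fully within the
    last ``window`` bases.
    """
    fwd = target.ref_seq[target.fwd_primer[0] : target.fwd_primer[1]]
    rev = target.ref_seq[target.rev_primer[0] : target.rev_primer[1]]
    if k > len(fwd) or k > len(rev):
        raise ValueError("k exceeds a primer length")
    head = read.seq[:window]
    tail = read.seq[-window:]
    fwd_ok = any(fwd[i : i + k] in head for i in range(len(fwd) - k + 1))
    rev_ok = any(rev[i : i + k] in tail for i in range(len(rev) - k + 1))
    return fwd_ok and rev_ok


@dataclass
class PrepResult:
    reads: list[MergedRead]
    stats: PrepStats
    dropped: dict[str, str] = field(default_factory=dict)  # pair_id -> stage


def prep_reads(
    pairs: list[ReadPair],
    target: AmpliconTarget,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    max_err_prob: float = 0.05,
    primer_kmer: int = 10,
    primer_window: int = 30,
) -> PrepResult:
    """Run the merge -> error filter -> primer filter chain.

    Every dropped pair is attributed to exactly one stage, so the stage
    counts are monotone non-increasing.
    """
    stats = PrepStats(n_input_pairs=len(pairs))
    kept: list[MergedRead] = []
    dropped: dict[str, str] = {}
    for pair in pairs:
        merged = merge_pair(pair, min_overlap, max_mismatch_frac)
        if merged is None:
            dropped[pair.pair_id] = "merge"
            continue
        stats.n_merged += 1
        if not filter_error_prob(merged, max_err_prob):
            dropped[pair.pair_id] = "error_prob"
            continue
        stats.n_pass_error += 1
        if not check_primers(merged, target, primer_kmer, primer_window):
            dropped[pair.pair_id] = "primers"
            continue
        stats.n_pass_primers += 1
        kept.append(merged)
    return PrepResult(reads=kept, stats=stats, dropped=dropped)
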