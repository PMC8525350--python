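"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written from scratch in plain Python (no
calls into the package's alignment or merging code paths) so that tests
compare two independent routes to the same answer.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_iupac_scan(seq: str, pattern: str) -> list[tuple[int, int]]:
    """Position-by-position IUPAC pattern matching."""
    w = len(pattern)
    hits = []
    for i in range(len(seq) - w + 1):
        if all(seq[i + k] in IUPAC[pattern[k]] for k in range(w)):
            hits.append((i, i + w))
    return hits


# ---------------------------------------------------------------------------
# exhaustive affine-gap alignment enumeration (small instances only)

NEG = float("-inf")


def _dp(read: str, ref: str, match=2, mismatch=-3, open_=-6, ext=-1):
    """dp[i][j][s]: best score for read[:i] vs ref[:j] ending in state s
    (0 = diagonal, 1 = deletion-of-ref, 2 = insertion-into-ref)."""
    n, m = len(read), len(ref)
    dp = [[[NEG] * 3 for _ in range(m + 1)] for _ in range(n + 1)]
    dp[0][0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if read[i - 1] == ref[j - 1] else mismatch
                best = max(dp[i - 1][j - 1])
                if best > NEG:
                    dp[i][j][0] = best + s
            if j > 0:
                openers = max(dp[i][j - 1][0], dp[i][j - 1][2])
                dp[i][j][1] = max(
                    dp[i][j - 1][1] + ext,
                    openers + open_ + ext if openers > NEG else NEG,
                )
            if i > 0:
                openers = max(dp[i - 1][j][0], dp[i - 1][j][1])
                dp[i][j][2] = max(
                    dp[i - 1][j][2] + ext,
                    openers + open_ + ext if openers > NEG else NEG,
                )
    return dp


def optimal_score(read: str, ref: str, **kw) -> float:
    dp = _dp(read, ref, **kw)
    return max(dp[len(read)][len(ref)])


def enumerate_optimal_paths(
    read: str, ref: str, match=2, mismatch=-3, open_=-6, ext=-1,
    max_paths: int = 50000,
) -> list[str]:
    """All co-optimal alignment paths as op strings over {M, D, I} in
    left-to-right order (M covers both match and substitution columns)."""
    dp = _dp(read, ref, match, mismatch, open_, ext)
    n, m = len(read), len(ref)
    best = max(dp[n][m])
    paths: list[str] = []

    def walk(i: int, j: int, state: int, suffix: list[str]) -> None:
        if len(paths) >= max_paths:
            raise RuntimeError("too many co-optimal paths")
        if i == 0 and j == 0:
            if state == 0:
                paths.append("".join(reversed(suffix)))
            return
        v = dp[i][j][state]
        if state == 0:
            s = match if read[i - 1] == ref[j - 1] else mismatch
            for prev in range(3):
                if dp[i - 1][j - 1][prev] + s == v:
                    suffix.append("M")
                    walk(i - 1, j - 1, prev, suffix)
                    suffix.pop()
        elif state == 1:
            if dp[i][j - 1][1] + ext == v:
                suffix.append("D")
                walk(i, j - 1, 1, suffix)
                suffix.pop()
            for prev in (0, 2):
                if dp[i][j - 1][prev] + open_ + ext == v:
                    suffix.append("D")
                    walk(i, j - 1, prev, suffix)
                    suffix.pop()
        else:
            if dp[i - 1][j][2] + ext == v:
                suffix.append("I")
                walk(i - 1, j, 2, suffix)
                suffix.pop()
            for prev in (0, 1):
                if dp[i - 1][j][prev] + open_ + ext == v:
                    suffix.append("I")
                    walk(i - 1, j, prev, suffix)
                    suffix.pop()

    for state in range(3):
        if dp[n][m][state] == best:
            walk(n, m, state, [])
    return paths


def _path_to_rows(path: str, read: str, ref: str) -> tuple[str, str]:
    ri = qi = 0
    ref_row, read_row = [], []
    for op in path:
        if op == "M":
            ref_row.append(ref[ri]); read_row.append(read[qi]); ri += 1; qi += 1
        elif op == "D":
            ref_row.append(ref[ri]); read_row.append("-"); ri += 1
        else:
            ref_row.append("-"); read_row.append(read[qi]); qi += 1
    assert ri == len(ref) and qi == len(read)
    return "".join(ref_row), "".join(read_row)


def _shift_gaps_left(ref_row: str, read_row: str) -> tuple[str, str]:
    r, q = list(ref_row), list(read_row)
    moved = True
    while moved:
        moved = False
        for col in range(1, len(r)):
            gap_in_q = q[col] == "-" and r[col] != "-"
            gap_in_r = r[col] == "-" and q[col] != "-"
            if not (gap_in_q or gap_in_r):
                continue
            # locate run end
            b = col
            while b < len(r) and (
                (q[b] == "-" and r[b] != "-") if gap_in_q
                else (r[b] == "-" and q[b] != "-")
            ):
                b += 1
            a = col
            prev_match = q[a - 1] != "-" and r[a - 1] != "-" and q[a - 1] == r[a - 1]
            if gap_in_q and prev_match and r[a - 1] == r[b - 1]:
                q[b - 1], q[a - 1] = q[a - 1], "-"
                moved = True
            elif gap_in_r and prev_match and q[a - 1] == q[b - 1]:
                r[b - 1], r[a - 1] = r[a - 1], "-"
                moved = True
    return "".join(r), "".join(q)


def events_from_rows(ref_row: str, read_row: str) -> tuple:
    """Maximal non-match runs -> (klass, ref_start, ref_end, ins) tuples;
    substitution-only runs are dropped."""
    events = []
    pos = 0
    run = None  # [start, ndel, ins, has_gap]
    for rc, qc in zip(ref_row, read_row):
        if rc != "-" and rc == qc:
            if run and run[3]:
                events.append(run)
            run = None
            pos += 1
            continue
        if run is None:
            run = [pos, 0, "", False]
        if rc != "-":
            run[1] += 1
            pos += 1
        if qc != "-":
            run[2] += qc
        if rc == "-" or qc == "-":
            run[3] = True
    if run and run[3]:
        events.append(run)
    out = []
    for start, ndel, ins, _ in events:
        if ndel and ins:
            out.append(("Delin", start, start + ndel, ins))
        elif ndel:
            out.append(("Deletion", start, start + ndel, ""))
        else:
            out.append(("Insertion", start, start, ins))
    return tuple(out)


def canonical_event_sets(read: str, ref: str, **kw) -> set[tuple]:
    """Canonicalized event tuples of every co-optimal alignment."""
    out = set()
    for path in enumerate_optimal_paths(read, ref, **kw):
        rows = _shift_gaps_left(*_path_to_rows(path, read, ref))
        out.add(events_from_rows(*rows))
    return out


# ---------------------------------------------------------------------------
# brute-force mate merging

_RC = str.maketrans("ACGT", "TGCA")


def brute_merge(
    r1: str, q1, r2: str, q2, min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
):
    """Naive overlap-consensus merge: returns the consensus sequence or None.

    Scans every overlap of the reverse-complemented R2 against R1, keeps the
    one with the most matches (longest overlap on ties), and rejects it if
    its mismatch fraction is too high.  Overlap bases come from the mate
    with the higher Phred score (R1 on ties).
    """
    r2rc = r2.translate(_RC)[::-1]
    q2r = list(q2)[::-1]
    best = None
    for o in range(min_overlap, min(len(r1), len(r2)) + 1):
        matches = sum(
            1 for k in range(o) if r1[len(r1) - o + k] == r2rc[k]
        )
        if best is None or matches >= best[1]:
            best = (o, matches)
    if best is None:
        return None
    o, matches = best
    if (o - matches) / o > max_mismatch_frac:
        return None
    cons = list(r1[: len(r1) - o])
    for k in range(o):
        b1, b2 = r1[len(r1) - o + k], r2rc[k]
        if b1 == b2:
            cons.append(b1)
        else:
            cons.append(b1 if q1[len(r1) - o + k] >= q2r[k] else b2)
    cons.extend(r2rc[o:])
    return "".join(cons)
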