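"""Synthetic amplicon targets and paired-end reads with known editing truth.

The generator emulates the statistical structure of a Cas9 amplicon-seq
experiment: a 283–490 bp amplicon carrying a protospacer + NGG PAM with an
overlapping diagnostic restriction site, a blunt cut 3 bp upstream of the
PAM, and a repair-outcome spectrum dominated by 1 bp A/T insertions with a
tail of longer insertions (up to 72 bp), deletions (up to 46 bp) and delins.
Reads are Illumina-style overlapping mates with per-base Phred qualities and
substitution-only errors at rate 10^(-Q/10).

Repair outcomes recur: >1 bp insertions are modelled as tandem duplications
of the sequence 5' of the cut and deletions are centred on the cut with a
deterministic interval per size, so independent cells produce identical
event signatures, as they do in real Cas9 data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .enzymes import IUPAC, EnzymeSite, site_scan

__all__ = [
    "WT", "DELETION", "INSERTION", "DELIN", "CLASSES",
    "AmpliconTarget", "EditOutcome", "SimScenario", "ReadPair",
    "make_amplicon", "draw_edit", "apply_edit", "canonicalize_edit",
    "simulate_read_pair", "simulate_run", "revcomp", "positive_control",
]

WT = "WT"
DELETION = "Deletion"
INSERTION = "Insertion"
DELIN = "Delin"
CLASSES = (WT, DELETION, INSERTION, DELIN)

_BASES = "ACGT"
_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class EditOutcome:
    """A single editing outcome: class, deleted reference interval, insertion.

    ``ref_start == ref_end`` for pure insertions; ``ins_seq`` is empty for WT
    and pure deletions.  Coordinates are 0-based half-open on the amplicon
    reference.
    """

    klass: str
    ref_start: int = 0
    ref_end: int = 0
    ins_seq: str = ""

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if self.ref_end < self.ref_start:
            raise ValueError("ref_end < ref_start")
        if self.klass == WT and (self.ref_end != self.ref_start or self.ins_seq):
            raise ValueError("WT carries no interval or insertion")
        if self.klass == DELETION and not (
            self.ref_end > self.ref_start and not self.ins_seq
        ):
            raise ValueError("Deletion needs a non-empty interval, no insertion")
        if self.klass == INSERTION and not (
            self.ref_end == self.ref_start and len(self.ins_seq) >= 1
        ):
            raise ValueError("Insertion needs an empty interval and bases")
        if self.klass == DELIN and not (
            self.ref_end > self.ref_start and len(self.ins_seq) >= 1
        ):
            raise ValueError("Delin needs a non-empty interval and bases")

    @property
    def signature(self) -> tuple[str, int, int, str]:
        return (self.klass, self.ref_start, self.ref_end, self.ins_seq)


@dataclass(frozen=True)
class AmpliconTarget:
    """An amplicon reference with primer, protospacer, PAM and site annotations.

    All intervals are 0-based half-open on ``ref_seq``; the reverse-primer
    annealing region is stored in reference orientation.  ``cut_pos`` is a
    between-base index.
    """

    name: str
    ref_seq: str
    fwd_primer: tuple[int, int]
    rev_primer: tuple[int, int]
    protospacer: tuple[int, int]
    pam: tuple[int, int]
    cut_pos: int
    enzyme_sites: tuple[tuple[EnzymeSite, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.ref_seq)
        if any(c not in "ACGT" for c in self.ref_seq):
            raise ValueError("ref_seq must be uppercase A/C/G/T")
        if self.fwd_primer[0] != 0 or self.rev_primer[1] != n:
            raise ValueError("primers must flank the amplicon ends")
        ps, pe = self.protospacer
        if self.pam != (pe, pe + 3) and self.pam != (ps - 3, ps):
            raise ValueError("PAM must be 3 bp and adjacent to the protospacer")
        lo = min(ps, self.pam[0])
        hi = max(pe, self.pam[1])
        if lo < self.fwd_primer[1] or hi > self.rev_primer[0]:
            raise ValueError("protospacer/PAM overlap a primer interval")
        if not ps <= self.cut_pos < self.pam[1]:
            raise ValueError("cut_pos outside protospacer/PAM")
        for enz, (s, e) in self.enzyme_sites:
            if e - s != len(enz.pattern) or any(
                self.ref_seq[s + i] not in IUPAC[c]
                for i, c in enumerate(enz.pattern)
            ):
                raise ValueError(f"annotated {enz.name} site does not match ref")

    @property
    def diagnostic_site(self) -> tuple[EnzymeSite, tuple[int, int]]:
        """The annotated enzyme occurrence overlapping the cut position."""
        for enz, (s, e) in self.enzyme_sites:
            if s < self.cut_pos < e:
                return enz, (s, e)
        raise ValueError("no annotated enzyme site overlaps the cut position")


@dataclass(frozen=True)
class ReadPair:
    """One simulated or parsed mate pair (Phred scores, not ASCII)."""

    pair_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray
    truth: Optional[EditOutcome] = None

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(
            self.r2_qual
        ):
            raise ValueError("sequence and quality lengths differ")


def _geometric(p: float, lo: int, hi: int) -> dict[int, float]:
    sizes = np.arange(lo, hi + 1)
    w = (1 - p) ** (sizes - lo) * p
    w /= w.sum()
    return {int(s): float(x) for s, x in zip(sizes, w)}


def _default_ins_sizes() -> dict[int, float]:
    # 1 bp insertions dominate (the staggered-cut / A-rule outcome); the
    # remaining mass decays geometrically out to 72 bp.
    dist = {1: 0.8}
    tail = _geometric(0.35, 2, 72)
    for s, w in tail.items():
        dist[s] = 0.2 * w
    return dist


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated editing experiment."""

    edited_fraction: float = 0.23
    class_weights: dict[str, float] = field(
        default_factory=lambda: {INSERTION: 0.65, DELETION: 0.25, DELIN: 0.10}
    )
    del_size_dist: dict[int, float] = field(
        default_factory=lambda: _geometric(0.2, 1, 46)
    )
    ins_size_dist: dict[int, float] = field(default_factory=_default_ins_sizes)
    ins1bp_base_bias: dict[str, float] = field(
        default_factory=lambda: {"A": 0.45, "T": 0.45, "C": 0.05, "G": 0.05}
    )
    read_len: int = 200
    n_pairs: int = 2000
    mean_q: float = 30.0
    qual_sd: float = 3.0
    substitution_errors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.edited_fraction <= 1.0:
            raise ValueError("edited_fraction outside [0, 1]")
        for name, dist in (
            ("class_weights", self.class_weights),
            ("del_size_dist", self.del_size_dist),
            ("ins_size_dist", self.ins_size_dist),
            ("ins1bp_base_bias", self.ins1bp_base_bias),
        ):
            vals = np.fromiter(dist.values(), float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} is not a probability vector")
        if set(self.class_weights) != {DELETION, INSERTION, DELIN}:
            raise ValueError("class_weights must cover Deletion/Insertion/Delin")
        if not all(1 <= s <= 46 for s in self.del_size_dist):
            raise ValueError("deletion sizes must lie in 1..46")
        if not all(1 <= s <= 72 for s in self.ins_size_dist):
            raise ValueError("insertion sizes must lie in 1..72")

    def replace(self, **kw) -> "SimScenario":
        return dataclasses.replace(self, **kw)


def positive_control(**kw) -> SimScenario:
    """The positive-control scenario: ~23% edited, insertion-dominated."""
    return SimScenario(**kw)


def make_amplicon(
    length: int,
    enzyme: EnzymeSite,
    primer_len: int = 20,
    seed: int = 0,
    proto_len: int = 20,
    max_tries: int = 500,
) -> AmpliconTarget:
    """Generate a random amplicon whose protospacer carries exactly one
    occurrence of ``enzyme``'s recognition site overlapping the cut position.

    The protospacer + PAM sit mid-amplicon, the PAM is NGG, and the cut is
    placed 3 bp upstream of the PAM (blunt SpCas9 cut).  Deterministic for a
    fixed seed; raises ``RuntimeError`` if the geometric constraints cannot
    be satisfied within ``max_tries`` resamplings.
    """
    if length < 2 * primer_len + 60:
        raise ValueError("amplicon too short for primers plus target region")
    width = len(enzyme.pattern)
    if width >= proto_len:
        raise ValueError("recognition pattern does not fit the protospacer")
    rng = np.random.default_rng(seed)
    proto_start = (length - proto_len - 3) // 2
    pam = (proto_start + proto_len, proto_start + proto_len + 3)
    cut = pam[0] - 3
    site_start = cut - width // 2
    site_start = min(max(site_start, proto_start), cut - 1)
    region = (proto_start, pam[1])
    for _ in range(max_tries):
        seq = rng.choice(list(_BASES), size=length)
        seq[pam[0] + 1] = "G"
        seq[pam[0] + 2] = "G"
        for i, code in enumerate(enzyme.pattern):
            seq[site_start + i] = rng.choice(list(IUPAC[code]))
        ref = "".join(seq)
        hits = site_scan(ref, enzyme)
        in_region = [
            (s, e) for s, e in hits if s < region[1] and e > region[0]
        ]
        if in_region != [(site_start, site_start + width)]:
            continue
        s, e = in_region[0]
        if not s < cut < e:
            continue
        return AmpliconTarget(
            name=f"amplicon_{length}bp_{enzyme.name}_seed{seed}",
            ref_seq=ref,
            fwd_primer=(0, primer_len),
            rev_primer=(length - primer_len, length),
            protospacer=(proto_start, proto_start + proto_len),
            pam=pam,
            cut_pos=cut,
            enzyme_sites=tuple((enzyme, h) for h in hits),
        )
    raise RuntimeError(
        f"could not satisfy amplicon constraints in {max_tries} tries"
    )


def apply_edit(target: AmpliconTarget, edit: EditOutcome) -> str:
    """Reference with the edit spliced in; WT returns the reference unchanged.

    The edit interval must lie within the amplicon and outside both primer
    annealing regions.
    """
    if edit.klass == WT:
        return target.ref_seq
    s, e = edit.ref_start, edit.ref_end
    if not 0 <= s <= e <= len(target.ref_seq):
        raise ValueError("edit interval outside the amplicon")
    if s < target.fwd_primer[1] or e > target.rev_primer[0]:
        raise ValueError("edit interval overlaps a primer annealing region")
    return target.ref_seq[:s] + edit.ins_seq + target.ref_seq[e:]


def canonicalize_edit(ref: str, edit: EditOutcome) -> EditOutcome:
    """Canonical (maximally left-shifted, reduced) form of a single edit.

    Splices the edit into ``ref``, trims the maximal common suffix then the
    maximal common prefix of (reference, edited) — which yields the leftmost
    equivalent placement — and reclassifies.  An edit whose deleted and
    inserted parts reduce to an equal-length core is substitution-only and
    canonicalizes to WT (substitutions are not editing events here).
    """
    if edit.klass == WT:
        return EditOutcome(WT)
    alt = ref[: edit.ref_start] + edit.ins_seq + ref[edit.ref_end :]
    # maximal common suffix, then maximal common prefix of the remainder
    suf = 0
    while (
        suf < min(len(ref), len(alt)) and ref[len(ref) - 1 - suf] == alt[len(alt) - 1 - suf]
    ):
        suf += 1
    pre = 0
    while (
        pre < min(len(ref), len(alt)) - suf and ref[pre] == alt[pre]
    ):
        pre += 1
    core_ref = ref[pre : len(ref) - suf]
    core_alt = alt[pre : len(alt) - suf]
    if not core_ref and not core_alt:
        return EditOutcome(WT)
    if len(core_ref) == len(core_alt):
        return EditOutcome(WT)  # substitution-only difference
    if not core_alt:
        return EditOutcome(DELETION, pre, pre + len(core_ref))
    if not core_ref:
        return EditOutcome(INSERTION, pre, pre, core_alt)
    return EditOutcome(DELIN, pre, pre + len(core_ref), core_alt)


def _draw_from(dist: dict, rng: np.random.Generator):
    keys = list(dist.keys())
    probs = np.fromiter(dist.values(), float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _deletion_interval(target: AmpliconTarget, d: int) -> tuple[int, int]:
    cut = target.cut_pos
    start = cut - (d + 1) // 2
    lo = target.fwd_primer[1]
    hi = target.rev_primer[0]
    start = min(max(start, lo), hi - d)
    return start, start + d


def _delin_pool(target: AmpliconTarget, s: int, e: int) -> list[str]:
    # bases absent from the deleted run and its flanks: such an insertion
    # cannot be reinterpreted by the aligner as substitutions plus a smaller
    # indel, so the delin's canonical form keeps its class and interval
    forbidden = set(target.ref_seq[s:e])
    forbidden.add(target.ref_seq[s - 1])
    if e < len(target.ref_seq):
        forbidden.add(target.ref_seq[e])
    return [b for b in _BASES if b not in forbidden]


def draw_edit(
    scenario: SimScenario, target: AmpliconTarget, rng: np.random.Generator
) -> EditOutcome:
    """Draw one repair outcome anchored at the target's cut position."""
    if rng.random() >= scenario.edited_fraction:
        return EditOutcome(WT)
    klass = _draw_from(scenario.class_weights, rng)
    cut = target.cut_pos
    if klass == INSERTION:
        n = _draw_from(scenario.ins_size_dist, rng)
        if n == 1:
            base = _draw_from(scenario.ins1bp_base_bias, rng)
            return EditOutcome(INSERTION, cut, cut, base)
        # templated tandem duplication of the n bases 5' of the cut
        lo = target.fwd_primer[1]
        n = min(n, cut - lo)
        return EditOutcome(INSERTION, cut, cut, target.ref_seq[cut - n : cut])
    if klass == DELETION:
        d = _draw_from(scenario.del_size_dist, rng)
        s, e = _deletion_interval(target, d)
        return EditOutcome(DELETION, s, e)
    for _ in range(50):
        d = _draw_from(scenario.del_size_dist, rng)
        s, e = _deletion_interval(target, d)
        pool = _delin_pool(target, s, e)
        if pool:
            break
    else:  # a wide deleted run can cover all four bases; fall back to 1 bp
        s, e = _deletion_interval(target, 1)
        pool = _delin_pool(target, s, e)
    n = min(_draw_from(scenario.ins_size_dist, rng), 3)
    if n == e - s:
        # equal-length fill-in is a substitution run, not a delin
        n = n + 1 if n < 3 else n - 1
    # like >1 bp insertions, delins recur as discrete outcomes: the filled-in
    # sequence is a deterministic function of the deleted interval
    return EditOutcome(DELIN, s, e, sorted(pool)[0] * n)


def _noisy_read(template: str, scenario: SimScenario,
                rng: np.random.Generator) -> tuple[str, np.ndarray]:
    n = len(template)
    qual = np.clip(
        np.rint(rng.normal(scenario.mean_q, scenario.qual_sd, n)), 2, 40
    ).astype(int)
    seq = np.array(list(template))
    if scenario.substitution_errors:
        p = 10.0 ** (-qual / 10.0)
        hit = rng.random(n) < p
        for i in np.flatnonzero(hit):
            seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
    return "".join(seq), qual


def simulate_read_pair(
    template: str,
    scenario: SimScenario,
    rng: np.random.Generator,
    pair_id: str = "pair0",
    truth: Optional[EditOutcome] = None,
) -> ReadPair:
    """Overlapping Illumina-style mates from one amplicon template.

    R1 is the 5' prefix of the template and R2 the reverse complement of the
    3' suffix, each ``read_len`` long; mates must overlap by at least 10 bp.
    Substitution errors are injected per base at probability 10^(-Q/10).
    """
    L = scenario.read_len
    if L > len(template):
        raise ValueError("read_len exceeds template length")
    if 2 * L < len(template) + 10:
        raise ValueError("mates would overlap by fewer than 10 bp")
    r1, q1 = _noisy_read(template[:L], scenario, rng)
    r2, q2 = _noisy_read(revcomp(template[len(template) - L :]), scenario, rng)
    return ReadPair(pair_id, r1, r2, q1, q2, truth=truth)


def simulate_run(
    target: AmpliconTarget,
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
) -> list[ReadPair]:
    """Simulate ``scenario.n_pairs`` read pairs; truth edits are attached to
    each pair in canonical (left-aligned, reduced) form."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    pairs = []
    for i in range(scenario.n_pairs):
        edit = draw_edit(scenario, target, rng)
        assert edit.klass == WT or (
            edit.ref_start >= target.fwd_primer[1]
            and edit.ref_end <= target.rev_primer[0]
        ), "drawn edit overlaps a primer interval"
        template = apply_edit(target, edit)
        truth = canonicalize_edit(target.ref_seq, edit)
        pairs.append(
            simulate_read_pair(
                template, scenario, rng, pair_id=f"pair{i:06d}", truth=truth
            )
        )
    return pairs
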