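"""Aggregation of read calls into outcome tables and scenario comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from statsmodels.stats.proportion import proportion_confint

from .calling import ReadCall
from .simulate import CLASSES, DELETION, DELIN, INSERTION, WT

__all__ = ["OutcomeTable", "ScenarioComparison", "summarize", "compare_scenarios"]

_NONWT = (DELETION, INSERTION, DELIN)


@dataclass
class OutcomeTable:
    """Per-class counts and percentages over filter-passing reads."""

    n_reads: int
    counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in CLASSES}
    )

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_reads:
            raise ValueError("class counts do not sum to n_reads")

    @property
    def status(self) -> str:
        return "ok" if self.n_reads else "no passing reads"

    def _require_reads(self) -> None:
        if self.n_reads == 0:
            raise ValueError("no passing reads: percentages are undefined")

    @property
    def pct(self) -> dict[str, float]:
        self._require_reads()
        return {k: 100.0 * v / self.n_reads for k, v in self.counts.items()}

    @property
    def mutated_pct(self) -> float:
        self._require_reads()
        return 100.0 * (self.n_reads - self.counts[WT]) / self.n_reads

    @property
    def n_mutated(self) -> int:
        return self.n_reads - self.counts[WT]

    def to_dict(self) -> dict:
        out = {"n_reads": self.n_reads, "status": self.status,
               "counts": dict(self.counts)}
        if self.n_reads:
            out["pct"] = self.pct
            out["mutated_pct"] = self.mutated_pct
        return out


def summarize(calls: Iterable[ReadCall]) -> OutcomeTable:
    """Exact per-class counting over one pooled sample's read calls."""
    counts = {k: 0 for k in CLASSES}
    n = 0
    for call in calls:
        counts[call.klass] += 1
        n += 1
    return OutcomeTable(n_reads=n, counts=counts)


@dataclass
class ScenarioComparison:
    """Mutated-fraction ratio a/b with a 95% CI, and the total-variation
    distance between the two non-WT class mixes."""

    ratio: Optional[float]
    ratio_ci: Optional[tuple[float, float]]
    composition_distance: Optional[float]
    status: str = "ok"


def _wilson(count: int, nobs: int, alpha: float) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def compare_scenarios(
    a: OutcomeTable, b: OutcomeTable, alpha: float = 0.05
) -> ScenarioComparison:
    """Compare two outcome tables (e.g. positive control vs a weaker
    delivery): ratio of mutated fractions with a Wilson-based 95% CI, plus
    the total-variation distance between non-WT class compositions."""
    a._require_reads()
    b._require_reads()
    if b.n_mutated == 0:
        return ScenarioComparison(None, None, None, status="undefined ratio")
    pa, pb = a.n_mutated / a.n_reads, b.n_mutated / b.n_reads
    a_lo, a_hi = _wilson(a.n_mutated, a.n_reads, alpha)
    b_lo, b_hi = _wilson(b.n_mutated, b.n_reads, alpha)
    ratio = pa / pb
    ci = (a_lo / b_hi if b_hi > 0 else float("inf"),
          a_hi / b_lo if b_lo > 0 else float("inf"))
    tv: Optional[float] = None
    if a.n_mutated and b.n_mutated:
        mix_a = {k: a.counts[k] / a.n_mutated for k in _NONWT}
        mix_b = {k: b.counts[k] / b.n_mutated for k in _NONWT}
        tv = 0.5 * sum(abs(mix_a[k] - mix_b[k]) for k in _NONWT)
    return ScenarioComparison(ratio=ratio, ratio_ci=ci, composition_distance=tv)
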