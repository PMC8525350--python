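"""CAN1-style colony-count statistics: titers, mutation frequencies, and
mutation-position classification relative to the PAM.

Mutants (e.g. canavanine-resistant colonies from a CAN1 loss-of-function
screen) are counted on selective plates; the viable population is titered
from serial dilutions on rich plates.  The mutation frequency is the
resistant count divided by the estimated number of viable cells screened.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlateCount", "FrequencyResult", "titer_from_dilutions",
    "mutation_frequency", "replicate_frequencies",
    "classify_mutation_position", "TARGET_PROXIMAL", "DISTAL",
]

TARGET_PROXIMAL = "target-proximal"
DISTAL = "distal"


@dataclass(frozen=True)
class PlateCount:
    """Colonies on one plate: count, fold-dilution and plated volume."""

    colonies: int
    dilution_factor: float = 1.0
    plated_volume_ml: float = 0.1

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colony count must be non-negative")
        if self.dilution_factor <= 0 or self.plated_volume_ml <= 0:
            raise ValueError("dilution factor and volume must be positive")

    @property
    def titer(self) -> float:
        """Cells per ml of the undiluted culture implied by this plate."""
        return self.colonies * self.dilution_factor / self.plated_volume_ml


def titer_from_dilutions(plates: Sequence[PlateCount]) -> float:
    """Count-weighted mean titer (cells/ml) across countable plates."""
    countable = [p for p in plates if p.colonies > 0]
    if not countable:
        raise ValueError("no countable plate (all colony counts are zero)")
    weights = np.array([p.colonies for p in countable], float)
    titers = np.array([p.titer for p in countable])
    return float(np.average(titers, weights=weights))


@dataclass(frozen=True)
class FrequencyResult:
    resistant_total: int
    viable_total_estimate: float
    frequency: float
    ci95: tuple[float, float]


def _poisson_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    # Garwood exact interval on a Poisson count
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2
    return lo, hi


def mutation_frequency(
    resistant: Sequence[PlateCount], totals: Sequence[PlateCount]
) -> FrequencyResult:
    """Mutation frequency: resistant colonies divided by the viable cells
    screened on the selective plates, with a 95% Poisson CI on the count.

    The viable titer comes from the serial-dilution plates; the number of
    cells screened is titer times the (dilution-corrected) volume spread on
    the selective plates.
    """
    titer = titer_from_dilutions(totals)
    screened = titer * sum(
        p.plated_volume_ml / p.dilution_factor for p in resistant
    )
    if screened <= 0:
        raise ValueError("zero viable cells screened")
    k = sum(p.colonies for p in resistant)
    lo, hi = _poisson_ci(k)
    return FrequencyResult(
        resistant_total=k,
        viable_total_estimate=screened,
        frequency=k / screened,
        ci95=(lo / screened, hi / screened),
    )


def replicate_frequencies(
    replicates: Sequence[tuple[Sequence[PlateCount], Sequence[PlateCount]]],
) -> dict:
    """Per-replicate frequencies with mean and SEM, plus the pooled result.

    Each replicate is a (resistant plates, total-count plates) pair, e.g.
    one co-cultivation.
    """
    per = [mutation_frequency(res, tot) for res, tot in replicates]
    freqs = np.array([r.frequency for r in per])
    # pooled denominator: sum of per-replicate screened cells
    screened = sum(r.viable_total_estimate for r in per)
    k = sum(r.resistant_total for r in per)
    lo, hi = _poisson_ci(k)
    pooled = FrequencyResult(k, screened, k / screened,
                             (lo / screened, hi / screened))
    sem = float(freqs.std(ddof=1) / np.sqrt(len(freqs))) if len(freqs) > 1 else 0.0
    return {
        "per_replicate": per,
        "mean": float(freqs.mean()),
        "sem": sem,
        "pooled": pooled,
    }


def classify_mutation_position(
    mut_pos: int,
    pam: tuple[int, int],
    window: int = 10,
    strand: str = "+",
) -> str:
    """Classify a mutation as target-proximal (within ``window`` bases
    upstream of the PAM, inclusive) or distal.

    On the plus strand "upstream" means 5' of ``pam.start``; on the minus
    strand it means 3' of ``pam.end`` in reference coordinates.
    """
    if strand == "+":
        dist = pam[0] - mut_pos
    elif strand == "-":
        dist = mut_pos - pam[1] + 1
    else:
        raise ValueError("strand must be '+' or '-'")
    return TARGET_PROXIMAL if 1 <= dist <= window else DISTAL
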