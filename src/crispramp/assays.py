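"""In-silico counterparts of the gel-based mutation-detection assays.

Loss-of-restriction-site (RFLP) assay: an indel destroying the diagnostic
recognition site makes the PCR product digestion-resistant.  Pre-digesting
genomic DNA with the same enzyme before PCR removes intact (wild-type)
templates and so enriches mutated ones; ``predigest_pool`` models that
enrichment and ``enrichment_correct`` inverts it.  The T7 endonuclease I
assay estimates the edited fraction from cleaved-band intensities on a gel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .enzymes import EnzymeSite, site_scan
from .simulate import WT, AmpliconTarget, EditOutcome, apply_edit

__all__ = [
    "BandQuant", "site_lost", "predigest_pool", "enrichment_correct",
    "t7e1_percent_indel",
]


@dataclass(frozen=True)
class BandQuant:
    """Gel band intensities for one lane: the intact (uncleaved) band and
    any number of cleavage-product bands, in arbitrary units."""

    lane_id: str
    intact_intensity: float
    cleaved_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = (self.intact_intensity, *self.cleaved_intensities)
        if any(v < 0 or not math.isfinite(v) for v in vals):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def cleaved_fraction(self) -> float:
        total = self.intact_intensity + sum(self.cleaved_intensities)
        if total == 0:
            raise ValueError("all band intensities are zero")
        return sum(self.cleaved_intensities) / total


def site_lost(
    target: AmpliconTarget,
    edit: EditOutcome,
    enzyme: Optional[EnzymeSite] = None,
    site: Optional[tuple[int, int]] = None,
) -> bool:
    """Whether the edit destroys the diagnostic recognition site.

    The diagnostic site defaults to the annotated occurrence overlapping the
    cut position.  The edited sequence is rescanned in a window around the
    site's mapped locus, so an edit that happens to recreate the pattern
    nearby still counts as intact.
    """
    if enzyme is None or site is None:
        diag_enzyme, diag_site = target.diagnostic_site
        enzyme = enzyme or diag_enzyme
        site = site or diag_site
    if edit.klass == WT:
        return False
    edited = apply_edit(target, edit)
    s0, e0 = site
    delta = len(edit.ins_seq) - (edit.ref_end - edit.ref_start)
    # map the site interval through the edit (conservatively wide)
    lo = s0 if s0 <= edit.ref_start else max(edit.ref_start, s0 + delta)
    hi = e0 + delta if e0 >= edit.ref_end else e0
    hi = max(hi, lo)
    width = len(enzyme.pattern)
    w_lo = max(0, lo - width)
    w_hi = min(len(edited), hi + width)
    window = edited[w_lo:w_hi]
    for s, e in site_scan(window, enzyme):
        if w_lo + s < hi + width and w_lo + e > lo - width:
            return False
    return True


def predigest_pool(
    templates: Sequence[tuple[str, float]],
    enzyme: EnzymeSite,
    efficiency: float,
) -> list[tuple[str, float]]:
    """Reweight a template pool after pre-digestion with ``enzyme``.

    Templates carrying at least one intact recognition site survive with
    probability ``1 - efficiency``; site-free templates are untouched.
    Weights are renormalized to sum to 1.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    out = []
    for seq, w in templates:
        if w < 0:
            raise ValueError("weights must be non-negative")
        if site_scan(seq, enzyme):
            w *= 1.0 - efficiency
        out.append((seq, w))
    total = sum(w for _, w in out)
    if total == 0:
        raise ValueError("pre-digestion removed the entire pool")
    return [(seq, w / total) for seq, w in out]


def enrichment_correct(observed_fraction: float, efficiency: float) -> float:
    """Invert pre-digestion enrichment: recover the true mutant fraction f
    from the observed (post-enrichment) fraction.

    Enrichment maps f to f / (f + (1 - f)(1 - e)); this returns the unique
    f solving that relation, the identity when e = 0.
    """
    if not 0.0 <= observed_fraction <= 1.0 or not 0.0 <= efficiency <= 1.0:
        raise ValueError("inputs must lie in [0, 1]")
    if observed_fraction == 1.0 and efficiency == 1.0:
        raise ValueError("observed fraction 1 at complete digestion is undefined")
    return (
        observed_fraction * (1.0 - efficiency)
        / (1.0 - observed_fraction * efficiency)
    )


def t7e1_percent_indel(
    band: BandQuant, heteroduplex_correction: bool = True
) -> float:
    """Percent indels from T7EI band intensities.

    With the cleaved fraction fc = cleaved / (intact + cleaved), the default
    estimate is 100 * (1 - sqrt(1 - fc)): after denature/reanneal, a mutant
    fraction m yields a heteroduplex (cleavable) fraction of 1 - (1-m)^2
    when mutant/mutant homoduplexes are negligible.  Set
    ``heteroduplex_correction=False`` for the raw cleaved percentage.
    """
    fc = band.cleaved_fraction
    if not heteroduplex_correction:
        return 100.0 * fc
    return 100.0 * (1.0 - math.sqrt(1.0 - fc))
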