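"""Restriction-enzyme definitions and IUPAC site scanning.

Loss-of-restriction-site assays hinge on a diagnostic recognition site that
overlaps the Cas9 cut position: an indel destroys the site and renders the
PCR product digestion-resistant.  This module holds the enzyme definitions
used throughout (DdeI and NcoI by default) and a scanner that reports every
occurrence of an enzyme's IUPAC recognition pattern on a sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["EnzymeSite", "site_scan", "NCOI", "DDEI", "ENZYMES", "IUPAC"]

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class EnzymeSite:
    """A restriction enzyme: recognition pattern plus cut offset.

    ``pattern`` is an IUPAC DNA string; ``cut_offset`` is the position of the
    cut within the pattern (0 .. len(pattern)), on the top strand.
    """

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.pattern or any(c not in IUPAC for c in self.pattern):
            raise ValueError(f"pattern {self.pattern!r} is not IUPAC DNA")
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError("cut_offset outside pattern")

    def regex(self) -> str:
        return "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in self.pattern
        )

    def rc_pattern(self) -> str:
        return self.pattern.translate(_COMPLEMENT)[::-1]


NCOI = EnzymeSite("NcoI", "CCATGG", 1)
DDEI = EnzymeSite("DdeI", "CTNAG", 1)

ENZYMES: dict[str, EnzymeSite] = {e.name: e for e in (NCOI, DDEI)}


def site_scan(
    seq: str, enzyme: EnzymeSite, both_strands: bool = False
) -> list[tuple[int, int]]:
    """All occurrences of the recognition pattern, as 0-based half-open intervals.

    Scans the forward strand; overlapping occurrences are reported.  The
    built-in enzymes need no reverse-strand scan (CCATGG is its own reverse
    complement and CTNAG's reverse complement matches CTNAG under N), but
    ``both_strands=True`` additionally matches the reverse-complement pattern
    on the forward strand for arbitrary enzymes.

    Raises ``ValueError`` on characters outside A/C/G/T.
    """
    if re.search(r"[^ACGT]", seq):
        raise ValueError("sequence must be uppercase A/C/G/T")
    patterns = [enzyme.regex()]
    if both_strands:
        rc = EnzymeSite(enzyme.name, enzyme.rc_pattern(), enzyme.cut_offset).regex()
        if rc != patterns[0]:
            patterns.append(rc)
    hits: set[tuple[int, int]] = set()
    for pat in patterns:
        width = len(enzyme.pattern)
        for m in re.finditer("(?=" + pat + ")", seq):
            hits.add((m.start(), m.start() + width))
    return sorted(hits)
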