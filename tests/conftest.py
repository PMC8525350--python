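from __future__ import annotations

import numpy as np
import pytest

from crispramp.enzymes import DDEI, NCOI
from crispramp.simulate import AmpliconTarget, make_amplicon


@pytest.fixture(scope="session")
def nco_target() -> AmpliconTarget:
    return make_amplicon(283, NCOI, primer_len=20, seed=7)


@pytest.fixture(scope="session")
def dde_target() -> AmpliconTarget:
    return make_amplicon(100, DDEI, primer_len=20, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def toy_target(ref: str, cut: int | None = None) -> AmpliconTarget:
    """Minimal valid target over an arbitrary reference: 1 bp primers at the
    ends, protospacer/PAM tiling the interior."""
    n = len(ref)
    if n < 6:
        raise ValueError("reference too short for a toy target")
    proto = (1, n - 4)
    pam = (n - 4, n - 1)
    return AmpliconTarget(
        name="toy",
        ref_seq=ref,
        fwd_primer=(0, 1),
        rev_primer=(n - 1, n),
        protospacer=proto,
        pam=pam,
        cut_pos=cut if cut is not None else max(proto[0], pam[0] - 3),
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
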