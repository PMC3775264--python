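"""Shared fixtures: small synthetic reference families and corrected reads."""

from __future__ import annotations

import numpy as np
import pytest

from gtamp.seqio import SequenceRecord
from gtamp.simulate import SimSpec, make_reference_family

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130917)


@pytest.fixture(scope="session")
def small_refset():
    """Three families, three members each, 120-residue proteins."""
    spec = SimSpec(n_families=3, seed=11)
    return make_reference_family(spec)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[k] for k in rng.integers(len(AA), size=length))


@pytest.fixture
def toy_alignment():
    """Five gap-free aligned proteins sharing a conserved core."""
    base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    rows = [
        base,
        base[:10] + "L" + base[11:],
        base[:20] + "N" + base[21:],
        base,
        base[:5] + "G" + base[6:],
    ]
    return [SequenceRecord(id=f"s{i}", seq=s) for i, s in enumerate(rows)]
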