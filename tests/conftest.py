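"""Shared fixtures: deterministic RNGs and small sequence factories."""

import numpy as np
import pytest

from srnase_screen.io import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def aa_record_factory(rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def make(seq_id="p1", length=50):
        residues = "".join(rng.choice(list(aa), size=length))
        return SequenceRecord(seq_id, residues, moltype="aa")

    return make


@pytest.fixture
def nt_record_factory(rng):
    def make(seq_id="n1", length=120):
        residues = "".join(rng.choice(list("ACGT"), size=length))
        return SequenceRecord(seq_id, residues, moltype="nt")

    return make
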