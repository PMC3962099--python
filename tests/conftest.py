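import numpy as np
import pytest

from dipasym import (
    ProteinSequence,
    SequenceSet,
    generate_proteins,
    make_preset,
)
from dipasym.sequence_io import STANDARD_RESIDUES


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def random_protein_set(rng):
    """100 random 200-residue sequences over the standard alphabet."""
    letters = np.array(list(STANDARD_RESIDUES))
    members = [
        ProteinSequence(f"r{i:03d}", "".join(rng.choice(letters, size=200)))
        for i in range(100)
    ]
    return SequenceSet(members, label="random100")


@pytest.fixture(scope="session")
def messy_protein_set(rng):
    """Sequences salted with non-standard letters and '*' separators."""
    letters = np.array(list(STANDARD_RESIDUES + "BJOUXZ*"))
    members = [
        ProteinSequence(f"m{i:03d}", "".join(rng.choice(letters, size=120)))
        for i in range(40)
    ]
    return SequenceSet(members, label="messy40")


@pytest.fixture(scope="session")
def asymmetric_preset():
    return make_preset("table3_asymmetric")


@pytest.fixture(scope="session")
def symmetric_preset():
    return make_preset("symmetric")


@pytest.fixture(scope="session")
def asymmetric_set(asymmetric_preset):
    """A mid-sized set from the asymmetric preset for stability tests."""
    return generate_proteins(
        asymmetric_preset.model, 600, 300, seed=301, label="asym600"
    )
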