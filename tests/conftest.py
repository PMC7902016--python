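import numpy as np
import pytest

from coldcomp.io_model import FlexibilityScheme, ProteinRecord, AA_ALPHABET
from coldcomp.synthetic_data import generate_tm_table


@pytest.fixture(scope="session")
def scheme():
    return FlexibilityScheme()


@pytest.fixture(scope="session")
def tm_table():
    # seeded synthetic table: 100 negative, 100 low, 200 other
    return generate_tm_table(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length, protein_id="p", organism_id="org"):
    seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
    return ProteinRecord(protein_id, organism_id, seq)


@pytest.fixture()
def make_protein(rng):
    def _make(length, protein_id="p", organism_id="org"):
        return random_protein(rng, length, protein_id, organism_id)

    return _make
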