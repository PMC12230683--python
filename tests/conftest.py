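from __future__ import annotations

import numpy as np
import pytest

from diffdigest import load_bundled_table
from diffdigest.cli_io import generate_test_plasmid
from diffdigest.digestion import SequenceRecord, Topology


@pytest.fixture(scope="session")
def enzymes():
    """Bundled enzyme table as a name -> EnzymeRecord mapping."""
    return {r.name: r for r in load_bundled_table()}


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


def random_seq(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def ranking_pair():
    """Two circular plasmids identical except for one extra EcoRI site
    planted in the second; XhoI and HindIII sites are shared."""
    plants = [
        ("CTCGAG", 200), ("CTCGAG", 1400),    # XhoI
        ("AAGCTT", 700), ("AAGCTT", 2200),    # HindIII
        ("GAATTC", 400), ("GAATTC", 1800),    # EcoRI
    ]
    a = generate_test_plasmid(3000, plants, seed=11, id="plasmidA")
    b = generate_test_plasmid(
        3000, plants + [("GAATTC", 2600)], seed=11, id="plasmidB"
    )
    assert a.seq[:2600] == b.seq[:2600] and a.seq[2606:] == b.seq[2606:]
    return a, b
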