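import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from cladescout import synthetic_data as synth


@pytest.fixture(scope="session")
def default_family():
    """One default synthetic operon family shared across read-only tests."""
    config = synth.SimulationConfig(seed=7)
    return config, synth.generate_operon_family(config)


@pytest.fixture(scope="session")
def default_community(default_family):
    """Family plus occurrence matrix and site metadata."""
    config, family = default_family
    matrix, sites = synth.generate_occurrences(config, family.labels)
    return config, family, matrix, sites


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_dna(rng, seq: str, rate: float) -> str:
    """Substitution-only mutation, uniform over the three alternatives."""
    bases = "ACGT"
    out = []
    for base in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in bases if b != base]))
        else:
            out.append(base)
    return "".join(out)
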