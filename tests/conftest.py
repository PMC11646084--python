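import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from starwfa import Sequence, SequenceSet, SimParams, select_center, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim():
    """A small simulated dataset with its known true alignment."""
    return simulate(SimParams(n=12, root_length=400, target_similarity=0.95, seed=11))


@pytest.fixture
def small_set(small_sim):
    return SequenceSet(small_sim.sequences, select_center(small_sim.sequences))


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""
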