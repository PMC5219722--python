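import numpy as np
import pytest

from overko.datasets import synthetic_example_pair
from overko.restriction import load_enzymes
from overko.synthgen import SimParams, generate_pair


@pytest.fixture(scope="session")
def example_pair():
    """The bundled worked example: start-loss at codon 0, first stop at 3."""
    return synthetic_example_pair()


@pytest.fixture(scope="session")
def enzymes():
    return load_enzymes("builtin")


def make_pairs(n, seed, **overrides):
    """Seeded synthetic pairs shared by the oracle-equivalence tests."""
    params = SimParams(n_pairs=n, seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    return [generate_pair(params, rng) for _ in range(n)]
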