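import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bnexpand.dag_core import DAG, CoreNetwork
from bnexpand.data_model import DiscretizedMatrix, ExpressionMatrix
from bnexpand.synthetic_data import default_core_spec, sample_dataset


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down reference spec for fast pipeline tests."""
    return replace(
        default_core_spec(seed=42),
        n_pairwise=6,
        n_higher_order=4,
        n_independent=30,
        n_lowquality=4,
        m_experiments=150,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return sample_dataset(small_spec)


@pytest.fixture
def tiny_expression():
    return ExpressionMatrix(
        ("g1", "g2", "g3"),
        ("e1", "e2", "e3", "e4"),
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [0.5, np.nan, 1.5, 2.5],
            ]
        ),
    )


@pytest.fixture
def chain_core():
    """A 3-node chain core a->b->c with identity row mapping."""
    return CoreNetwork(DAG(("a", "b", "c"), [("a", "b"), ("b", "c")]))


def random_discretized(rng, n_genes, m, missing_rate=0.0, prefix="g"):
    states = rng.integers(0, 3, size=(n_genes, m)).astype(np.int8)
    if missing_rate:
        states[rng.random(states.shape) < missing_rate] = -1
    return DiscretizedMatrix(
        tuple(f"{prefix}{i}" for i in range(n_genes)),
        tuple(f"e{j}" for j in range(m)),
        states,
    )
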