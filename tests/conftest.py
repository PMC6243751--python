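import numpy as np
import pandas as pd
import pytest

from chondronet import (
    ActivationSpec,
    AdditiveModel,
    Edge,
    ExpressionMatrix,
    Node,
    NodeAliasTable,
    RegulatoryNetwork,
)


@pytest.fixture
def toggle_network():
    """Mutual-inhibition toggle switch with self-activation, all slow edges."""
    return RegulatoryNetwork(
        [Node("X"), Node("Y")],
        [
            Edge("X", "Y", -1, 1.0, "slow"),
            Edge("Y", "X", -1, 1.0, "slow"),
            Edge("X", "X", 1, 1.0, "slow"),
            Edge("Y", "Y", 1, 1.0, "slow"),
        ],
        NodeAliasTable(),
    )


@pytest.fixture
def toggle_model(toggle_network):
    return AdditiveModel(toggle_network, ActivationSpec("step"), markers=["X", "Y"])


@pytest.fixture
def toy_expression():
    """4 genes x 20 samples with built-in structure: B tracks A, D is noise."""
    rng = np.random.default_rng(7)
    a = rng.normal(size=20)
    b = 2.0 * a + rng.normal(scale=0.1, size=20)
    c = -a + rng.normal(scale=0.3, size=20)
    d = rng.normal(size=20)
    values = pd.DataFrame(
        [a, b, c, d],
        index=["A", "B", "C", "D"],
        columns=[f"s{i}" for i in range(20)],
    )
    return ExpressionMatrix(values)


def chain_expression(n_samples: int, seed: int, noise: float = 0.6) -> ExpressionMatrix:
    """Linear chain A -> B -> C: A and C are conditionally independent given B."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n_samples)
    b = a + rng.normal(scale=noise, size=n_samples)
    c = b + rng.normal(scale=noise, size=n_samples)
    values = pd.DataFrame(
        [a, b, c], index=["A", "B", "C"], columns=[f"s{i}" for i in range(n_samples)]
    )
    return ExpressionMatrix(values)
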