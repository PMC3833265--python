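import numpy as np
import pytest

from actichain.network import ExpressionDataset, FunctionalNetwork, Link
from actichain.simulate import SimulationConfig, simulate_expression, simulate_network


@pytest.fixture
def path_network():
    """Undirected path A - B - C."""
    return FunctionalNetwork(links=[Link("A", "B"), Link("B", "C")])


@pytest.fixture
def four_cycle():
    """Undirected cycle 1 - 2 - 3 - 4 - 1."""
    return FunctionalNetwork(
        links=[Link("1", "2"), Link("2", "3"), Link("3", "4"), Link("4", "1")]
    )


@pytest.fixture
def small_expression():
    """Four genes, 2+2 samples, simple integer values."""
    genes = ("A", "B", "C", "D")
    samples = ("s1", "s2", "s3", "s4")
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 0.0, 1.0, 1.0],
            [5.0, 5.0, 5.0, 5.0],
            [2.0, 1.0, 4.0, 3.0],
        ]
    )
    cond = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    return ExpressionDataset(genes, samples, values, cond)


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study at the reference conditions, shared per session."""
    cfg = SimulationConfig(seed=11)
    net, targets, planted = simulate_network(cfg)
    expr = simulate_expression(net, planted, cfg)
    return cfg, net, targets, planted, expr
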