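import numpy as np
import pytest

from cytovam import ExpressionMatrix, LabeledDataset, SimulationConfig
from cytovam.simulate import simulated_labeled_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """Random log-scale expression, 12 cells x 8 genes."""
    values = rng.gamma(1.0, 1.0, size=(12, 8)) * rng.integers(0, 2, size=(12, 8))
    genes = [f"g{i}" for i in range(8)]
    cells = [f"c{i}" for i in range(12)]
    return ExpressionMatrix(values, genes, cells)


@pytest.fixture
def toy_planted():
    """Tiny two-condition dataset with one planted up and one down gene.

    Condition A cells: gene gA strongly up, gene gB strongly down relative
    to condition B; genes gC..gE identical noise across conditions.
    """
    rng = np.random.default_rng(7)
    n = 10
    base = rng.gamma(1.5, 0.7, size=(2 * n, 5))
    base[:n, 0] += 2.5   # gA up in A
    base[n:, 1] += 2.5   # gB up in B => down in A-vs-rest
    genes = ["gA", "gB", "gC", "gD", "gE"]
    cells = [f"c{i}" for i in range(2 * n)]
    labels = ["A"] * n + ["B"] * n
    return LabeledDataset(ExpressionMatrix(base, genes, cells), labels)


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default synthetic stimulation experiment."""
    return simulated_labeled_dataset(SimulationConfig(seed=11))
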