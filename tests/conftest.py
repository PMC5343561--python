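import numpy as np
import pytest

from egonet.data_io import ExpressionDataset, InteractionNetwork
from egonet.synthetic_data import SyntheticConfig, generate_dataset


def make_expression(values, n_cases, gene_prefix="g"):
    """Build a validated ExpressionDataset from a raw matrix and a case count."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    labels = {
        s: ("case" if i < n_cases else "control") for i, s in enumerate(samples)
    }
    return ExpressionDataset(genes=genes, samples=samples, values=values, labels=labels)


@pytest.fixture
def null_expression():
    """25-sample (19 case / 6 control) pure-noise dataset, fixed seed."""
    rng = np.random.default_rng(123)
    return make_expression(rng.normal(size=(12, 25)), n_cases=19)


@pytest.fixture(scope="session")
def default_synthetic():
    """One default synthetic dataset shared by read-only tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture
def line_network():
    """A 4-node path a-b-c-d with unit weights."""
    return InteractionNetwork.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
    )
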