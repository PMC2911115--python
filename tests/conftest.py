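import numpy as np
import pytest

from g1snet.pipeline import run_synthetic
from g1snet.simulate import generate_dataset, split_truth_controls


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across the suite."""
    return generate_dataset(seed=7)


@pytest.fixture(scope="session")
def controls_benchmarks(dataset):
    return split_truth_controls(dataset.truth, dataset.genes, seed=3)


@pytest.fixture(scope="session")
def synthetic_run():
    """Full in-memory analysis (dataset, controls, benchmarks, per-TF results)."""
    return run_synthetic(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
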