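import numpy as np
import pytest

from hydml.core import MethylationMatrix, SampleLabels
from hydml.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort with strong planted signal for selector-level tests."""
    return simulate_cohort(
        n_normal=15, n_tumor=15, n_loci=200, n_dml=10, effect_size=0.4, seed=42
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_matrix(rng, n_loci=8, n_samples=6, missing_rate=0.0):
    values = rng.random((n_loci, n_samples))
    if missing_rate:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return MethylationMatrix(
        [f"cg{i:04d}" for i in range(n_loci)],
        [f"S{j}" for j in range(n_samples)],
        values,
    )


def balanced_labels(sample_ids):
    n = len(sample_ids)
    return SampleLabels(sample_ids, np.array([0] * (n // 2) + [1] * (n - n // 2)))
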