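import numpy as np
import pytest

from polarmace.polar import MeasurementMatrix
from polarmace.synthetic import GeneratorConfig, simulate_cohort
from polarmace.texture import DiscretizationRule


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_matrix(rng):
    return MeasurementMatrix(rng.uniform(0.1, 4.0, size=(16, 36)))


@pytest.fixture
def random_matrices(rng):
    return [MeasurementMatrix(rng.uniform(0.1, 4.0, size=(16, 36))) for _ in range(5)]


@pytest.fixture
def rule():
    # spans the fixtures' [0.1, 4.0] range
    return DiscretizationRule(bin_width=(4.0 - 0.1) / 16, origin=0.1)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but event-rich synthetic cohort for cheap pipeline tests."""
    records, truths = simulate_cohort(GeneratorConfig(n_patients=60, seed=7))
    return records, truths
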