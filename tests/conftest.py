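import numpy as np
import pytest

from hippogen.simcore import DamageCoverageParams, DemographicModel, simulate_dataset


@pytest.fixture(scope="session")
def small_truth():
    """A small clean quartet dataset shared by several tests: 40 windows
    of 2 kb, one diploid per ingroup species, no damage."""
    model = DemographicModel(mu=5e-8)
    truth, _ = simulate_dataset(model, n_windows=40, window_length=2000, damage=None, seed=11)
    return truth


@pytest.fixture(scope="session")
def small_called():
    """Simulated + observed + consensify-called quartet (clean, high
    coverage) for pipeline-level tests."""
    from hippogen.workflows import simulate_called_genomes

    model = DemographicModel(mu=5e-8)
    truth, genomes = simulate_called_genomes(
        model, n_windows=30, window_length=2000, coverage=DamageCoverageParams(coverage=12.0), seed=3
    )
    return truth, genomes
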