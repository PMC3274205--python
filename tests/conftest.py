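import numpy as np
import pytest

from ramanforensiq.pipeline import ExperimentConfig, preprocess
from ramanforensiq.synthetic import (
    SimulationConfig,
    component_library,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def library():
    """The frozen 8-component chemical library on the working grid."""
    return component_library()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact noisy three-fluid campaign (6 donors x 4 spots per fluid),
    vector-normalized, for fast classifier tests."""
    cfg = SimulationConfig(n_samples_per_fluid=6, spots_per_sample=4, seed=11)
    return preprocess(simulate_dataset(cfg), ExperimentConfig())


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 17 donors per fluid, 10 spots each,
    peak SNR 25, seed 42; vector-normalized."""
    cfg = SimulationConfig(seed=42)
    return preprocess(simulate_dataset(cfg), ExperimentConfig())


@pytest.fixture(scope="session")
def noise_free_semen(library):
    """200 noise-free, baseline-free semen spot spectra (20 donors x 10)."""
    cfg = SimulationConfig(
        n_samples_per_fluid=20,
        spots_per_sample=10,
        peak_snr=np.inf,
        baseline_strength=0.0,
        seed=7,
    )
    return simulate_dataset(cfg).select("semen")


@pytest.fixture(scope="session")
def noise_free_blood():
    cfg = SimulationConfig(
        n_samples_per_fluid=20,
        spots_per_sample=10,
        peak_snr=np.inf,
        baseline_strength=0.0,
        seed=7,
    )
    return simulate_dataset(cfg).select("blood")
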