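"""Shared fixtures: small planted-structure datasets built at test time."""

import numpy as np
import pytest

from oscirsa import (GeneratorSpec, PlantedComponent, TFGrid,
                     simulate_meg_epochs, simulate_reference_rdms)


@pytest.fixture(scope="session")
def small_refs():
    """Reference RDM pair over 16 conditions (low/high geometries)."""
    return simulate_reference_rdms(16, 0.3, seed=11, latent_dim=12)


@pytest.fixture(scope="session")
def power_coded_epochs():
    """Noise-free single-trial epochs with one power-coded 20 Hz component."""
    rng = np.random.default_rng(5)
    comp = PlantedComponent(freq=20.0, time_window=(0.0, 0.6), coding="power",
                            geometry=rng.standard_normal((8, 5)),
                            amplitude_gain=4.0)
    spec = GeneratorSpec(n_conditions=8, n_sensors=12, n_trials=1,
                         components=[comp], noise_scale=0.0, seed=7)
    return spec, simulate_meg_epochs(spec)


@pytest.fixture(scope="session")
def phase_coded_epochs():
    """Noise-free single-trial epochs with one phase-coded 10 Hz component."""
    rng = np.random.default_rng(6)
    comp = PlantedComponent(freq=10.0, time_window=(0.0, 0.8), coding="phase",
                            geometry=rng.standard_normal((8, 5)),
                            phase_gain=2.0)
    spec = GeneratorSpec(n_conditions=8, n_sensors=12, n_trials=1,
                         components=[comp], noise_scale=0.0, seed=9)
    return spec, simulate_meg_epochs(spec)


@pytest.fixture()
def tiny_grid():
    return TFGrid(np.array([10.0, 20.0]), np.array([0.2, 0.4]))
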