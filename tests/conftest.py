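import numpy as np
import pytest

from gabacircuit.simulate import (
    PlantedCellParams,
    PscSim,
    SimConfig,
    simulate_psc_recording,
    simulate_session_set,
    simulate_voltage_sweeps,
)


@pytest.fixture(scope="session")
def small_session_set():
    """Short sessions for I/O and plumbing tests (not detection power)."""
    cfg = SimConfig(
        n_neurons=12, session_length=200.0, n_stimuli_per_session=12,
        min_interval=6.0, max_interval=9.0, seed=7,
    )
    return simulate_session_set(cfg)


@pytest.fixture(scope="session")
def full_session_set():
    """Full 900-s protocol at a small neuron count, for detection tests."""
    return simulate_session_set(SimConfig(n_neurons=30, seed=5))


@pytest.fixture(scope="session")
def sbc_sweeps():
    return simulate_voltage_sweeps(PlantedCellParams(archetype="SBC-like"))


@pytest.fixture(scope="session")
def ngf_sweeps():
    return simulate_voltage_sweeps(PlantedCellParams(archetype="NGF-like"))


@pytest.fixture(scope="session")
def psc_trials():
    return simulate_psc_recording(PscSim(ipsc_release_probability=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
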