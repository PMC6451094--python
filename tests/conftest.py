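"""Shared fixtures: small noiseless and noisy synthetic populations."""

import numpy as np
import pytest

from smfret.config import SimulationConfig, linear_chain_matrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def noiseless_config():
    """Exact forward model: no noise, no background, ideal detection."""
    return SimulationConfig(
        n_molecules=5,
        n_frames=200,
        seed=0,
        background=(0.0, 0.0),
        noise_model="gaussian_read",
        read_noise_sd=0.0,
        crosstalk_alpha=0.0,
        gamma=1.0,
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.0,
    )


@pytest.fixture()
def default_config():
    """Default SNR conditions used across recovery tests."""
    return SimulationConfig(n_molecules=20, n_frames=400, seed=0)


@pytest.fixture()
def three_state_chain():
    return linear_chain_matrix([0.1, 0.05], [0.05, 0.1])
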