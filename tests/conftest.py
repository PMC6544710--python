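"""Shared fixtures: parameter sets, single-block configs, short simulations."""

import numpy as np
import pytest

import mhhnet as M


@pytest.fixture(scope="session")
def tg_params():
    """Default trigeminal-ganglion block (Cm 5 pF, gNaS 100 nS)."""
    return M.BlockParams()


@pytest.fixture(scope="session")
def oscillating_params():
    """A block inside the model's oscillatory gNaS regime."""
    return M.BlockParams(gNaS=280.0)


def single_block_config(params, convention=None):
    """A one-block 'chain' (zero coupling) for direct block simulation."""
    kwargs = {} if convention is None else {"convention": convention}
    return M.NetworkConfig(blocks=(params,), G=0.0, tdcs_target=params.label, **kwargs)


@pytest.fixture(scope="session")
def chain_config():
    return M.NetworkConfig()


def constant_stimulus(value, duration):
    return M.Stimulus(np.array([0.0]), np.array([float(value)]), float(duration))


@pytest.fixture(scope="session")
def short_chain_trace(chain_config):
    """One 150 ms constant-input chain run shared by several metric tests."""
    return M.simulate(chain_config, constant_stimulus(30.0, 150.0), dt=0.02)
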