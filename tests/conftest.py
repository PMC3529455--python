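import numpy as np
import pytest

from gapcpg.model_core import ModelParams
from gapcpg.network import GapNetwork
from gapcpg.simulate import StimulusProtocol, run_simulation
from gapcpg.experiments import default_reduced_setup, run_cell, \
    TWO_GROUP_POINT


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def single_net():
    """One uncoupled neuron."""
    return GapNetwork(1, np.empty((0, 2), dtype=np.int64), g_gap=0.0)


def constant_protocol(I, t_end, seed=0, **kw):
    """Un-jittered constant current step from t=0."""
    return StimulusProtocol(amplitude=I, onset_mean=0.0, onset_jitter=0.0,
                            offset_mean=t_end + 1.0, offset_jitter=0.0,
                            seed=seed, **kw)


@pytest.fixture(scope="session")
def pinned_default_runs():
    """Ten seeds of the planar reduced-model run at the published settings
    (I = 0.1, g_gap = 0.003 uS, 10x10 lattice, radius 5, 50%)."""
    out = []
    for seed in range(10):
        p, net, proto = default_reduced_setup(seed=seed, I_input=0.1,
                                              g_gap=0.003)
        out.append(run_cell(p, net, proto, seed=seed))
    return out


@pytest.fixture(scope="session")
def two_group_runs():
    """Five seeds at the calibrated two-group operating point."""
    out = []
    for seed in range(5):
        p, net, proto = default_reduced_setup(seed=seed, **TWO_GROUP_POINT)
        out.append((net,) + run_cell(p, net, proto, seed=seed))
    return out
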