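import numpy as np
import pytest

from divnorm.datatypes import (
    Condition,
    ConductanceParams,
    DelayModel,
    GridSpec,
    SynapticKinetics,
    Trace,
)
from divnorm.synthgen import ExperimentConfig, generate_experiment, generate_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec(4, 4)


@pytest.fixture
def passive_params():
    return ConductanceParams(duration_ms=80.0)


@pytest.fixture
def dynamic_delay():
    return DelayModel(delta_min_ms=2.0, k_per_ns=0.5, m_ms=8.15, mode="dynamic")


@pytest.fixture
def exc_kinetics():
    return SynapticKinetics(g_bar=1.0, tau_rise_ms=2.0, tau_decay_ms=10.0)


@pytest.fixture
def small_network(small_grid):
    return generate_network(small_grid, seed=7)


@pytest.fixture(scope="session")
def demo_experiment():
    """A small multi-condition experiment shared across tests."""
    cfg = ExperimentConfig(
        grid_rows=4, grid_cols=4, design={1: 10, 2: 4, 5: 4}, n_repeats=3,
        conditions=(Condition.CC_CONTROL, Condition.CC_GABAZINE,
                    Condition.VC_MINUS70, Condition.VC_0))
    return generate_experiment(cfg, seed=21)


def make_trace(samples, dt_ms=0.05, units="mV", stim_onset_ms=None,
               baseline=None, interest=None):
    n = len(samples)
    duration = (n - 1) * dt_ms
    if stim_onset_ms is None:
        stim_onset_ms = duration / 2
    return Trace(dt_ms=dt_ms, samples=np.asarray(samples, float), units=units,
                 stim_onset_ms=stim_onset_ms,
                 baseline_window_ms=baseline or (0.0, stim_onset_ms),
                 interest_window_ms=interest or (stim_onset_ms, duration))
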