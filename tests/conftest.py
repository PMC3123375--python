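"""Shared fixtures: parameter sets, isolated-cell helpers, cached groups."""

import copy

import numpy as np
import pytest

import hstheta as hs
from hstheta.engine import SimulationConfig, integrate_trial


@pytest.fixture(scope="session")
def params():
    """The shipped control parameter set (fresh copy per access is not
    needed: tests must not mutate it — use ``copy.deepcopy`` if they do)."""
    return hs.default_parameters()


@pytest.fixture()
def params_copy(params):
    return copy.deepcopy(params)


def isolate(params, cell_class, n=1, mu_i=None, sigma_i=0.0):
    """Parameter set with a single population of ``n`` neurons, no synapses."""
    q = copy.deepcopy(params)
    for name in q["populations"]:
        q["populations"][name]["n"] = n if name == cell_class else 0
        q["populations"][name]["sigma_i"] = sigma_i
    if mu_i is not None:
        q["populations"][cell_class]["mu_i"] = mu_i
    q["projections"] = []
    return q


def run_isolated(
    params, cell_class, mu_i, duration_ms=2000.0, dt=0.05, noise_sd=0.0, seed=7
):
    """Integrate one isolated neuron through the network kernel."""
    q = isolate(params, cell_class, mu_i=mu_i)
    cfg = SimulationConfig.from_params(
        q,
        dt=dt,
        duration_ms=duration_ms,
        transient_discard_ms=0.0,
        noise_sd=noise_sd,
        seeds={"connectome": seed, "drive": seed + 1, "noise": seed + 2},
    )
    return integrate_trial(q, cfg)


@pytest.fixture(scope="session")
def control_trial(params):
    """One seeded 10-s control trial with the default noise level."""
    cfg = SimulationConfig.from_params(
        params, seeds={"connectome": 11, "drive": 21, "noise": 31}
    )
    return integrate_trial(params, cfg)


def assert_close(a, b, rtol=0.0, atol=0.0):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
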