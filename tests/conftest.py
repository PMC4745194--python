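import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliostem import ModelParameters, death_rates, kronik_forms
from gliostem.simulate import SCENARIO_NAMES, integrate, scenario

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def forms(params):
    return kronik_forms(params)


@pytest.fixture(scope="session")
def mu(params):
    return death_rates(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_16)


@pytest.fixture(scope="session")
def scenario_runs():
    """The three bundled treatment studies, integrated once per session.

    Yields {name: (scenario, trajectory, wall_seconds)}.
    """
    out = {}
    for name in SCENARIO_NAMES:
        sc = scenario(name)
        t0 = time.perf_counter()
        traj = integrate(sc.params, sc.init, sc.t_end)
        out[name] = (sc, traj, time.perf_counter() - t0)
    return out


def random_states(rng, n, scales=(1e8, 1e7, 1e7, 1e4, 1e3, 300.0, 1e5)):
    return rng.uniform(0.0, 1.0, (n, 7)) * np.asarray(scales)
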