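import numpy as np
import pytest

import radioplan as rp
from radioplan.swarm import SwarmConfig
from radioplan.planner import PrescriptionFreePlanner


@pytest.fixture(scope="session")
def scheme20():
    return rp.FractionationScheme(20)


@pytest.fixture(scope="session")
def small_phantom():
    return rp.generate_phantom(rp.small_phantom_config(), seed=11)


@pytest.fixture(scope="session")
def beamlets(small_phantom):
    return rp.generate_beamlets(small_phantom)


@pytest.fixture(scope="session")
def tcp_set1():
    return rp.tcp_parameter_set(1)


@pytest.fixture(scope="session")
def ntcp_params(small_phantom):
    return rp.ntcp_parameter_set(small_phantom.oar_names)


@pytest.fixture(scope="session")
def planner(small_phantom, beamlets, tcp_set1, ntcp_params):
    return PrescriptionFreePlanner(
        small_phantom,
        beamlets,
        tcp_set1,
        ntcp_params,
        swarm=SwarmConfig(n_particles=20, n_epochs=5, seed=7),
    )


@pytest.fixture(scope="session")
def planning_result(planner):
    """One full desk-scale prescription-free run, shared across tests."""
    return planner.run()
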