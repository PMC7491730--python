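import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import firewoodnet as fw

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return fw.ModelParams()


@pytest.fixture(scope="session")
def two_patch_network():
    """Symmetric 2-patch network: all trips go to the other patch."""
    return fw.TravelNetwork(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def small_network():
    """5-node synthetic network with a flagged focal node."""
    return fw.generate_synthetic_network(n_nodes=5, seed=7)


@pytest.fixture(scope="session")
def medium_network():
    """The calibrated study network: 100 synthetic patches."""
    return fw.generate_synthetic_network(n_nodes=100, seed=1)


def single_patch_run(params, S0, I0, B0=0.0, L0=0.5, t_end=5.0, **kw):
    """Integrate one effectively isolated patch (d = 0 on a 2-patch network).

    With d = 0 the patches decouple completely, so patch 0 follows the
    single-patch dynamics exactly; patch 1 idles at carrying capacity.
    """
    net = fw.TravelNetwork([0, 1], np.array([[0.0, 1.0], [1.0, 0.0]]))
    p = params.with_overrides(d=0.0)
    state = fw.SystemState(
        S=np.array([S0, p.K]),
        I=np.array([I0, 0.0]),
        B=np.array([B0, 0.0]),
        L=np.array([L0, L0]),
        T=np.array([I0, 0.0]),
    )
    return fw.run_simulation(net, p, initial_state=state, t_end=t_end, **kw)
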