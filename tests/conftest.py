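import numpy as np
import pandas as pd
import pytest

import effortcast as ec


@pytest.fixture(scope="session")
def world():
    return ec.generate_world(ec.WorldConfig())


@pytest.fixture(scope="session")
def small_world():
    cfg = ec.WorldConfig(n_lat=8, n_lon=12, resolution_deg=10.0,
                         years=list(range(2016, 2021)), land_fraction=0.2,
                         n_eez=2, n_ports=3, n_seamounts=5, seed=5)
    return ec.generate_world(cfg)


@pytest.fixture(scope="session")
def toy_run(world):
    """Default toy world with environment, historical network, and effort."""
    env = ec.simulate_environment(world, seed=11)
    net = ec.simulate_network(world, seed=11)
    beh = ec.BehaviorParams()
    eff = ec.simulate_effort(world, env, net, beh, seed=11)
    return {"world": world, "env": env, "net": net, "behavior": beh, "effort": eff}


@pytest.fixture(scope="session")
def feature_table(toy_run):
    return ec.build_feature_table(toy_run["world"], toy_run["env"],
                                  toy_run["effort"], toy_run["net"])
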