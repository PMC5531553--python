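import numpy as np
import pytest

import gridplace as gp
from gridplace.environment import DEFAULT_ENV
from gridplace import feedforward as ff
from gridplace import recurrent as rc
from gridplace import spatial_inputs as si


@pytest.fixture(scope="session")
def env():
    return DEFAULT_ENV


@pytest.fixture(scope="session")
def grid_pop_default():
    """Default four-module grid population at the model's grid-cell count."""
    return si.sample_grid_population(183, DEFAULT_ENV, seed=0)


@pytest.fixture(scope="session")
def grid_maps_default(grid_pop_default):
    return si.grid_population_maps(grid_pop_default, DEFAULT_ENV)


@pytest.fixture(scope="session")
def trained_ffnet():
    """Reduced MEC/LEC-partitioned feedforward net with learned weights."""
    net = ff.build_network(
        ff.InputMix(partition=True), ff.FFParams.reduced(4), seed=0
    )
    ff.learn_ec_ca3(net)
    return net


@pytest.fixture(scope="session")
def recurrent_run():
    """Reduced recurrent net simulated for 40 s at the default kernel width."""
    params = rc.RecurrentNetParams.reduced()
    traj = rc.generate_trajectory(duration_s=40.0, seed=0)
    centers = rc.assign_place_centers(params.n_e, DEFAULT_ENV, seed=1)
    weights = rc.build_recurrent_weights(params, centers, seed=2)
    record = rc.simulate(params, weights, centers, traj, seed=3)
    maps = rc.rate_maps_from_record(record, DEFAULT_ENV)
    return {
        "params": params,
        "trajectory": traj,
        "centers": centers,
        "weights": weights,
        "record": record,
        "maps": maps,
    }
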