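import logging

import numpy as np
import pytest

import rootkin as rk

logging.getLogger("rootkin").setLevel(logging.ERROR)


@pytest.fixture
def straight_trajectory():
    """Noise-free vertical growth: 1 cm/day for 7 days at 3-min sampling."""
    params = rk.GrowthParams(axial_rate=1.0, nutation_amplitude=0.0)
    return rk.generate_trajectory(params, plant_id="straight")


@pytest.fixture
def helix_trajectory():
    """Clean circular nutation (radius 0.2 cm, 90 min) on 1 cm/day growth."""
    params = rk.GrowthParams(
        axial_rate=1.0, nutation_amplitude=0.2, nutation_period=90.0
    )
    return rk.generate_trajectory(params, plant_id="helix")


def make_trajectory(xyz, dt=180.0, plant_id="t"):
    """Trajectory from an (n, 3) coordinate array on a uniform time grid."""
    xyz = np.asarray(xyz, dtype=float)
    t = np.arange(len(xyz)) * dt
    return rk.Trajectory(plant_id=plant_id, species="synthetic", t=t, xyz=xyz)


@pytest.fixture
def make_traj():
    return make_trajectory
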