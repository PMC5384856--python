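import numpy as np
import pytest

import shellfield as sf


@pytest.fixture(scope="session")
def dmp():
    return sf.dmp_gauche_gauche()


@pytest.fixture(scope="session")
def water_model():
    return sf.load_water_model()


@pytest.fixture(scope="session")
def small_traj(dmp):
    """Short droplet trajectory for I/O and field plumbing tests."""
    cell = sf.SimulationCell("droplet", 7.0)
    params = sf.MCParams(temperature=298.0, n_sweeps=1500, seed=11, sample_stride=100)
    return sf.mc_sample(dmp, 20, cell, params), cell


@pytest.fixture(scope="session")
def shell_trajectories(dmp):
    """Reduced-droplet trajectories at 298 and 330 K for the qualitative
    shell-structure checks: 60 waters (≈ bulk density) in a 7.6 Å droplet,
    6e5 single-molecule moves with the first half discarded, both
    temperatures launched from the identical seed-7 initial configuration
    so differences are attributable to temperature."""
    cell = sf.SimulationCell("droplet", 7.6)
    out = {}
    for temp in (298.0, 330.0):
        params = sf.MCParams(
            temperature=temp, n_sweeps=600_000, equilibration_fraction=0.5,
            seed=7, sample_stride=200, max_translation=0.3, max_rotation=0.45,
        )
        out[temp] = sf.mc_sample(dmp, 60, cell, params)
    return out, cell


def make_frame(dmp, water_model, oxygens, quats=None):
    oxygens = np.asarray(oxygens, dtype=float)
    if quats is None:
        quats = np.tile([0.0, 0.0, 0.0, 1.0], (len(oxygens), 1))
    return sf.Frame(dmp, oxygens, np.asarray(quats, dtype=float), water_model)
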