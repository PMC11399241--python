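"""Shared fixtures: small laser fields, scenes and simulated stacks.

All stacks are generated at reduced problem sizes (32 x 32 pixels or
smaller, 64 delay steps) so the whole suite runs on one CPU in minutes;
noiseless variants serve as oracles.
"""

from __future__ import annotations

import numpy as np
import pytest

import ixflim


@pytest.fixture(scope="session")
def t_axis():
    return ixflim.default_t_axis()  # 512 bins over 10 ns


@pytest.fixture(scope="session")
def irf():
    return ixflim.default_irf()  # 50 ps FWHM, t0 = 0.5 ns


@pytest.fixture(scope="session")
def small_laser():
    return ixflim.LaserField.gaussian(600.0, 100.0, 520.0, 680.0,
                                      n_delays=64)


@pytest.fixture(scope="session")
def oxonol_small():
    """Capillary fixture at test scale with its simulated stack."""
    scene, laser, truth = ixflim.make_fixture(
        "oxonol_capillaries", {"shape": (32, 32), "n_delays": 64})
    t = ixflim.default_t_axis()
    stack = ixflim.simulate_stack(scene, laser, t, ixflim.default_irf(),
                                  1e6, seed=1)
    return scene, laser, truth, stack


@pytest.fixture(scope="session")
def oxonol_cube(oxonol_small):
    _, _, truth, stack = oxonol_small
    cube = ixflim.reconstruct(stack, normalize=False)
    return cube, truth


@pytest.fixture(scope="session")
def single_species_noiseless(t_axis, irf):
    """Uniform one-species scene, noiseless, full 301-step delay scan."""
    laser = ixflim.LaserField.gaussian(600.0, 100.0, 520.0, 680.0,
                                       n_delays=301)
    species = ixflim.Species(
        "dye", ixflim.gaussian_band(laser.wavelength_grid, 590.0, 40.0),
        decay_rate=1.0)
    scene = ixflim.Scene((4, 4), [(species, np.ones((4, 4)))])
    stack = ixflim.simulate_stack(scene, laser, t_axis, irf, 1e6, seed=0,
                                  noiseless=True)
    return scene, laser, species, stack


def cosine_similarity(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
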