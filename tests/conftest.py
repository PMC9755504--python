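"""Shared fixtures: small grids and synthetic fields."""

import numpy as np
import pytest

import kmdev as km


@pytest.fixture(scope="session")
def small_grid():
    """Single-frequency grid small enough for fast unit tests."""
    return km.AcquisitionGrid(
        shape=(32, 32, 8), spacing=(1.6, 1.6, 2.0), n_timesteps=8, frequencies=(30.0,)
    )


@pytest.fixture(scope="session")
def study_grid():
    """Grid matching the acceptance scenarios: four frequencies."""
    return km.AcquisitionGrid(
        shape=(64, 64, 24),
        spacing=(1.6, 1.6, 2.0),
        n_timesteps=8,
        frequencies=(20.0, 25.0, 30.0, 35.0),
    )


def plane_wave_field(
    grid,
    sws=1.2,
    pr=np.inf,
    propagation=(1.0, 0.0, 0.0),
    polarization=(0.0, 0.0, 1.0),
    amplitude=10.0,
    phase=0.0,
    noise_sigma=0.0,
    seed=0,
):
    """Single plane shear wave filling the grid."""
    comp = km.Compartment(mask=np.ones(grid.shape, bool), sws=sws, pr=pr)
    src = km.ShearSource(
        propagation=propagation,
        polarization=polarization,
        amplitude=amplitude,
        phase=phase,
    )
    spec = km.PhantomSpec(
        grid=grid,
        compartments=(comp,),
        sources=(src,),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return km.synthesize(spec)


@pytest.fixture(scope="session")
def plane_field_30hz(small_grid):
    return plane_wave_field(small_grid, sws=1.2)


@pytest.fixture(scope="session")
def brain_phantom():
    """Brain-like phantom on the default 64×64×24 grid (deterministic)."""
    spec, mask = km.brain_like_phantom(seed=7)
    return spec, mask, km.synthesize(spec)
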