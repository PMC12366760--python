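"""Shared fixtures: the validation-phantom medium and a seeded MC history set."""

from __future__ import annotations

import numpy as np
import pytest

from scotkit.medium import BoxInclusion, OpticalMedium
from scotkit import speckle


#: phantom of the linearity experiments
@pytest.fixture(scope="session")
def phantom():
    return OpticalMedium(mua=0.0, musp=1.0, n=1.33, wavelength_nm=800.0, Db0=1e-6)


@pytest.fixture(scope="session")
def tau_grid():
    return speckle.default_tau_grid(2e-3)


#: tagged perturbation regions of the session MC run, in order
MC_REGIONS = (
    BoxInclusion((15.0, 0.0, 30.0), (60.0, 50.0, 40.0)),  # large inclusion
    BoxInclusion((15.0, 0.0, 30.0), (10.0, 10.0, 10.0)),  # small inclusion
    BoxInclusion((0.0, 0.0, 30.0), (30.0, 50.0, 40.0)),   # spatial R1
    BoxInclusion((30.0, 0.0, 30.0), (30.0, 50.0, 40.0)),  # spatial R2
)


@pytest.fixture(scope="session")
def mc_regions():
    return MC_REGIONS


@pytest.fixture(scope="session")
def mc_run(phantom):
    """Seeded 1.2M-photon history set at rho = 30 mm, reused across tests."""
    from scotkit import montecarlo as mc

    return mc.simulate_histories(
        phantom, regions=MC_REGIONS, rho=30.0, n_photons=1_200_000, seed=42
    )
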