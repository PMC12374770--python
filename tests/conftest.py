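"""Shared fixtures: study media, geometries, and a moderate Monte Carlo
baseline reused by the gating and property tests."""

from __future__ import annotations

import numpy as np
import pytest

from layertof.diffusion_forward import two_layer_td_reflectance
from layertof.media import DetectionGeometry, OpticalLayer, TimeGrid, TwoLayerMedium
from layertof.mc_simulator import MCConfig, mc_layers_from_medium, run_layered_mc


@pytest.fixture(scope="session")
def geometry() -> DetectionGeometry:
    return DetectionGeometry(rho=2.0, wavelength=850.0)


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid(0.0, 5.0, 200)


@pytest.fixture(scope="session")
def study_medium_40() -> TwoLayerMedium:
    """Maternal layer over the 40%-TOI fetal condition."""
    return TwoLayerMedium(
        top=OpticalLayer(mua=0.11, musp=11.19, n=1.4, thickness=0.96),
        bottom=OpticalLayer(mua=0.09333, musp=9.551, n=1.4),
    )


@pytest.fixture(scope="session")
def study_density(study_medium_40, geometry, grid):
    """Noise-free forward transient of the study medium at rho = 2 cm."""
    return two_layer_td_reflectance(study_medium_40, geometry, grid)


@pytest.fixture(scope="session")
def mc_baseline(study_medium_40):
    """Moderate-size Monte Carlo baseline of the study medium (pathlength
    statistics for pulsatile synthesis and MC unit checks)."""
    cfg = MCConfig(n_photons=400_000, seed=123, rho=2.0, t_max=5.0, n_bins=200)
    return run_layered_mc(mc_layers_from_medium(study_medium_40), cfg)
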