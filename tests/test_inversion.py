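"""Optical-property fits: exact noise-free recovery, robustness to
initialization, CW degeneracy behaviour, and contract errors."""

import numpy as np
import pytest

from layertof.diffusion_forward import (
    TwoLayerEvaluator,
    semi_infinite_td_reflectance,
    two_layer_cw_reflectance,
    two_layer_td_reflectance,
)
from layertof.inversion import FitConfig, fit_homogeneous_td, fit_two_layer_cw, fit_two_layer_td
from layertof.media import DetectionGeometry, OpticalLayer, Transient, TwoLayerMedium
from layertof.mc_simulator import sample_counts

TRUTH = {"mua1": 0.11, "musp1": 11.19, "mua2": 0.09333, "musp2": 9.551}


def test_homogeneous_noise_free_exact(geometry, grid):
    density = semi_infinite_td_reflectance(OpticalLayer(0.1, 10.0, 1.4), 1.0, geometry, grid)
    fit = fit_homogeneous_td(Transient(grid, density.values * 3.0), geometry)
    assert fit.converged
    assert fit["mua"] == pytest.approx(0.1, rel=1e-6)
    assert fit["musp"] == pytest.approx(10.0, rel=1e-6)
    assert fit["amplitude"] == pytest.approx(3.0, rel=1e-6)
    assert fit.residual_norm < 1e-8


def test_homogeneous_poisson_recovery(geometry, grid):
    density = semi_infinite_td_reflectance(OpticalLayer(0.1, 10.0, 1.4), 1.0, geometry, grid)
    errs_mua, errs_musp = [], []
    for seed in range(8):
        counts = sample_counts(density, 1e6, seed)
        fit = fit_homogeneous_td(counts, geometry)
        errs_mua.append(abs(fit["mua"] - 0.1) / 0.1)
        errs_musp.append(abs(fit["musp"] - 10.0) / 10.0)
    assert np.median(errs_mua) < 0.03
    assert np.median(errs_musp) < 0.05


def _matched_evaluator(geometry, grid):
    """Evaluator with the same synthesis settings as the generator, so the
    noise-free fits probe optimizer convergence, not discretization."""
    return TwoLayerEvaluator(
        geometry=geometry, grid=grid, thickness=0.96, pad_factor=4, check=False
    )


def test_two_layer_noise_free_exact_from_truth(study_density, geometry, grid):
    cfg = FitConfig(init={**TRUTH, "amplitude": 1.0})
    fit = fit_two_layer_td(
        study_density, geometry, 0.96, cfg, evaluator=_matched_evaluator(geometry, grid)
    )
    assert fit.converged
    for name, value in TRUTH.items():
        assert fit[name] == pytest.approx(value, rel=1e-6)


@pytest.mark.parametrize("factor", [0.5, 1.5])
def test_two_layer_noise_free_from_perturbed_init(study_density, geometry, grid, factor):
    """Noise-free fits return to the generating parameters from +-50%
    perturbed initializations."""
    init = {k: v * factor for k, v in TRUTH.items()}
    init["amplitude"] = 1.0 * factor
    fit = fit_two_layer_td(
        study_density,
        geometry,
        0.96,
        FitConfig(init=init),
        evaluator=_matched_evaluator(geometry, grid),
    )
    assert fit.converged
    for name, value in TRUTH.items():
        assert fit[name] == pytest.approx(value, rel=1e-3)


def test_two_layer_auto_init_poisson(study_density, geometry):
    """With the automatic homogeneous initialization, a noisy fit still lands
    near the truth (deep-layer absorption within a few percent)."""
    counts = sample_counts(study_density, 1e6, seed=3)
    fit = fit_two_layer_td(counts, geometry, 0.96)
    assert fit.converged
    assert abs(fit["mua2"] - TRUTH["mua2"]) / TRUTH["mua2"] < 0.08


def test_low_tail_counts_warns(study_density, geometry, grid):
    """A transient whose late tail is empty triggers the deep-layer
    sensitivity warning."""
    counts = sample_counts(study_density, 1e6, seed=0)
    t_peak = counts.t[int(np.argmax(counts.values))]
    truncated = np.where(counts.t > 2.0 * t_peak, 0.0, counts.values)
    sparse = Transient(grid, truncated, "counts", geometry)
    with pytest.warns(UserWarning, match="deep-layer"):
        fit_two_layer_td(
            sparse, geometry, 0.96, FitConfig(init={**TRUTH, "amplitude": 1e6 * 0.02})
        )


def test_covariance_grows_with_top_thickness(geometry, grid):
    """Deep-layer identifiability degrades monotonically as the top layer
    thickens (covariance proxy on mua2)."""
    sigmas = []
    for thickness in (0.5, 1.0, 1.5):
        medium = TwoLayerMedium(
            top=OpticalLayer(0.11, 11.19, 1.4, thickness),
            bottom=OpticalLayer(0.09333, 9.551, 1.4),
        )
        density = two_layer_td_reflectance(medium, geometry, grid, check=False)
        scaled = Transient(grid, density.values * (1e6 / (density.values.sum())), "model_density")
        cfg = FitConfig(init={**TRUTH, "amplitude": 1e6 / density.values.sum()})
        fit = fit_two_layer_td(scaled, geometry, thickness, cfg)
        sigmas.append(fit.stderr("mua2"))
    assert sigmas[0] < sigmas[1] < sigmas[2]


def test_cw_noise_free_exact():
    medium = TwoLayerMedium(
        top=OpticalLayer(0.11, 11.19, 1.4, 0.96), bottom=OpticalLayer(0.09333, 9.551, 1.4)
    )
    rhos = np.array([1.0, 2.0, 3.0, 4.0])
    intensities = two_layer_cw_reflectance(medium, rhos)
    fit = fit_two_layer_cw(
        intensities, rhos, 0.96, FitConfig(free=("mua1", "musp1", "mua2", "musp2"), init=TRUTH),
        amplitude=1.0,
    )
    assert fit.converged
    for name, value in TRUTH.items():
        assert fit[name] == pytest.approx(value, rel=1e-5)


def test_cw_homogeneous_degeneracy():
    """Fitting a homogeneous truth with the two-layer model recovers equal
    layer absorptions."""
    medium = TwoLayerMedium(
        top=OpticalLayer(0.1, 10.0, 1.4, 0.96), bottom=OpticalLayer(0.1, 10.0, 1.4)
    )
    rhos = np.array([1.0, 2.0, 3.0, 4.0])
    intensities = two_layer_cw_reflectance(medium, rhos)
    fit = fit_two_layer_cw(intensities, rhos, 0.96, amplitude=1.0)
    assert fit["mua1"] == pytest.approx(fit["mua2"], rel=0.02)


def test_cw_underdetermined_rejected():
    with pytest.raises(ValueError, match="distances"):
        fit_two_layer_cw(np.array([1.0, 0.5]), np.array([1.0, 2.0]), 0.96, amplitude=1.0)
    # profiled amplitude consumes one degree of freedom
    with pytest.raises(ValueError, match="distances"):
        fit_two_layer_cw(
            np.array([1.0, 0.5, 0.2, 0.1]), np.array([1.0, 2.0, 3.0, 4.0]), 0.96
        )


def test_fit_config_validation():
    with pytest.raises(ValueError, match="loss"):
        FitConfig(loss="huber")
    with pytest.raises(ValueError, match="bounds"):
        FitConfig(bounds={"mua": (1.0, 0.1)})
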