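"""Forward-model oracles: closed-form limits, Beer-Lambert scaling,
monotone depth sensitivity, and CW/TD internal consistency."""

import numpy as np
import pytest

from layertof.diffusion_forward import (
    TwoLayerEvaluator,
    boundary_factor_A,
    semi_infinite_td_reflectance,
    two_layer_cw_reflectance,
    two_layer_td_reflectance,
)
from layertof.media import C_CM_PER_NS, DetectionGeometry, OpticalLayer, TimeGrid, TwoLayerMedium


def test_boundary_factor_matched_is_one():
    assert boundary_factor_A(1.4, 1.4) == 1.0
    assert boundary_factor_A(1.0, 1.0) == 1.0


def test_boundary_factor_tissue_air():
    # standard value for n_rel = 1.4 is close to 2.95
    assert boundary_factor_A(1.4, 1.0) == pytest.approx(2.95, abs=0.08)


def test_semi_infinite_causality_and_decay(geometry, grid):
    layer = OpticalLayer(mua=0.1, musp=10.0, n=1.4)
    tr = semi_infinite_td_reflectance(layer, 1.0, geometry, grid)
    assert np.all(tr.values >= 0)
    assert tr.values[0] == pytest.approx(0.0, abs=1e-12)  # t -> 0+ limit
    assert tr.values[-1] < 1e-3 * tr.values.max()  # absorption decay


def test_semi_infinite_beer_lambert_exact(geometry, grid):
    """Adding delta to mua multiplies the closed form by exp(-v delta t) exactly."""
    delta = 0.05
    base = semi_infinite_td_reflectance(OpticalLayer(0.1, 10.0, 1.4), 1.0, geometry, grid)
    more = semi_infinite_td_reflectance(OpticalLayer(0.1 + delta, 10.0, 1.4), 1.0, geometry, grid)
    v = C_CM_PER_NS / 1.4
    expected = base.values * np.exp(-v * delta * grid.centers)
    np.testing.assert_allclose(more.values, expected, rtol=1e-12)


def test_two_layer_homogeneous_limit(geometry, grid):
    """Equal layers reduce the layered solution to the semi-infinite closed
    form within 1% wherever the signal exceeds 1e-4 of its peak."""
    layer = OpticalLayer(mua=0.11, musp=11.19, n=1.4)
    medium = TwoLayerMedium(
        top=OpticalLayer(0.11, 11.19, 1.4, thickness=0.96), bottom=layer
    )
    layered = two_layer_td_reflectance(medium, geometry, grid)
    closed = semi_infinite_td_reflectance(layer, 1.0, geometry, grid)
    mask = closed.values > 1e-4 * closed.values.max()
    rel = np.abs(layered.values[mask] - closed.values[mask]) / closed.values[mask]
    assert rel.max() < 0.01


def test_two_layer_deep_layer_unreachable(geometry, grid):
    """With a 10 cm top layer the bottom layer cannot influence the signal."""
    medium = TwoLayerMedium(
        top=OpticalLayer(0.11, 11.19, 1.4, thickness=10.0),
        bottom=OpticalLayer(0.22, 11.19, 1.4),
    )
    layered = two_layer_td_reflectance(medium, geometry, grid)
    closed = semi_infinite_td_reflectance(OpticalLayer(0.11, 11.19, 1.4), 1.0, geometry, grid)
    mask = closed.values > 1e-4 * closed.values.max()
    rel = np.abs(layered.values[mask] - closed.values[mask]) / closed.values[mask]
    assert rel.max() < 1e-3


@pytest.mark.parametrize("delta", [0.005, 0.02])
def test_two_layer_global_beer_lambert(geometry, grid, delta):
    """A common absorption offset in both layers rescales the transient by
    exp(-v delta t) within 0.5% on populated bins."""
    ev = TwoLayerEvaluator(geometry=geometry, grid=grid, check=False)
    base = ev.td(0.11, 11.19, 0.09333, 9.551)
    more = ev.td(0.11 + delta, 11.19, 0.09333 + delta, 9.551)
    v = C_CM_PER_NS / 1.4
    mask = base > 1e-4 * base.max()
    ratio = more[mask] / (base[mask] * np.exp(-v * delta * grid.centers[mask]))
    assert np.abs(ratio - 1.0).max() < 0.005


def test_two_layer_depth_sensitivity(geometry, grid):
    """More fetal absorption depresses the late tail but leaves the rising
    edge nearly unchanged -- the depth-sensitivity mechanism."""
    ev = TwoLayerEvaluator(geometry=geometry, grid=grid, check=False)
    base = ev.td(0.11, 11.19, 0.09333, 9.551)
    dark = ev.td(0.11, 11.19, 0.12, 9.551)
    t = grid.centers
    t_peak = t[np.argmax(base)]
    late = (t > 2 * t_peak) & (base > 1e-6 * base.max())
    assert np.all(dark[late] < base[late])
    rising = (base >= 0.1 * base.max()) & (t <= t_peak)
    rel = np.abs(dark[rising] / base[rising] - 1.0)
    assert rel.max() < 0.01


def test_energy_decreases_with_absorption(geometry, grid):
    ev = TwoLayerEvaluator(geometry=geometry, grid=grid, check=False)
    totals = [
        ev.td(mua1, 11.19, mua2, 9.551).sum()
        for mua1, mua2 in [(0.08, 0.09333), (0.11, 0.09333), (0.14, 0.09333)]
    ]
    assert totals[0] > totals[1] > totals[2]
    totals2 = [ev.td(0.11, 11.19, m2, 9.551).sum() for m2 in (0.07, 0.09333, 0.12)]
    assert totals2[0] > totals2[1] > totals2[2]


def test_cw_equals_time_integral():
    """Steady state is the time integral of the TD solution (checked in the
    homogeneous limit against the closed form, and against the layered TD)."""
    layer = OpticalLayer(0.11, 11.19, 1.4)
    medium = TwoLayerMedium(top=OpticalLayer(0.11, 11.19, 1.4, 0.96), bottom=layer)
    geom = DetectionGeometry(rho=2.0)
    long_grid = TimeGrid(0.0, 12.0, 1200)
    closed = semi_infinite_td_reflectance(layer, 1.0, geom, long_grid)
    integral = closed.values.sum() * long_grid.dt
    cw = two_layer_cw_reflectance(medium, [2.0])[0]
    assert cw == pytest.approx(integral, rel=0.01)

    # two-layer internal consistency at the study conditions
    medium2 = TwoLayerMedium(
        top=OpticalLayer(0.11, 11.19, 1.4, 0.96), bottom=OpticalLayer(0.09333, 9.551, 1.4)
    )
    td = two_layer_td_reflectance(medium2, geom, long_grid, check=False)
    cw2 = two_layer_cw_reflectance(medium2, [2.0])[0]
    assert cw2 == pytest.approx(td.values.sum() * long_grid.dt, rel=0.02)


def test_cw_monotone_in_distance():
    medium = TwoLayerMedium(
        top=OpticalLayer(0.11, 11.19, 1.4, 0.96), bottom=OpticalLayer(0.09333, 9.551, 1.4)
    )
    intensities = two_layer_cw_reflectance(medium, [1.0, 2.0, 3.0, 4.0])
    assert np.all(np.diff(intensities) < 0)
    with pytest.raises(ValueError):
        two_layer_cw_reflectance(medium, [0.0, 1.0])


def test_invalid_top_thickness_rejected(geometry, grid):
    with pytest.raises(ValueError, match="thickness"):
        TwoLayerEvaluator(geometry=geometry, grid=grid, thickness=0.0)
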