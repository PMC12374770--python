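"""Hemoglobin unmixing: round trips, scaling invariances, the affine
TOI-absorption relation of the study conditions, and TOI series assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layertof.chromophores import (
    ExtinctionTable,
    HemodynamicState,
    load_default_extinction_table,
    mua_from_state,
    toi_timeseries,
    unmix_two_wavelengths,
)

TABLE = load_default_extinction_table()


def test_table_validation():
    with pytest.raises(ValueError, match="increasing"):
        ExtinctionTable(np.array([800.0, 700.0]), np.array([1.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="positive"):
        ExtinctionTable(np.array([700.0, 800.0]), np.array([1.0, -1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="outside table range"):
        TABLE.eps(1500.0)


def test_isosbestic_point_near_800nm():
    wl = TABLE.isosbestic_wavelength()
    assert 780.0 <= wl <= 820.0
    eo, eh = TABLE.eps(740.0)
    assert eh > eo  # deoxy dominates below the crossing
    eo, eh = TABLE.eps(850.0)
    assert eo > eh  # oxy dominates above


def test_mua_zero_state():
    assert mua_from_state(HemodynamicState(0.0, 0.0), TABLE, 740.0) == 0.0


def test_mua_linearity_in_concentrations():
    s1 = HemodynamicState(4e-5, 2e-5)
    s3 = HemodynamicState(12e-5, 6e-5)
    assert mua_from_state(s3, TABLE, 850.0) == pytest.approx(
        3.0 * mua_from_state(s1, TABLE, 850.0), rel=1e-12
    )
    with_bg = HemodynamicState(4e-5, 2e-5, background={850.0: 0.02})
    assert mua_from_state(with_bg, TABLE, 850.0) == pytest.approx(
        mua_from_state(s1, TABLE, 850.0) + 0.02, rel=1e-12
    )


@settings(derandomize=True, max_examples=60)
@given(
    toi=st.floats(min_value=0.0, max_value=100.0),
    total=st.floats(min_value=1e-6, max_value=1e-3),
)
def test_unmix_round_trip_is_identity(toi, total):
    """mua_from_state followed by unmixing recovers any positive state."""
    state = HemodynamicState.from_toi(toi, total)
    res = unmix_two_wavelengths(
        mua_from_state(state, TABLE, 740.0), mua_from_state(state, TABLE, 850.0), TABLE
    )
    assert res.c_hbo2 == pytest.approx(state.c_hbo2, rel=1e-9, abs=1e-15)
    assert res.c_hb == pytest.approx(state.c_hb, rel=1e-9, abs=1e-15)
    if state.total > 0:
        assert res.toi == pytest.approx(state.toi, abs=1e-6)


def test_toi_invariant_under_total_hemoglobin_scaling():
    a = HemodynamicState(4e-5, 6e-5)
    b = HemodynamicState(8e-5, 12e-5)
    assert a.toi == pytest.approx(b.toi, abs=1e-12)


def test_pure_hbo2_unmixes_to_full_saturation():
    state = HemodynamicState(5e-5, 0.0)
    res = unmix_two_wavelengths(
        mua_from_state(state, TABLE, 740.0), mua_from_state(state, TABLE, 850.0), TABLE
    )
    assert res.c_hb == pytest.approx(0.0, abs=1e-15)
    assert res.toi == pytest.approx(100.0, abs=1e-9)


def test_negative_concentration_flagged_not_clipped():
    # an absorption pair no nonnegative state can produce
    res = unmix_two_wavelengths(0.0005, 0.2, TABLE)
    assert not res.valid
    assert res.c_hb < 0 or res.c_hbo2 < 0  # retained in the record
    assert np.isnan(res.toi)


def test_study_conditions_affine_in_toi():
    """The five tabulated fetal (TOI, mua) pairs lie on a straight line to
    within 2e-5 cm^-1 -- consistent with fixed total hemoglobin."""
    tois = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
    muas = np.array([0.08488, 0.08910, 0.09333, 0.09755, 0.1018])
    coeffs = np.polyfit(tois, muas, 1)
    residuals = muas - np.polyval(coeffs, tois)
    assert np.abs(residuals).max() < 2e-5


class _Fit:
    def __init__(self, mua2, converged=True):
        self.estimates = {"mua2": mua2}
        self.converged = converged


def test_toi_timeseries_constant_state():
    state = HemodynamicState.from_toi(40.0, 5e-5)
    m740 = mua_from_state(state, TABLE, 740.0)
    m850 = mua_from_state(state, TABLE, 850.0)
    frames = []
    for ts in (0.0, 1.0, 2.0):
        frames += [(ts, 740.0, _Fit(m740)), (ts, 850.0, _Fit(m850))]
    series = toi_timeseries(frames, TABLE)
    assert len(series) == 3
    np.testing.assert_allclose(series["toi_pct"], 40.0, atol=1e-9)


def test_toi_timeseries_failed_fit_gives_missing_value():
    state = HemodynamicState.from_toi(40.0, 5e-5)
    m740 = mua_from_state(state, TABLE, 740.0)
    m850 = mua_from_state(state, TABLE, 850.0)
    frames = [
        (0.0, 740.0, _Fit(m740)),
        (0.0, 850.0, _Fit(m850)),
        (1.0, 740.0, _Fit(m740, converged=False)),
        (1.0, 850.0, _Fit(m850)),
    ]
    series = toi_timeseries(frames, TABLE)
    assert np.isnan(series["toi_pct"].iloc[1])
    assert series["toi_pct"].iloc[0] == pytest.approx(40.0, abs=1e-9)


def test_toi_timeseries_unpaired_frames_rejected():
    frames = [(0.0, 740.0, _Fit(0.1)), (1.0, 850.0, _Fit(0.1))]
    with pytest.raises(ValueError, match="paired"):
        toi_timeseries(frames, TABLE)
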