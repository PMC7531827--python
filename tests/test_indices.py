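"""Unit and property tests for the WBCS climatic parameters and indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbcs import compute_indices, default_ruleset, indices_cell, summer_aridity

from conftest import random_cells

RS = default_ruleset()


def cell(ti, prec=None, diurnal=5.0, lat=48.0, elev=200.0):
    ti = np.asarray(ti, dtype=float)
    prec = np.zeros(12) if prec is None else np.asarray(prec, dtype=float)
    return indices_cell(ti - diurnal, ti + diurnal, prec, lat, RS, elev)


class TestMonthlyMeansAndThermal:
    def test_monthly_means_are_min_max_average(self):
        tmin = np.full(12, 10.0)
        idx = indices_cell(tmin, tmin, np.zeros(12), 48.0, RS)
        assert np.allclose(idx.Ti, 10.0)
        idx2 = indices_cell(
            np.r_[-20.0, np.full(11, 0.0)], np.r_[-10.0, np.full(11, 10.0)],
            np.zeros(12), 48.0, RS,
        )
        assert idx2.Ti[0] == -15.0
        # mean of Ti equals the mean over all 24 min/max values
        tmin, tmax = np.arange(12.0), np.arange(12.0) + 7.0
        idx3 = indices_cell(tmin, tmax, np.zeros(12), 48.0, RS)
        assert np.isclose(idx3.T, np.mean(np.r_[tmin, tmax]))

    def test_constant_profile(self):
        idx = cell(np.full(12, 10.0))
        assert idx.Tp == 1200.0 and idx.Ic == 0.0

    def test_all_negative_profile_has_zero_positive_temperature(self):
        idx = cell(np.full(12, -5.0))
        assert idx.Tp == 0.0 and idx.Tps == 0.0
        assert np.isnan(idx.Io)

    def test_sinusoid_amplitude_sets_continentality(self):
        months = np.arange(12)
        ti = 5.0 + 20.0 * np.cos(2 * np.pi * (months - 6) / 12)
        idx = cell(ti)
        assert np.isclose(idx.Ic, 40.0)
        assert np.isclose(idx.Tmax, 25.0) and np.isclose(idx.Tmin, -15.0)

    def test_coldest_month_tie_takes_earliest(self):
        ti = np.full(12, 10.0)
        ti[2] = ti[9] = -3.0  # two equally cold months -> March wins
        tmin, tmax = ti - 4.0, ti + 6.0
        idx = indices_cell(tmin, tmax, np.zeros(12), 48.0, RS)
        brute = min(range(12), key=lambda i: (ti[i], i))
        assert brute == 2
        assert idx.m == tmin[2] and idx.M == tmax[2]


class TestPrecipitationParameters:
    def test_uniform_field(self):
        idx = cell(np.full(12, 10.0), np.full(12, 30.0))
        assert idx.P == 360.0
        assert idx.Ps == 90.0 and idx.Pw == 90.0
        assert idx.Pcm1 == 120.0 and idx.Pss == 180.0

    def test_no_positive_months_means_no_positive_precipitation(self):
        idx = cell(np.full(12, -1.0), np.full(12, 50.0))
        assert idx.Pp == 0.0 and idx.P == 600.0

    def test_northern_summer_quarter_membership(self):
        prec = np.zeros(12)
        prec[6] = 50.0  # July only
        idx = cell(np.full(12, 10.0), prec, lat=48.0)
        assert idx.Ps == 50.0 and idx.Pw == 0.0
        # same rain in a southern-hemisphere cell falls in its winter
        idx_s = cell(np.full(12, 10.0), prec, lat=-33.0)
        assert idx_s.Ps == 0.0 and idx_s.Pw == 50.0


class TestOmbrothermic:
    def test_uniform_ombrothermic_index(self):
        idx = cell(np.full(12, 10.0), np.full(12, 20.0))
        assert np.isclose(idx.Io, 2.0)  # 10 * 240 / 1200

    def test_zero_precipitation(self):
        idx = cell(np.full(12, 10.0), np.zeros(12))
        assert idx.Io == 0.0 and idx.Ios2 == 0.0

    def test_warmest_two_summer_months(self):
        ti = np.full(12, 5.0)
        prec = np.full(12, 30.0)
        ti[5], ti[6], ti[7] = 20.0, 25.0, 24.0
        prec[5], prec[6], prec[7] = 10.0, 5.0, 8.0
        idx = cell(ti, prec)
        # warmest contiguous pair is (Jul, Aug): 10*(5+8)/(10*(25+24))
        assert np.isclose(idx.Ios2, 10.0 * 13.0 / 490.0)


class TestCompensatedThermicity:
    def test_neutral_band_is_uncompensated(self):
        months = np.arange(12)
        ti = 10.0 + 6.0 * np.cos(2 * np.pi * (months - 6) / 12)  # Ic = 12
        idx = cell(ti)
        assert idx.C == 0.0 and idx.Itc == idx.It

    def test_step_table_value(self, rs):
        assert rs.compensation_C(30.0) == 120.0
        assert rs.compensation_C(19.5) == 7.5
        assert rs.compensation_C(4.0) == -40.0

    def test_monotone_above_neutral(self, rs):
        ics = np.linspace(18.0, 66.0, 500)
        c = rs.compensation_C(ics)
        assert np.all(np.diff(c) >= -1e-12)

    def test_negative_ic_rejected(self, rs):
        with pytest.raises(ValueError):
            rs.compensation_C(-1.0)


class TestReduction:
    def test_reference_elevation_is_identity(self):
        ti = 5.0 + 15.0 * np.cos(2 * np.pi * (np.arange(12) - 6) / 12)
        idx = cell(ti, elev=200.0)
        assert idx.T200 == idx.T and idx.Tp200 == idx.Tp
        assert idx.Itc200 == idx.Itc and idx.M200 == idx.M

    def test_warming_shift_at_1200m(self):
        ti = np.full(12, 3.0)
        idx = cell(ti, elev=1200.0)
        # 0.6 deg per 100 m over 1000 m -> +6.0 on every month
        assert np.isclose(idx.T200, 9.0)
        assert np.isclose(idx.Tp200, 10 * 12 * 9.0)

    def test_reduction_strictly_increases_tp_through_zero_crossing(self):
        ti = np.full(12, 5.0)
        ti[0] = -2.0  # month inside (-delta, 0]
        idx = cell(ti, elev=1000.0)  # delta = +4.8
        assert idx.Tp200 > idx.Tp + 10 * 4.8 * 11  # the thawed month contributes


class TestSummerAridity:
    @pytest.mark.parametrize(
        "ios2, iosc3, iosc4, io, expected",
        [
            (3.5, 0.0, 0.0, 1.0, False),   # wet two-month core
            (1.0, 1.2, 1.5, 5.0, True),    # no compensation branch fires
            (1.8, 2.5, 0.0, 1.0, False),   # quarter-level compensation
            (1.8, 1.9, 2.5, 5.0, False),   # four-month compensation, wet year
            (1.8, 1.9, 2.5, 1.0, True),    # same but annually dry: not compensated
        ],
    )
    def test_cascade(self, ios2, iosc3, iosc4, io, expected):
        assert summer_aridity(ios2, iosc3, iosc4, io, RS) is expected


class TestInvariantsAndDualRoute:
    @given(delta=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_uniform_warming_preserves_ic_and_grows_tp(self, delta, seed):
        tmin, tmax, prec, lat, elev = random_cells(1, seed)
        a = indices_cell(tmin[0], tmax[0], prec[0], lat[0], RS, elev[0])
        b = indices_cell(tmin[0] + delta, tmax[0] + delta, prec[0], lat[0], RS, elev[0])
        assert np.isclose(a.Ic, b.Ic)
        assert b.Tp >= a.Tp

    @given(k=st.floats(0.0, 5.0), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_precipitation_scaling(self, k, seed):
        tmin, tmax, prec, lat, elev = random_cells(1, seed)
        a = indices_cell(tmin[0], tmax[0], prec[0], lat[0], RS, elev[0])
        b = indices_cell(tmin[0], tmax[0], k * prec[0], lat[0], RS, elev[0])
        for attr in ("P", "Pp", "Ps", "Pw"):
            assert np.isclose(getattr(b, attr), k * getattr(a, attr))
        for attr in ("Io", "Ios2"):
            va, vb = getattr(a, attr), getattr(b, attr)
            if not np.isnan(va):
                assert np.isclose(vb, k * va)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_ordering_invariants(self, seed):
        tmin, tmax, prec, lat, elev = random_cells(1, seed)
        idx = indices_cell(tmin[0], tmax[0], prec[0], lat[0], RS, elev[0])
        assert idx.Tps <= idx.Tp + 1e-9
        assert idx.Pps <= idx.Pp + 1e-9
        assert idx.Pp <= idx.P + 1e-9
        assert idx.Ps + idx.Pw <= idx.P + 1e-9
        assert idx.Ic >= 0 and idx.M >= idx.m

    def test_purity_bit_identical(self):
        tmin, tmax, prec, lat, elev = random_cells(1, 5)
        a = indices_cell(tmin[0], tmax[0], prec[0], lat[0], RS, elev[0])
        b = indices_cell(tmin[0], tmax[0], prec[0], lat[0], RS, elev[0])
        for attr in ("T", "Tp", "Io", "Ios2", "Iod2", "Pcm1", "Itc200"):
            va, vb = getattr(a, attr), getattr(b, attr)
            assert (np.isnan(va) and np.isnan(vb)) or va == vb

    def test_vectorised_equals_scalar_route(self):
        tmin, tmax, prec, lat, elev = random_cells(250, 11)
        table = compute_indices(tmin, tmax, prec, lat, elev, RS)
        for i in range(250):
            ref = indices_cell(tmin[i], tmax[i], prec[i], lat[i], RS, elev[i])
            for col in table.columns:
                if col.startswith(("Psm", "Tsm", "Iosi")):
                    continue
                got = table.at[i, col]
                want = getattr(ref, col) if col != "summer_arid" else ref.summer_arid
                if isinstance(want, (bool, np.bool_)):
                    assert got == want, (i, col)
                elif np.isnan(want):
                    assert np.isnan(got), (i, col)
                else:
                    assert np.isclose(got, want, rtol=0, atol=1e-10), (i, col)
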