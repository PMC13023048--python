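"""Environmental-covariate formulas: THI, RH, windows, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cattlernm import enviro
from cattlernm.enviro import (DataError, DegenerateGradientError, ECDefinition,
                              compute_rh, compute_thi, cumulative_precip_window,
                              mean_thi_window, scale_ec)


class TestRH:
    def test_saturation_gives_100(self):
        assert compute_rh(20.0, 20.0) == pytest.approx(100.0, abs=1e-12)

    def test_hand_value(self):
        # Magnus ratio at T=20, DT=10: e(17.625*10/253.04)/e(17.625*20/263.04)
        expected = 100 * np.exp(17.625 * 10 / 253.04) / np.exp(17.625 * 20 / 263.04)
        assert compute_rh(20.0, 10.0) == pytest.approx(expected, rel=1e-12)
        assert compute_rh(20.0, 10.0) == pytest.approx(52.5, abs=0.1)

    @given(st.floats(-30, 45), st.floats(-30, 45))
    @settings(max_examples=60, deadline=None)
    def test_rh_below_100_iff_dewpoint_below_temp(self, t, dt):
        rh = compute_rh(t, dt)
        assert (rh <= 100.0 + 1e-9) == (dt <= t + 1e-12)

    def test_monotone_in_dewpoint(self):
        grid = np.linspace(-10, 19.9, 50)
        rh = compute_rh(np.full(50, 20.0), grid)
        assert np.all(np.diff(rh) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            compute_rh(np.nan, 10.0)


class TestTHI:
    def test_rh100_identity(self):
        # at RH=100 the adjustment term vanishes: THI = 1.8 T + 32
        t = np.linspace(-5, 45, 50)
        assert np.allclose(compute_thi(t, np.full(50, 100.0)), 1.8 * t + 32, atol=1e-12)

    def test_pivot_temperature(self):
        # 1.8 T - 26 = 0 at T = 130/9: THI = 58 at any humidity
        for rh in (5.0, 50.0, 100.0):
            assert compute_thi(130.0 / 9.0, rh) == pytest.approx(58.0, abs=1e-12)

    def test_hand_value(self):
        assert compute_thi(30.0, 50.0) == pytest.approx(86.0 - 0.275 * 28.0, abs=1e-12)
        assert compute_thi(30.0, 100.0) == pytest.approx(86.0, abs=1e-12)

    def test_thi_of_saturated_air_equals_identity_composition(self):
        t = np.linspace(0, 40, 21)
        assert np.allclose(compute_thi(t, compute_rh(t, t)), 1.8 * t + 32, atol=1e-12)


class TestWindows:
    @staticmethod
    def _daily(values, start="2010-01-01"):
        dates = pd.date_range(start, periods=len(values), freq="D")
        return pd.DataFrame({"date": dates, "precip_mm": values})

    def test_constant_series(self):
        daily = self._daily([2.0] * 120)
        assert cumulative_precip_window(daily, "2010-04-01", 90) == pytest.approx(180.0)

    def test_all_zero(self):
        daily = self._daily([0.0] * 120)
        assert cumulative_precip_window(daily, "2010-04-01", 90) == 0.0

    def test_hand_sum_excludes_birth_day(self):
        vals = [1, 0, 3, 0, 0, 2, 0, 0, 0, 5]
        daily = self._daily(vals + [99.0])  # day 11 = birth day, excluded
        assert cumulative_precip_window(daily, "2010-01-11", 10) == pytest.approx(11.0)

    def test_window_additivity(self):
        rng = np.random.default_rng(3)
        daily = self._daily(rng.gamma(0.5, 4.0, 400))
        birth = "2011-01-20"
        s365 = cumulative_precip_window(daily, birth, 365)
        s280 = cumulative_precip_window(daily, birth, 280)
        first85 = cumulative_precip_window(
            daily, pd.Timestamp(birth) - pd.Timedelta(days=280), 85)
        assert s365 == pytest.approx(s280 + first85, rel=1e-12)

    def test_incomplete_coverage_is_an_error(self):
        daily = self._daily([1.0] * 50)
        with pytest.raises(DataError):
            cumulative_precip_window(daily, "2010-04-01", 90)

    def test_mean_thi_constant_and_toy(self):
        hours = pd.date_range("2010-01-01", periods=91 * 24, freq="h")
        hourly = pd.DataFrame({"timestamp": hours, "temp_c": 30.0, "dewpoint_c": 30.0})
        assert mean_thi_window(hourly, "2010-04-01", 90) == pytest.approx(86.0)

    def test_mean_thi_matches_quadrature(self):
        hours = pd.date_range("2010-01-01", periods=91 * 24, freq="h")
        t = 25 + 8 * np.sin(np.arange(len(hours)) * 2 * np.pi / 24)
        hourly = pd.DataFrame({"timestamp": hours, "temp_c": t, "dewpoint_c": t - 8})
        birth = pd.Timestamp("2010-04-01")
        got = mean_thi_window(hourly, birth, 90)
        mask = (hours >= birth - pd.Timedelta(days=90)) & (hours < birth)
        expected = np.mean(enviro.compute_thi(
            t[mask], enviro.compute_rh(t[mask], t[mask] - 8)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_low_coverage_is_an_error(self):
        hours = pd.date_range("2010-01-01", periods=30 * 24, freq="h")
        hourly = pd.DataFrame({"timestamp": hours, "temp_c": 30.0, "dewpoint_c": 20.0})
        with pytest.raises(DataError):
            mean_thi_window(hourly, "2010-04-01", 90)


class TestScaling:
    def test_endpoints_and_midpoint(self):
        scaled, sc = scale_ec([100.0, 300.0, 200.0])
        assert np.allclose(scaled, [-1.0, 1.0, 0.0])

    def test_hand_values(self):
        scaled, _ = scale_ec([0.0, 50.0, 200.0])
        assert np.allclose(scaled, [-1.0, -0.5, 1.0])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=30).filter(
        lambda v: max(v) - min(v) > 1e-6))
    @settings(max_examples=60, deadline=None)
    def test_round_trip(self, values):
        scaled, sc = scale_ec(values)
        back = sc.unscale(scaled)
        assert np.allclose(back, values, rtol=1e-12, atol=1e-9)
        assert scaled.min() == pytest.approx(-1.0) and scaled.max() == pytest.approx(1.0)

    def test_degenerate_gradient(self):
        with pytest.raises(DegenerateGradientError):
            scale_ec([5.0, 5.0, 5.0])

    def test_definition_validation(self):
        assert ECDefinition.from_name("sumPrec280").window_days == 280
        assert ECDefinition.from_name("meanTHI90").kind == "thi_mean"
        with pytest.raises(ValueError):
            ECDefinition("sumPrec365", "precip_sum", 90)
        with pytest.raises(ValueError):
            ECDefinition("meanTHI90", "thi_mean", 365)
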