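"""Conductance fitting: OLS oracle equivalence, invariances, ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import protonleak as pl
from protonleak.exceptions import InsufficientDataError, InvalidInputError


def ols_slope_intercept(u, i):
    """Independent normal-equations oracle for the straight-line fit."""
    u = np.asarray(u, float)
    i = np.asarray(i, float)
    du = u - u.mean()
    slope = float(np.dot(du, i - i.mean()) / np.dot(du, du))
    return slope, float(i.mean() - slope * u.mean())


class TestOhmicFit:
    def test_all_zero_currents(self):
        trace = pl.IVTrace(np.arange(-50.0, 51.0, 10.0), np.zeros(11), area=1.0)
        res = pl.fit_ohmic_conductance(trace)
        assert res.G_specific == 0.0
        assert not res.intercept_defined and res.intercept_U0 is None

    def test_zero_noise_round_trip(self, quiet_cfg):
        trace = pl.gen_iv_trace(10.0, 1.0, 0.0, 0.0, quiet_cfg)
        res = pl.fit_ohmic_conductance(trace)
        assert res.G_specific == pytest.approx(10.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_noisy_trace_equals_normal_equations_oracle(self):
        cfg = pl.GeneratorConfig(seed=5, noise_sd_current=2.0)
        trace = pl.gen_iv_trace(500.0, 2e-4, 0.0, 10.0, cfg)
        res = pl.fit_ohmic_conductance(trace)
        slope, offset = ols_slope_intercept(trace.voltage, trace.current)
        assert res.G_specific == pytest.approx(slope / trace.area, rel=1e-12)
        assert res.intercept_U0 == pytest.approx(-offset / slope, rel=1e-9)

    @given(
        seed=st.integers(0, 10_000),
        g=st.floats(1.0, 5e3),
        sd=st.floats(0.0, 5.0),
    )
    def test_oracle_equivalence_property(self, seed, g, sd):
        cfg = pl.GeneratorConfig(seed=seed, noise_sd_current=sd)
        trace = pl.gen_iv_trace(g, 1e-4, 0.0, 0.0, cfg)
        res = pl.fit_ohmic_conductance(trace)
        slope, _ = ols_slope_intercept(trace.voltage, trace.current)
        assert res.G_specific == pytest.approx(slope / 1e-4, rel=1e-10)

    def test_reorder_invariance_and_area_scaling(self):
        cfg = pl.GeneratorConfig(seed=9, noise_sd_current=1.0)
        trace = pl.gen_iv_trace(800.0, 1e-4, 0.0, 0.0, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(trace.voltage.size)
        shuffled = pl.IVTrace(trace.voltage[perm], trace.current[perm], trace.area)
        assert pl.fit_ohmic_conductance(shuffled).G_specific == pytest.approx(
            pl.fit_ohmic_conductance(trace).G_specific, rel=1e-12
        )
        doubled = pl.IVTrace(trace.voltage, trace.current, 2 * trace.area)
        assert pl.fit_ohmic_conductance(doubled).G_specific == pytest.approx(
            pl.fit_ohmic_conductance(trace).G_specific / 2, rel=1e-12
        )

    def test_current_offset_moves_intercept_not_slope(self):
        cfg = pl.GeneratorConfig(seed=3, noise_sd_current=1.0)
        trace = pl.gen_iv_trace(800.0, 1e-4, 0.0, 0.0, cfg)
        base = pl.fit_ohmic_conductance(trace)
        shifted = pl.IVTrace(trace.voltage, trace.current + 5.0, trace.area)
        res = pl.fit_ohmic_conductance(shifted)
        assert res.G_specific == pytest.approx(base.G_specific, rel=1e-12)
        assert res.intercept_U0 != pytest.approx(base.intercept_U0, abs=1e-3)

    def test_window_restricts_points(self):
        trace = pl.IVTrace(np.arange(-100.0, 101.0, 20.0), np.arange(11.0), area=1.0)
        res = pl.fit_ohmic_conductance(trace, window=(-50, 50))
        assert res.n_points == 5
        with pytest.raises(InsufficientDataError):
            pl.fit_ohmic_conductance(trace, window=(-10, 10))


class TestVoltageDependence:
    def test_constant_conductance(self):
        pts = [(0.0, 20.4), (50.0, 20.4), (100.0, 20.4), (190.0, 20.4)]
        fit = pl.fit_voltage_dependence(pts)
        assert fit.slope_b == pytest.approx(0.0, abs=1e-12)
        assert fit.G0_amplitude == pytest.approx(20.4, rel=1e-9)

    def test_round_trip_recovery(self):
        # amplitude 20.4 nS/cm^2 growing one order of magnitude by 190 mV
        b_true = np.log(10.0) / 190.0
        psi = np.arange(0.0, 191.0, 10.0)
        pts = np.column_stack([psi, 20.4 * np.exp(b_true * psi)])
        fit = pl.fit_voltage_dependence(pts)
        assert fit.G0_amplitude == pytest.approx(20.4, rel=1e-6)
        assert fit.slope_b == pytest.approx(b_true, rel=1e-6)

    def test_log_residuals_unbiased_over_two_decades(self):
        rng = np.random.default_rng(7)
        b_true = np.log(100.0) / 190.0  # two decades across the range
        psi = np.arange(10.0, 191.0, 10.0)
        g = 5.0 * np.exp(b_true * psi) * np.exp(rng.normal(0, 0.05, psi.size))
        fit = pl.fit_voltage_dependence(np.column_stack([psi, g]))
        log_resid = np.log(g) - np.log(fit.predict(psi))
        assert abs(log_resid.mean()) < 0.02

    def test_symmetry_in_potential_sign(self):
        pts = np.array([(-100.0, 50.0), (-50.0, 30.0), (50.0, 30.0), (100.0, 50.0)])
        fit = pl.fit_voltage_dependence(pts)
        assert fit.predict(-80.0) == pytest.approx(fit.predict(80.0))

    def test_rejects_non_positive_conductance(self):
        with pytest.raises(InvalidInputError):
            pl.fit_voltage_dependence([(0.0, 1.0), (50.0, -2.0), (100.0, 3.0)])


class TestRatios:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(1750.0, 440.0, 3.98), (39.5, 8.4, 4.70), (7.0, 7.0, 1.0)],
    )
    def test_activation_ratio(self, num, den, expected):
        assert pl.activation_ratio(num, den) == pytest.approx(expected, abs=0.005)

    def test_activation_ratio_rejects_non_positive(self):
        with pytest.raises(InvalidInputError):
            pl.activation_ratio(100.0, 0.0)

    @pytest.mark.parametrize(
        "g, expected", [(100.0, 1.0), (10.0, 0.0), (55.0, 0.5)]
    )
    def test_relative_conductance_endpoints_and_linearity(self, g, expected):
        rel = pl.relative_conductance(g, G_no_inhibitor=100.0, G_baseline=10.0)
        assert rel.value == pytest.approx(expected)
        assert not rel.clipped

    def test_relative_conductance_clips_below_baseline(self):
        rel = pl.relative_conductance(5.0, 100.0, 10.0)
        assert rel.value == 0.0 and rel.clipped

    def test_relative_conductance_bad_denominator(self):
        with pytest.raises(InvalidInputError):
            pl.relative_conductance(50.0, 10.0, 10.0)
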