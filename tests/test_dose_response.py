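"""Inhibition fitting: round-trips, model constraints, bootstrap, ranking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import protonleak as pl
from protonleak.exceptions import (DegenerateFitError, InsufficientDataError,
                                   InvalidInputError)


class TestFitInhibition:
    @pytest.mark.parametrize(
        "ec50, imax", [(18.9, 64.2), (32.3, 44.3), (5.0, 100.0)]
    )
    def test_zero_noise_round_trip(self, ec50, imax, quiet_cfg):
        series = pl.gen_dose_response(ec50, imax, cfg=quiet_cfg)
        fit = pl.fit_inhibition(series)
        assert fit.ec50 == pytest.approx(ec50, rel=1e-6)
        assert fit.imax == pytest.approx(imax, rel=1e-6)
        assert fit.converged

    def test_full_inhibition_drives_response_to_zero(self, quiet_cfg):
        series = pl.gen_dose_response(10.0, 100.0, cfg=quiet_cfg)
        fit = pl.fit_inhibition(series)
        assert fit.imax == pytest.approx(100.0, rel=1e-6)
        assert fit.predict(np.array([1e7]))[0] == pytest.approx(0.0, abs=1e-4)

    def test_unit_covariance_of_concentration_scale(self, quiet_cfg):
        c = np.geomspace(1.0, 1000.0, 8)
        uM = pl.gen_dose_response(18.9, 64.2, 1.0, c, quiet_cfg)
        nM = pl.DoseSeries(uM.concentration * 1000.0, uM.rel_conductance)
        fit_uM, fit_nM = pl.fit_inhibition(uM), pl.fit_inhibition(nM)
        assert fit_nM.ec50 == pytest.approx(fit_uM.ec50 * 1000.0, rel=1e-6)
        assert fit_nM.imax == pytest.approx(fit_uM.imax, rel=1e-6)

    def test_free_hill_recovers_steep_curve(self, quiet_cfg):
        series = pl.gen_dose_response(18.9, 64.2, hill=2.0, cfg=quiet_cfg)
        fit = pl.fit_inhibition(series, fix_hill=None)
        assert fit.hill == pytest.approx(2.0, rel=1e-5)
        assert fit.ec50 == pytest.approx(18.9, rel=1e-5)

    def test_degenerate_and_insufficient_inputs(self):
        flat = pl.DoseSeries(np.array([1.0, 10.0, 100.0, 1000.0]), np.full(4, 0.7))
        with pytest.raises(DegenerateFitError):
            pl.fit_inhibition(flat)
        few = pl.DoseSeries(np.array([1.0, 1.0, 10.0, 10.0]), np.array([1.0, 0.9, 0.6, 0.5]))
        with pytest.raises(InsufficientDataError):
            pl.fit_inhibition(few)
        with pytest.raises(InvalidInputError):
            pl.DoseSeries(np.array([-1.0, 1.0]), np.array([1.0, 0.5]))

    def test_recovery_bias_under_noise(self):
        """EC50 and I_max estimator bias stays under 5% at cv = 0.1 with the
        default 8-point log-spaced design (500 simulated titrations)."""
        ec50s, imaxs = [], []
        for k in range(500):
            cfg = pl.GeneratorConfig(seed=50_000 + k, noise_cv_conductance=0.1)
            fit = pl.fit_inhibition(pl.gen_dose_response(18.9, 64.2, cfg=cfg))
            ec50s.append(fit.ec50)
            imaxs.append(fit.imax)
        assert abs(np.mean(ec50s) / 18.9 - 1.0) < 0.05
        assert abs(np.mean(imaxs) / 64.2 - 1.0) < 0.05


class TestModelConstraints:
    @given(
        ec50=st.floats(0.1, 1e3),
        imax=st.floats(1.0, 100.0),
        hill=st.floats(0.3, 5.0),
    )
    def test_anchored_at_one_and_monotone(self, ec50, imax, hill):
        c = np.concatenate([[0.0], np.geomspace(1e-3, 1e6, 40)])
        rel = pl.inhibition_model(c, ec50, imax, hill)
        assert rel[0] == 1.0  # exact anchor, not a fitted intercept
        assert np.all(np.diff(rel) <= 1e-12)  # non-increasing for h > 0
        assert rel[-1] >= 1.0 - imax / 100.0 - 1e-9


class TestBootstrap:
    def test_seed_determinism(self):
        cfg = pl.GeneratorConfig(seed=21, noise_cv_conductance=0.1)
        series = pl.gen_dose_response(18.9, 64.2, cfg=cfg)
        a = pl.bootstrap_ci(series, n_boot=200, seed=5)
        b = pl.bootstrap_ci(series, n_boot=200, seed=5)
        assert a == b

    def test_zero_noise_interval_collapses(self, quiet_cfg):
        series = pl.gen_dose_response(18.9, 64.2, cfg=quiet_cfg)
        (e_lo, e_hi), (i_lo, i_hi) = pl.bootstrap_ci(series, n_boot=200, seed=1)
        assert e_hi - e_lo < 1e-6 * 18.9
        assert i_hi - i_lo < 1e-6 * 64.2

    def test_replicate_blocks_are_the_resampling_unit(self):
        rng = np.random.default_rng(4)
        c = np.tile(np.geomspace(2.0, 200.0, 8), 5)
        rep = np.repeat(np.arange(5), 8)
        rel = pl.inhibition_model(c, 18.9, 64.2) * (1 + rng.normal(0, 0.1, c.size))
        series = pl.DoseSeries(c, rel, replicate_id=rep)
        ci = pl.bootstrap_ci(series, n_boot=200, seed=2)
        assert ci[0][0] < 18.9 < ci[0][1]

    def test_requires_enough_resamples_and_units(self, quiet_cfg):
        series = pl.gen_dose_response(18.9, 64.2, cfg=quiet_cfg)
        with pytest.raises(InvalidInputError):
            pl.bootstrap_ci(series, n_boot=50, seed=0)


class TestCompareCompounds:
    def _fits(self):
        return [
            pl.DoseResponseFit(32.3, 44.3, 1.0, compound="BA"),
            pl.DoseResponseFit(18.9, 64.2, 1.0, compound="CATR"),
        ]

    def test_ranked_by_potency(self):
        table = pl.compare_compounds(self._fits())
        assert list(table["compound"]) == ["CATR", "BA"]

    def test_order_independent_of_input_order(self):
        a = pl.compare_compounds(self._fits())
        b = pl.compare_compounds(self._fits()[::-1])
        assert list(a["compound"]) == list(b["compound"])

    def test_duplicates_keep_stable_order(self):
        fit = pl.DoseResponseFit(18.9, 64.2, 1.0, compound="CATR")
        table = pl.compare_compounds([fit, fit])
        assert list(table["compound"]) == ["CATR", "CATR"]

    def test_unreliable_fit_is_flagged_not_dropped(self):
        # a compound whose I_max interval includes 0 carries reliable=False
        weak = pl.DoseResponseFit(50.0, 5.0, 1.0, compound="GMP",
                                  ci_ec50=(1.0, 900.0), ci_imax=(0.0, 12.0))
        table = pl.compare_compounds(self._fits() + [weak])
        assert bool(table.loc[table["compound"] == "GMP", "reliable"].iloc[0]) is False
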