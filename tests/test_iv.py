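"""2SLS engine: closed-form oracles, diagnostics, design construction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ed_avoidance import iv, synthetic
from ed_avoidance.calendars import WaveCalendar, default_calendar
from ed_avoidance.etl import DailyStratumSeries, Stratum
from ed_avoidance.iv import IVDesign, SingularDesignError, TwoSLSFit

from conftest import random_design


def closed_form_2sls(design):
    """Independent oracle: theta = (X' P_W X)^-1 X' P_W y via projection."""
    n = design.n
    w = np.column_stack([np.ones(n), design.Z, design.S])
    x = np.column_stack([np.ones(n), design.A, design.S])
    pw = w @ np.linalg.solve(w.T @ w, w.T)
    return np.linalg.solve(x.T @ pw @ x, x.T @ pw @ design.D)


def make_fit(theta1, se=0.0, stratum=Stratum(">=65", "F")):
    return TwoSLSFit(
        stratum=stratum,
        lag=0,
        n_days=100,
        theta0=0.0,
        theta1=theta1,
        se_theta0=0.0,
        se_theta1=se,
        ci_theta1=(theta1 - 1.96 * se, theta1 + 1.96 * se),
        partial_f=100.0,
        partial_f_p=0.0,
        first_stage=None,
    )


class TestBuildDesign:
    def test_lag_zero_identity(self, four_wave_calendar):
        cfg = synthetic.recovery_config(0, calendar=four_wave_calendar)
        series, _ = synthetic.generate_daily_counts(cfg)
        s = next(iter(series.values()))
        d = iv.build_design(s, four_wave_calendar, 0)
        np.testing.assert_array_equal(d.D, s.deaths28)
        np.testing.assert_array_equal(d.A, s.visits)
        assert d.n == len(s)

    def test_day_of_year_is_zero_based(self):
        s = iv.seasonal_covariates(
            pd.DatetimeIndex(["2016-01-01", "2016-01-02", "2017-01-01"]), 2016
        )
        np.testing.assert_array_equal(s[:, 1], [0.0, 1.0, 0.0])  # t
        np.testing.assert_array_equal(s[:, 0], [0.0, 0.0, 1.0])  # year index
        np.testing.assert_array_equal(s[:, 2], s[:, 1] ** 2)
        np.testing.assert_array_equal(s[:, 3], s[:, 1] ** 3)

    def test_lag_trims_trailing_rows(self):
        cal = default_calendar()
        cfg = synthetic.recovery_config(0)
        series, _ = synthetic.generate_daily_counts(cfg)
        s = next(iter(series.values()))
        assert len(s) == 2192
        d = iv.build_design(s, cal, 5)
        assert d.n == 2187
        np.testing.assert_array_equal(d.D, s.deaths28[5:])
        np.testing.assert_array_equal(d.A, s.visits[:-5])

    def test_excessive_lag_rejected(self, tiny_calendar):
        dates = tiny_calendar.dates()
        s = DailyStratumSeries(
            Stratum(">=65", "F"), dates, np.ones(len(dates)), np.ones(len(dates))
        )
        with pytest.raises(ValueError, match="lag"):
            iv.build_design(s, tiny_calendar, len(dates))

    def test_wave_indicators_mutually_exclusive(self, four_wave_calendar):
        frame = four_wave_calendar.instrument_frame()
        assert frame.to_numpy().sum(axis=1).max() <= 1
        # after_wave is 0 before the first wave ends, 1 on later non-wave days
        before = frame.loc[: pd.Timestamp("2020-01-24")]
        assert before["after_wave"].sum() == 0
        after = frame.loc[pd.Timestamp("2020-03-01") : pd.Timestamp("2020-03-16")]
        assert after["after_wave"].all()


class TestFirstStage:
    def test_recovers_wave_effects(self, four_wave_calendar):
        hits = 0
        beta_true = synthetic.recovery_config(0).beta_wave
        for seed in range(40):
            cfg = synthetic.recovery_config(seed, calendar=four_wave_calendar)
            series, _ = synthetic.generate_daily_counts(cfg)
            d = iv.build_design(next(iter(series.values())), four_wave_calendar, 0)
            first = iv.fit_first_stage(d)
            se = np.sqrt(first.sigma2 * np.diag(first.xtx_inv))
            coef = first.coef
            ok = all(
                abs(coef[k] - beta_true[k]) < 1.96 * se[list(coef.index).index(k)]
                for k in ("wave1", "wave2", "wave3", "wave4")
            )
            hits += ok
        # joint 95% CIs over 4 coefficients: expect ~81% joint coverage
        assert hits >= 24

    def test_constant_exposure_gives_zero_slopes(self, four_wave_calendar):
        dates = four_wave_calendar.dates()
        s = DailyStratumSeries(
            Stratum(">=65", "F"), dates, np.full(len(dates), 100), np.zeros(len(dates))
        )
        d = iv.build_design(s, four_wave_calendar, 0)
        first = iv.fit_first_stage(d)
        assert first.beta.abs().max() < 1e-8

    def test_missing_wave_named_in_singularity_error(self, tiny_calendar):
        # only wave1 exists in this calendar: wave2..4 columns are all zero
        dates = tiny_calendar.dates()
        rng = np.random.default_rng(0)
        s = DailyStratumSeries(
            Stratum(">=65", "F"),
            dates,
            rng.integers(50, 70, len(dates)),
            rng.integers(0, 5, len(dates)),
        )
        d = iv.build_design(s, tiny_calendar, 0)
        with pytest.raises(SingularDesignError, match="wave2"):
            iv.fit_first_stage(d)


class TestTwoSLS:
    def test_matches_closed_form_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = random_design(rng)
            fit = iv.fit_2sls(d, weak_f_floor=0.0)
            oracle = closed_form_2sls(d)
            assert fit.theta1 == pytest.approx(oracle[1], rel=1e-8)
            assert fit.theta0 == pytest.approx(oracle[0], rel=1e-8)

    def test_matches_statsmodels_iv2sls(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        rng = np.random.default_rng(7)
        d = random_design(rng, n=80)
        x = np.column_stack([np.ones(d.n), d.A, d.S])
        w = np.column_stack([np.ones(d.n), d.Z, d.S])
        sm_fit = IV2SLS(d.D, x, instrument=w).fit()
        fit = iv.fit_2sls(d, weak_f_floor=0.0)
        assert fit.theta1 == pytest.approx(sm_fit.params[1], rel=1e-8)

    def test_identity_instrument_equals_ols(self):
        """When Z is the exposure itself, 2SLS collapses to OLS exactly."""
        rng = np.random.default_rng(3)
        n = 50
        a = rng.normal(100, 10, n)
        dvec = 5 - 0.3 * a + rng.standard_normal(n)
        d = IVDesign(
            stratum=Stratum(">=65", "F"),
            dates=pd.date_range("2020-01-01", periods=n),
            Z=a[:, None],
            S=np.empty((n, 0)),
            A=a,
            D=dvec,
            lag=0,
            instrument_names=("z",),
            seasonal_names=(),
        )
        fit = iv.fit_2sls(d, weak_f_floor=0.0)
        slope = np.polyfit(a, dvec, 1)[0]
        assert fit.theta1 == pytest.approx(slope, rel=1e-10)

    def test_wald_ratio_on_12_row_fixture(self):
        """Just-identified binary IV equals the hand-computed Wald ratio."""
        z = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1], dtype=float)
        a = np.array([10, 12, 11, 9, 10, 8, 5, 6, 4, 5, 7, 3], dtype=float)
        dvec = np.array([2, 3, 2, 4, 3, 2, 6, 5, 7, 6, 5, 7], dtype=float)
        d = IVDesign(
            stratum=Stratum(">=65", "F"),
            dates=pd.date_range("2020-01-01", periods=12),
            Z=z[:, None],
            S=np.empty((12, 0)),
            A=a,
            D=dvec,
            lag=0,
            instrument_names=("z",),
            seasonal_names=(),
        )
        fit = iv.fit_2sls(d, weak_f_floor=0.0)
        wald = (dvec[z == 1].mean() - dvec[z == 0].mean()) / (
            a[z == 1].mean() - a[z == 0].mean()
        )
        assert wald == pytest.approx(-2.0 / 3.0)
        assert fit.theta1 == pytest.approx(wald, rel=1e-12)

    def test_instrument_shift_invariance(self):
        """Adding a constant to every instrument column leaves theta1 unchanged."""
        rng = np.random.default_rng(5)
        d = random_design(rng, n=70)
        base = iv.fit_2sls(d, weak_f_floor=0.0).theta1
        for c in (1.0, -3.5, 100.0):
            shifted = IVDesign(
                stratum=d.stratum,
                dates=d.dates,
                Z=d.Z + c,
                S=d.S,
                A=d.A,
                D=d.D,
                lag=0,
                instrument_names=d.instrument_names,
                seasonal_names=d.seasonal_names,
            )
            assert iv.fit_2sls(shifted, weak_f_floor=0.0).theta1 == pytest.approx(
                base, rel=1e-8
            )

    def test_hc1_close_to_classical_under_homoskedasticity(self):
        rng = np.random.default_rng(9)
        d = random_design(rng, n=80)
        se_c = iv.fit_2sls(d, se_type="classical", weak_f_floor=0.0).se_theta1
        se_h = iv.fit_2sls(d, se_type="hc1", weak_f_floor=0.0).se_theta1
        assert se_h == pytest.approx(se_c, rel=0.5)

    def test_weak_instrument_warning_attached(self):
        rng = np.random.default_rng(13)
        n = 200
        z = (rng.random((n, 2)) < 0.5).astype(float)
        a = rng.normal(100, 5, n)  # instruments do not move the exposure
        dvec = rng.normal(10, 2, n)
        d = IVDesign(
            stratum=Stratum(">=65", "F"),
            dates=pd.date_range("2020-01-01", periods=n),
            Z=z,
            S=np.empty((n, 0)),
            A=a,
            D=dvec,
            lag=0,
            instrument_names=("z1", "z2"),
            seasonal_names=(),
        )
        fit = iv.fit_2sls(d)
        assert any("weak" in w for w in fit.warnings)


class TestPartialF:
    def test_matches_explicit_rss_arithmetic(self):
        rng = np.random.default_rng(21)
        d = random_design(rng, n=20)
        f_stat, p = iv.partial_f(d)
        # independent arithmetic with raw least squares
        x_full = np.column_stack([np.ones(20), d.Z, d.S])
        x_rest = np.column_stack([np.ones(20), d.S])
        rss_f = np.sum((d.A - x_full @ np.linalg.lstsq(x_full, d.A, rcond=None)[0]) ** 2)
        rss_r = np.sum((d.A - x_rest @ np.linalg.lstsq(x_rest, d.A, rcond=None)[0]) ** 2)
        q, k = 5, 10
        expected = ((rss_r - rss_f) / q) / (rss_f / (20 - k))
        assert f_stat == pytest.approx(expected, rel=1e-8)
        assert 0 <= p <= 1

    def test_null_instruments_give_moderate_f(self):
        rng = np.random.default_rng(2)
        fs = []
        for _ in range(30):
            n = 300
            z = (rng.random((n, 5)) < 0.3).astype(float)
            s = rng.standard_normal((n, 4))
            a = 50 + s @ np.array([1.0, 0.5, 0.2, 0.1]) + rng.standard_normal(n)
            d = IVDesign(
                stratum=Stratum(">=65", "F"),
                dates=pd.date_range("2020-01-01", periods=n),
                Z=z,
                S=s,
                A=a,
                D=a,
                lag=0,
                instrument_names=tuple(f"z{i}" for i in range(5)),
                seasonal_names=tuple(f"s{i}" for i in range(4)),
            )
            fs.append(iv.partial_f(d)[0])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_strong_simulated_instruments_significant(self, four_wave_calendar):
        cfg = synthetic.recovery_config(1, calendar=four_wave_calendar)
        series, _ = synthetic.generate_daily_counts(cfg)
        d = iv.build_design(next(iter(series.values())), four_wave_calendar, 0)
        f_stat, p = iv.partial_f(d)
        assert p < 0.05


class TestReporting:
    @pytest.mark.parametrize(
        "theta1, expected", [(-0.02, 2.0), (0.0, 0.0), (0.01, -1.0)]
    )
    def test_late_per_100_point(self, theta1, expected):
        late = iv.late_per_100(make_fit(theta1))
        assert late.point == pytest.approx(expected)

    def test_late_ci_sign_flip_and_reorder(self):
        """theta1=-0.0095 with CI (-0.0152, -0.0038) -> 0.95 (0.38, 1.52)."""
        se = (0.0152 - 0.0038) / 2 / 1.96
        late = iv.late_per_100(make_fit(-0.0095, se))
        assert late.point == pytest.approx(0.95)
        assert late.ci_lo == pytest.approx(0.38, abs=1e-9)
        assert late.ci_hi == pytest.approx(1.52, abs=1e-9)
        assert late.ci_lo < late.ci_hi

    def test_total_excess_hand_arithmetic(self):
        fits = {
            Stratum(">=65", "M"): make_fit(-0.01, stratum=Stratum(">=65", "M")),
            Stratum(">=65", "F"): make_fit(-0.02, stratum=Stratum(">=65", "F")),
        }
        reductions = {Stratum(">=65", "M"): 10_000.0, Stratum(">=65", "F"): 20_000.0}
        est = iv.total_excess(fits, reductions)
        assert est.total == pytest.approx(500.0)
        assert est.total_se == 0.0

    def test_total_excess_zero_thetas(self):
        fits = {Stratum(">=65", "M"): make_fit(0.0, 0.001, Stratum(">=65", "M"))}
        est = iv.total_excess(fits, {Stratum(">=65", "M"): 5000.0})
        assert est.total == 0.0
        assert est.total_ci[0] == pytest.approx(-est.total_ci[1])

    def test_total_excess_ci_symmetric(self):
        fits = {Stratum(">=65", "M"): make_fit(-0.015, 0.004, Stratum(">=65", "M"))}
        est = iv.total_excess(fits, {Stratum(">=65", "M"): 30_000.0})
        assert est.total_ci[1] - est.total == pytest.approx(est.total - est.total_ci[0])

    def test_total_excess_mismatched_strata(self):
        fits = {Stratum(">=65", "M"): make_fit(-0.01, stratum=Stratum(">=65", "M"))}
        with pytest.raises(ValueError, match="stratum sets differ"):
            iv.total_excess(fits, {Stratum(">=65", "F"): 1.0})


class TestLagSweep:
    def test_single_lag_matches_direct_fit(self, four_wave_calendar):
        cfg = synthetic.recovery_config(3, calendar=four_wave_calendar)
        series, _ = synthetic.generate_daily_counts(cfg)
        s = next(iter(series.values()))
        sweep = iv.lag_sweep(s, four_wave_calendar, [0])
        direct = iv.fit_2sls(iv.build_design(s, four_wave_calendar, 0))
        assert len(sweep) == 1
        assert sweep[0].theta1 == pytest.approx(direct.theta1)

    def test_sweep_row_counts(self):
        cal = default_calendar()
        cfg = synthetic.recovery_config(4)
        series, _ = synthetic.generate_daily_counts(cfg)
        sweep = iv.lag_sweep(next(iter(series.values())), cal, range(15))
        assert len(sweep) == 15
        for lag, fit in enumerate(sweep):
            assert fit.n_days == 2192 - lag

    def test_per_lag_errors_propagated_without_abort(self, tiny_calendar):
        dates = tiny_calendar.dates()
        rng = np.random.default_rng(1)
        s = DailyStratumSeries(
            Stratum(">=65", "F"),
            dates,
            rng.integers(50, 70, len(dates)),
            rng.integers(0, 5, len(dates)),
        )
        sweep = iv.lag_sweep(s, tiny_calendar, [0, 1])  # singular: waves 2-4 absent
        assert len(sweep) == 2
        assert all(isinstance(f, SingularDesignError) for f in sweep)
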