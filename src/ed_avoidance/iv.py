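"""Two-stage least squares engine for wave-instrumented excess mortality.

Model, per retained stratum and lag ``i`` (in days):

    stage 1:  A_t     = b0 + sum_k beta_k Z_kt + g' s_t + u_t
    stage 2:  D_{t+i} = theta0 + theta1 * A_t + g'' s_t + e_t

``A_t`` is the daily ED visit count (exposure), ``D`` the daily 28-day death
count tallied by last-visit date (outcome), ``Z`` the five binary wave
instruments (after-wave, wave1..wave4) and ``s_t`` four seasonality terms:
year index (first study year = 0), day-of-year t (Jan 1 = 0), t^2 and t^3.
Stage 2 regresses the outcome on the stage-1 fitted exposure; ``theta1`` is
the local average treatment effect (LATE) among wave compliers, in deaths per
visit.  Standard errors are proper 2SLS errors: the residual variance is
computed with the *actual* exposure substituted back into the second-stage
equation.  ``-100 * theta1`` rescales the LATE to excess deaths per 100
reduced visits.

The joint first-stage explanatory power of the instruments is assessed with a
partial F test against the seasonal-covariates-only model; low values flag
weak instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import INSTRUMENT_LABELS, WaveCalendar
from .etl import DailyStratumSeries, Stratum

logger = logging.getLogger(__name__)

SEASONAL_LABELS = ("year", "t", "t2", "t3")


class SingularDesignError(ValueError):
    """First-stage design matrix is rank-deficient."""


@dataclass
class IVDesign:
    """Row-aligned design for one stratum at one lag."""

    stratum: Stratum
    dates: pd.DatetimeIndex  # exposure days, after lag trimming
    Z: np.ndarray  # (n, 5) binary instruments
    S: np.ndarray  # (n, 4) seasonal covariates
    A: np.ndarray  # exposure: visits/day
    D: np.ndarray  # outcome: deaths28 shifted by lag
    lag: int
    instrument_names: tuple[str, ...] = INSTRUMENT_LABELS
    seasonal_names: tuple[str, ...] = SEASONAL_LABELS

    @property
    def n(self) -> int:
        return len(self.A)


@dataclass
class FirstStageFit:
    coef: pd.Series  # named: const, instruments, seasonal terms
    fitted: np.ndarray
    residuals: np.ndarray
    xtx_inv: np.ndarray
    sigma2: float

    @property
    def beta(self) -> pd.Series:
        """Instrument coefficients only (visits/day shifts)."""
        return self.coef[list(INSTRUMENT_LABELS)]


@dataclass
class TwoSLSFit:
    stratum: Stratum
    lag: int
    n_days: int
    theta0: float
    theta1: float
    se_theta0: float
    se_theta1: float
    ci_theta1: tuple[float, float]
    partial_f: float
    partial_f_p: float
    first_stage: FirstStageFit
    warnings: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "age_group": self.stratum.age_group,
            "sex": self.stratum.sex,
            "lag": self.lag,
            "n_days": self.n_days,
            "theta1": self.theta1,
            "se_theta1": self.se_theta1,
            "ci_lo": self.ci_theta1[0],
            "ci_hi": self.ci_theta1[1],
            "partial_F": self.partial_f,
            "partial_F_p": self.partial_f_p,
        }


@dataclass
class Late:
    """Excess deaths per 100 reduced visits, with a 95% CI."""

    point: float
    ci_lo: float
    ci_hi: float


@dataclass
class ExcessDeathEstimate:
    per_stratum: pd.DataFrame  # theta1, se, reduction, excess, ci_lo, ci_hi
    total: float
    total_se: float
    total_ci: tuple[float, float]


# ---------------------------------------------------------------------------
# design construction


def seasonal_covariates(dates: pd.DatetimeIndex, base_year: int) -> np.ndarray:
    """Year index (base_year -> 0) and 0-based day-of-year t, t^2, t^3."""
    year = dates.year.to_numpy() - base_year
    t = (dates.dayofyear.to_numpy() - 1).astype(float)
    return np.column_stack([year.astype(float), t, t**2, t**3])


def build_design(
    series: DailyStratumSeries, calendar: WaveCalendar, lag: int = 0
) -> IVDesign:
    """Assemble instruments, seasonal covariates, exposure and lagged outcome.

    ``D[t] = deaths28[t + lag]``; the trailing ``lag`` rows are dropped rather
    than wrapped.  Seasonal covariates are evaluated at the exposure day, so
    both stages share identical covariates.
    """
    if not 0 <= lag < len(series):
        raise ValueError(f"lag {lag} outside [0, {len(series) - 1}]")
    n = len(series) - lag
    dates = series.dates[:n]
    z = calendar.instrument_frame(series.dates).to_numpy(dtype=float)[:n]
    s = seasonal_covariates(dates, calendar.study_start.year)
    a = series.visits[:n].astype(float)
    d = series.deaths28[lag:].astype(float)
    return IVDesign(series.stratum, dates, z, s, a, d, lag)


# ---------------------------------------------------------------------------
# least squares internals


def _ols(y: np.ndarray, x: np.ndarray, names: Sequence[str]):
    """QR-based OLS; raises SingularDesignError naming collinear columns."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    scale = np.linalg.norm(x, axis=0)
    scale[scale == 0] = 1.0
    bad = diag / scale < 1e-10
    if bad.any():
        offenders = [names[i] for i in np.nonzero(bad)[0]]
        raise SingularDesignError(
            f"design is rank deficient; collinear/degenerate columns: {offenders}"
        )
    coef = np.linalg.solve(r, q.T @ y)
    rinv = np.linalg.solve(r, np.eye(r.shape[0]))
    xtx_inv = rinv @ rinv.T
    fitted = x @ coef
    return coef, fitted, y - fitted, xtx_inv


def fit_first_stage(design: IVDesign) -> FirstStageFit:
    """OLS of the exposure on [1, Z, S]."""
    names = ["const", *design.instrument_names, *design.seasonal_names]
    x = np.column_stack([np.ones(design.n), design.Z, design.S])
    coef, fitted, resid, xtx_inv = _ols(design.A, x, names)
    dof = design.n - x.shape[1]
    if dof <= 0:
        raise ValueError(f"need more than {x.shape[1]} days, got {design.n}")
    sigma2 = float(resid @ resid / dof)
    return FirstStageFit(
        coef=pd.Series(coef, index=names),
        fitted=fitted,
        residuals=resid,
        xtx_inv=xtx_inv,
        sigma2=sigma2,
    )


def partial_f(design: IVDesign, first_stage: FirstStageFit | None = None):
    """Partial F test of the instruments in the first stage.

    Compares the full first-stage model with the seasonal-covariates-only
    restriction: F = [(RSS_r - RSS_f)/q] / [RSS_f/(n-k)], q = #instruments,
    k = full-model parameter count; p from F(q, n-k).
    """
    if first_stage is None:
        first_stage = fit_first_stage(design)
    q = design.Z.shape[1]
    k = 1 + q + design.S.shape[1]
    dof = design.n - k
    if dof <= 0:
        raise ValueError("not enough rows for the partial F test")
    x_restricted = np.column_stack([np.ones(design.n), design.S])
    _, _, resid_r, _ = _ols(
        design.A, x_restricted, ["const", *design.seasonal_names]
    )
    rss_full = float(first_stage.residuals @ first_stage.residuals)
    rss_restricted = float(resid_r @ resid_r)
    f_stat = ((rss_restricted - rss_full) / q) / (rss_full / dof)
    p = float(stats.f.sf(f_stat, q, dof))
    return float(f_stat), p


def fit_2sls(
    design: IVDesign,
    se_type: str = "classical",
    ci_level: float = 0.95,
    weak_f_floor: float = 10.0,
) -> TwoSLSFit:
    """Two-stage least squares of the lagged outcome on the exposure.

    Stage 2 regresses D on [1, A_hat, S].  Standard errors substitute the
    actual exposure into the structural residuals (proper 2SLS errors, the
    classical homoskedastic form by default; ``se_type='hc1'`` for
    heteroskedasticity-robust).  A partial F below ``weak_f_floor`` attaches
    a weak-instrument warning rather than failing.
    """
    if se_type not in {"classical", "hc1"}:
        raise ValueError("se_type must be 'classical' or 'hc1'")
    first = fit_first_stage(design)
    names2 = ["const", "exposure", *design.seasonal_names]
    xhat = np.column_stack([np.ones(design.n), first.fitted, design.S])
    coef2, _, _, xtx_inv = _ols(design.D, xhat, names2)
    # structural residuals with the actual exposure
    x_actual = np.column_stack([np.ones(design.n), design.A, design.S])
    resid = design.D - x_actual @ coef2
    k2 = xhat.shape[1]
    dof = design.n - k2
    if dof <= 0:
        raise ValueError("not enough rows for the second stage")
    if se_type == "classical":
        sigma2 = float(resid @ resid / dof)
        cov = sigma2 * xtx_inv
    else:  # HC1
        meat = (xhat * (resid**2)[:, None]).T @ xhat
        cov = xtx_inv @ meat @ xtx_inv * (design.n / dof)
    se = np.sqrt(np.diag(cov))
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2))
    theta1 = float(coef2[1])
    se1 = float(se[1])
    f_stat, f_p = partial_f(design, first)
    warnings: list[str] = []
    if f_stat < weak_f_floor:
        warnings.append(
            f"weak instruments: partial F = {f_stat:.2f} < {weak_f_floor}"
        )
        logger.warning("%s (stratum %s, lag %d)", warnings[-1], design.stratum.label, design.lag)
    return TwoSLSFit(
        stratum=design.stratum,
        lag=design.lag,
        n_days=design.n,
        theta0=float(coef2[0]),
        theta1=theta1,
        se_theta0=float(se[0]),
        se_theta1=se1,
        ci_theta1=(theta1 - zcrit * se1, theta1 + zcrit * se1),
        partial_f=f_stat,
        partial_f_p=f_p,
        first_stage=first,
        warnings=warnings,
    )


def ols_slope(design: IVDesign):
    """Naive OLS of D on [1, A, S] - the biased benchmark the IV corrects."""
    x = np.column_stack([np.ones(design.n), design.A, design.S])
    coef, _, resid, xtx_inv = _ols(design.D, x, ["const", "exposure", *design.seasonal_names])
    dof = design.n - x.shape[1]
    sigma2 = float(resid @ resid / dof)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return float(coef[1]), se


# ---------------------------------------------------------------------------
# reporting transforms


def late_per_100(fit: TwoSLSFit) -> Late:
    """Rescale theta1 to excess deaths per 100 reduced visits, CI reordered."""
    lo, hi = sorted((-100.0 * fit.ci_theta1[0], -100.0 * fit.ci_theta1[1]))
    return Late(point=-100.0 * fit.theta1, ci_lo=lo, ci_hi=hi)


def lag_sweep(
    series: DailyStratumSeries,
    calendar: WaveCalendar,
    lags: Sequence[int] = range(15),
    **fit_kwargs,
) -> list[TwoSLSFit | Exception]:
    """One 2SLS fit per lag; per-lag failures are returned, not raised."""
    out: list[TwoSLSFit | Exception] = []
    for lag in lags:
        try:
            out.append(fit_2sls(build_design(series, calendar, lag), **fit_kwargs))
        except Exception as exc:  # propagate per-lag without aborting the sweep
            logger.warning("lag %d failed for %s: %s", lag, series.stratum.label, exc)
            out.append(exc)
    return out


def sweep_table(fits: Sequence[TwoSLSFit | Exception]) -> pd.DataFrame:
    rows = [f.to_row() for f in fits if isinstance(f, TwoSLSFit)]
    return pd.DataFrame(rows)


def total_excess(
    fits: Mapping[Stratum, TwoSLSFit],
    reductions: Mapping[Stratum, float],
    ci_level: float = 0.95,
) -> ExcessDeathEstimate:
    """Aggregate per-stratum LATEs into total excess deaths.

    ``reductions`` are same-period visit reductions (positive = visits lost).
    Stratum excess = theta1 * (-reduction); the pooled variance sums
    reduction^2 * SE(theta1)^2 across strata (independence assumption).
    """
    if set(fits) != set(reductions):
        raise ValueError(
            f"stratum sets differ: fits={sorted(s.label for s in fits)} "
            f"reductions={sorted(s.label for s in reductions)}"
        )
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2))
    rows = []
    for stratum in sorted(fits):
        fit = fits[stratum]
        red = float(reductions[stratum])
        excess = fit.theta1 * (-red)
        se = abs(red) * fit.se_theta1
        rows.append(
            {
                "age_group": stratum.age_group,
                "sex": stratum.sex,
                "theta1": fit.theta1,
                "se_theta1": fit.se_theta1,
                "reduction": red,
                "excess": excess,
                "excess_se": se,
                "ci_lo": excess - zcrit * se,
                "ci_hi": excess + zcrit * se,
            }
        )
    table = pd.DataFrame(rows)
    total = float(table["excess"].sum())
    total_se = float(np.sqrt((table["excess_se"] ** 2).sum()))
    return ExcessDeathEstimate(
        per_stratum=table,
        total=total,
        total_se=total_se,
        total_ci=(total - zcrit * total_se, total + zcrit * total_se),
    )
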