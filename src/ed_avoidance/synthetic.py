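"""Synthetic ED cohort generator with known causal ground truth.

The hospital registry behind the avoidance analysis is confidential, so every
downstream stage is exercised against simulated data whose causal structure is
known exactly.  The generator follows the same linear structural model the
two-stage least squares (2SLS) estimator assumes, per age x sex stratum:

    A_t      = b0 * (1 + trend + season(t)) + sum_k beta_k Z_kt + u_t
    D_{t+i}  = theta0 + theta1 * A_t + d0 * (trend + season(t)) + v_t

where ``A_t`` is the daily visit count (exposure), ``D`` the daily 28-day
death count tallied by last-visit date (outcome), ``Z`` the five binary wave
instruments, ``i`` the injected lag, and ``(u_t, v_t)`` bivariate Gaussian
noise with correlation ``confound_rho``.  A nonzero rho makes naive OLS of
deaths on visits biased (sign of rho) while the wave instruments still
identify ``theta1``.  Counts are rounded and clipped at zero after adding
noise; at the default scale (~3000 visits/day in the large strata) the
rounding bias is negligible relative to estimator tolerances.

``theta1`` is in deaths per visit: theta1 = -0.02 means a day with 100 fewer
visits causes 2 additional deaths ``i`` days later.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calendars import INSTRUMENT_LABELS, WaveCalendar, default_calendar
from .etl import AGE_BINS, DailyStratumSeries, Stratum

logger = logging.getLogger(__name__)

#: Representative dotted ICD-9-CM codes per Deyo category, used when painting
#: diagnosis codes onto synthetic records.
DEYO_EXAMPLE_CODES: dict[str, list[str]] = {
    "myocardial_infarction": ["410.1", "410.9", "412"],
    "congestive_heart_failure": ["428.0", "428.1"],
    "peripheral_vascular_disease": ["443.9", "441.4"],
    "cerebrovascular_disease": ["434.91", "436"],
    "dementia": ["290.0", "290.4"],
    "chronic_pulmonary_disease": ["496", "491.21", "493.90"],
    "rheumatologic_disease": ["714.0", "710.0"],
    "peptic_ulcer_disease": ["531.9", "533.9"],
    "mild_liver_disease": ["571.5", "571.2"],
    "diabetes": ["250.00", "250.1"],
    "diabetes_with_complications": ["250.40", "250.6"],
    "hemiplegia_paraplegia": ["342.9", "344.1"],
    "renal_disease": ["585", "582.9", "586"],
    "malignancy": ["162.9", "153.9", "203.0"],
    "severe_liver_disease": ["572.2", "456.0"],
    "metastatic_tumor": ["197.7", "198.5"],
    "aids": ["042"],
}
#: Plausible non-Deyo filler codes (symptoms, infections, hypertension).
FILLER_CODES = ["786.50", "780.9", "486", "401.9", "599.0"]


@dataclass(frozen=True)
class StratumParams:
    """Baseline rates and causal coefficient for one stratum."""

    age_group: str
    sex: str
    visit_rate: float  # baseline visits/day
    death_rate: float  # baseline 28-day deaths/day
    theta1: float = 0.0  # causal deaths per visit (<=0 for avoidance harm)

    @property
    def stratum(self) -> Stratum:
        return Stratum(self.age_group, self.sex)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    calendar: WaveCalendar = field(default_factory=default_calendar)
    strata: tuple[StratumParams, ...] = ()
    #: per-instrument visit shifts, visits/day (<=0 encodes avoidance)
    beta_wave: Mapping[str, float] = field(default_factory=dict)
    confound_rho: float = 0.0
    season_amp: float = 0.05  # fractional seasonal amplitude
    year_trend: float = 0.01  # fractional drift per year
    lag: int = 0  # days between visit reduction and excess deaths
    ltc_fraction: float = 0.3  # LTC share among >=65 visitors
    doa_fraction: float = 0.15  # DOA/DBA share among decedents
    covid_positive_count: int = 0
    comorbidity_prevalence: Mapping[str, float] = field(default_factory=dict)
    repeat_visit_fraction: float = 0.35
    #: share of decedents who carry prior-visit history (adopt the identity of
    #: a recently active patient), enabling individual-level rate analyses
    decedent_history_fraction: float = 0.6
    reuse_lookback_days: int = 365  # repeat visits cluster within a year
    history_lookback_days: int = 900  # decedents' prior activity horizon
    filler_code_rate: float = 0.4

    def __post_init__(self) -> None:
        if not -1 < self.confound_rho < 1:
            raise ValueError("confound_rho must lie in (-1, 1)")
        if not 0 <= self.lag <= 14:
            raise ValueError("lag must be within 0-14 days")
        for name in ("ltc_fraction", "doa_fraction", "repeat_visit_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.covid_positive_count < 0:
            raise ValueError("covid_positive_count must be nonnegative")
        for cat, p in self.comorbidity_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"comorbidity prevalence for {cat} outside [0, 1]")
            if cat not in DEYO_EXAMPLE_CODES:
                raise ValueError(f"unknown comorbidity category {cat!r}")
        for params in self.strata:
            if params.visit_rate < 0 or params.death_rate < 0:
                raise ValueError("baseline rates must be nonnegative")
        unknown = set(self.beta_wave) - set(INSTRUMENT_LABELS)
        if unknown:
            raise ValueError(f"beta_wave keys not instruments: {sorted(unknown)}")

    @property
    def study_start(self) -> date:
        return self.calendar.study_start

    @property
    def study_end(self) -> date:
        return self.calendar.study_end

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["calendar"] = self.calendar.to_dict()
        payload["beta_wave"] = dict(self.beta_wave)
        payload["comorbidity_prevalence"] = dict(self.comorbidity_prevalence)
        return payload


@dataclass
class GroundTruth:
    """The simulated causal quantities downstream estimators must recover."""

    theta1: dict[str, float]  # per stratum label
    beta_wave: dict[str, float]
    realized_reduction: dict[str, float]  # visits lost to waves, >=0
    implied_excess: dict[str, float]  # -theta1 * reduction per stratum

    @property
    def total_implied_excess(self) -> float:
        return float(sum(self.implied_excess.values()))

    def to_dict(self) -> dict:
        return {
            "theta1": self.theta1,
            "beta_wave": self.beta_wave,
            "realized_reduction": self.realized_reduction,
            "implied_excess": self.implied_excess,
            "total_implied_excess": self.total_implied_excess,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)


def default_strata() -> tuple[StratumParams, ...]:
    """Twelve-stratum cohort echoing the scale of a large urban ED network.

    Totals come to ~5900 visits/day (~2.15M/year) and ~110 28-day deaths/day
    (~40k/year), with mortality concentrated in the oldest groups; the three
    youngest age bands average below one death per day so the sparse-stratum
    exclusion rule has realistic work to do.
    """
    rates = {
        # age_group: (visits/day/sex, deaths/day/sex, theta1)
        "0-17": (350.0, 0.05, 0.0),
        "18-34": (450.0, 0.2, 0.0),
        "35-44": (400.0, 0.6, -0.002),
        "45-54": (430.0, 3.0, -0.005),
        "55-64": (450.0, 8.0, -0.008),
        ">=65": (880.0, 42.0, -0.02),
    }
    return tuple(
        StratumParams(age_group, sex, v, d, theta1)
        for age_group, (v, d, theta1) in rates.items()
        for sex in ("M", "F")
    )


def default_beta_wave() -> dict[str, float]:
    """Wave-driven daily visit shifts: deep drops in waves, partial rebound after."""
    return {
        "wave1": -180.0,
        "wave2": -140.0,
        "wave3": -120.0,
        "wave4": -150.0,
        "after_wave": -60.0,
    }


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    kwargs: dict = dict(
        seed=seed,
        calendar=default_calendar(),
        strata=default_strata(),
        beta_wave=default_beta_wave(),
        confound_rho=0.3,
        covid_positive_count=3716,
        comorbidity_prevalence={
            "congestive_heart_failure": 0.12,
            "diabetes": 0.2,
            "renal_disease": 0.1,
            "malignancy": 0.1,
            "chronic_pulmonary_disease": 0.12,
            "dementia": 0.08,
            "cerebrovascular_disease": 0.08,
            "myocardial_infarction": 0.05,
            "severe_liver_disease": 0.02,
        },
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def recovery_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Single large-stratum configuration for estimator recovery studies.

    One >=65 stratum at ~3000 visits/day with theta1 = -0.02 and confounded
    noise (rho = 0.5): naive OLS is visibly biased while the wave instruments
    identify the truth.
    """
    kwargs: dict = dict(
        seed=seed,
        calendar=default_calendar(),
        strata=(StratumParams(">=65", "F", 3000.0, 40.0, -0.02),),
        beta_wave={
            "wave1": -800.0,
            "wave2": -600.0,
            "wave3": -500.0,
            "wave4": -700.0,
            "after_wave": -250.0,
        },
        confound_rho=0.5,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# structural expectations


#: Winter-high/summer-low annual shape: the least-squares cubic fit (in
#: fractional day-of-year) to an annual cosine.  Being a cubic in t keeps the
#: simulated seasonality inside the span of the estimator's seasonal
#: covariates, so the generator realizes exactly the structural model the
#: 2SLS assumes.
SEASON_SHAPE_COEF = (0.01993822, 9.08900631, -9.10609621, 1.51839506)


def _seasonal_terms(dates: pd.DatetimeIndex, start_year: int, config: SimulationConfig):
    yidx = dates.year.to_numpy() - start_year
    x = (dates.dayofyear.to_numpy() - 1) / 365.0
    season = np.polyval(SEASON_SHAPE_COEF, x)
    return config.year_trend * yidx + config.season_amp * season


def _beta_vector(config: SimulationConfig) -> np.ndarray:
    return np.array([config.beta_wave.get(k, 0.0) for k in INSTRUMENT_LABELS])


def expected_series(
    config: SimulationConfig,
) -> dict[Stratum, tuple[np.ndarray, np.ndarray]]:
    """Noiseless (mu_visits, mu_deaths) per stratum over the study window.

    ``mu_deaths[t]`` is the expected 28-day death count tallied at last-visit
    day ``t``, driven by the expected visits ``lag`` days before ``t``.
    """
    out: dict[Stratum, tuple[np.ndarray, np.ndarray]] = {}
    for params, mu_a_ext, mu_d, _ in _structural_parts(config):
        out[params.stratum] = (mu_a_ext[config.lag :], mu_d)
    return out


def _structural_parts(config: SimulationConfig):
    """Yield (params, mu_A over extended days, mu_D over study days, ext dates)."""
    lag = config.lag
    start = pd.Timestamp(config.study_start) - pd.Timedelta(days=lag)
    ext_dates = pd.date_range(start, config.study_end, freq="D")
    z_ext = config.calendar.instrument_frame(ext_dates).to_numpy(dtype=float)
    beta = _beta_vector(config)
    seas = _seasonal_terms(ext_dates, config.study_start.year, config)
    n_study = len(ext_dates) - lag
    for params in config.strata:
        mu_a = params.visit_rate * (1.0 + seas) + z_ext @ beta
        theta0 = params.death_rate - params.theta1 * params.visit_rate
        # expected deaths tallied at exposure day + lag, exposure days 0..n_study-1
        mu_d = (
            theta0
            + params.theta1 * mu_a[:n_study]
            + params.death_rate * seas[:n_study]
        )
        yield params, mu_a, mu_d, ext_dates


# ---------------------------------------------------------------------------
# generation


def generate_daily_counts(
    config: SimulationConfig,
) -> tuple[dict[Stratum, DailyStratumSeries], GroundTruth]:
    """Simulate per-stratum daily visit and 28-day-death counts.

    Deterministic for a fixed config (seed included).  Configs whose expected
    counts dip below zero on more than 1% of study days are rejected as
    implausible before any noise is drawn.
    """
    if not config.strata:
        raise ValueError("config.strata is empty")
    rng = np.random.default_rng([config.seed, 0])
    lag = config.lag
    study_dates = config.calendar.dates()
    z_study = config.calendar.instrument_frame(study_dates).to_numpy(dtype=float)
    beta = _beta_vector(config)
    rho = config.confound_rho

    series: dict[Stratum, DailyStratumSeries] = {}
    truth_theta: dict[str, float] = {}
    truth_red: dict[str, float] = {}
    truth_excess: dict[str, float] = {}
    reduction_total = float(-(z_study @ beta).sum())

    for params, mu_a, mu_d, ext_dates in _structural_parts(config):
        for name, mu in (("visit", mu_a), ("death", mu_d)):
            frac_neg = float((mu < 0).mean())
            if frac_neg > 0.01:
                raise ValueError(
                    f"stratum {params.stratum.label}: expected {name} counts "
                    f"negative on {frac_neg:.1%} of days - implausible config"
                )
        n_ext = len(ext_dates)
        n_study = n_ext - lag
        sd_u = np.sqrt(max(params.visit_rate, 1.0))
        sd_v = np.sqrt(max(params.death_rate, 0.25))
        z1 = rng.standard_normal(n_ext)
        z2 = rng.standard_normal(n_ext)
        u = sd_u * z1
        v = sd_v * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
        visits_ext = np.clip(np.rint(mu_a + u), 0, None).astype(np.int64)
        theta0 = params.death_rate - params.theta1 * params.visit_rate
        seas = _seasonal_terms(ext_dates, config.study_start.year, config)
        mu_d_realized = (
            theta0
            + params.theta1 * visits_ext[:n_study]
            + params.death_rate * seas[:n_study]
        )
        deaths = np.clip(np.rint(mu_d_realized + v[:n_study]), 0, None).astype(np.int64)
        stratum = params.stratum
        series[stratum] = DailyStratumSeries(
            stratum, study_dates, visits_ext[lag:], deaths
        )
        truth_theta[stratum.label] = params.theta1
        truth_red[stratum.label] = reduction_total
        truth_excess[stratum.label] = -params.theta1 * reduction_total
    truth = GroundTruth(
        theta1=truth_theta,
        beta_wave={k: float(config.beta_wave.get(k, 0.0)) for k in INSTRUMENT_LABELS},
        realized_reduction=truth_red,
        implied_excess=truth_excess,
    )
    return series, truth


def _sample_codes(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> list[str]:
    """Semicolon-joined ICD-9-CM code strings for ``n`` records."""
    per_record: list[list[str]] = [[] for _ in range(n)]
    for cat in sorted(config.comorbidity_prevalence):
        p = config.comorbidity_prevalence[cat]
        if p <= 0:
            continue
        mask = rng.random(n) < p
        if not mask.any():
            continue
        codes = rng.choice(DEYO_EXAMPLE_CODES[cat], size=int(mask.sum()))
        for idx, code in zip(np.nonzero(mask)[0], codes):
            per_record[idx].append(str(code))
    filler_mask = rng.random(n) < config.filler_code_rate
    fillers = rng.choice(FILLER_CODES, size=int(filler_mask.sum()))
    for idx, code in zip(np.nonzero(filler_mask)[0], fillers):
        per_record[idx].append(str(code))
    return [";".join(codes) for codes in per_record]


def generate_visit_records(
    config: SimulationConfig,
    series: Mapping[Stratum, DailyStratumSeries],
) -> pd.DataFrame:
    """Expand daily counts into visit-level records.

    Per stratum-day the record count equals the series' visit count exactly,
    and ``deaths28[t]`` patients have that day as their last visit with a
    death 0-28 days later (DOA/DBA decedents die on the visit day).  Repeat
    visits reuse earlier non-decedent patients, so decedents' last-visit
    assignment is exact by construction.
    """
    rng = np.random.default_rng([config.seed, 1])
    frames: list[pd.DataFrame] = []
    patient_counter = 0
    for si, stratum in enumerate(sorted(series)):
        s = series[stratum]
        visits = s.visits
        deaths = np.minimum(s.deaths28, visits)
        capped = int((s.deaths28 - deaths).sum())
        if capped:
            logger.warning(
                "stratum %s: capped %d deaths at the daily visit count",
                stratum.label,
                capped,
            )
        total = int(visits.sum())
        if total == 0:
            continue
        day_idx = np.repeat(np.arange(len(visits)), visits)
        starts = np.concatenate([[0], np.cumsum(visits)[:-1]])
        pos_in_day = np.arange(total) - np.repeat(starts, visits)
        is_dec = pos_in_day < np.repeat(deaths, visits)
        n_dec = int(is_dec.sum())

        low, high = AGE_BINS[stratum.age_group]
        high = 99 if high is None else high
        ages = rng.integers(low, high + 1, size=total)
        ltc = (
            (rng.random(total) < config.ltc_fraction).astype(np.int8)
            if stratum.age_group == ">=65"
            else np.zeros(total, dtype=np.int8)
        )
        pids = np.array(
            [f"S{si:02d}-{patient_counter + k:08d}" for k in range(total)],
            dtype=object,
        )
        patient_counter += total
        # repeat visits: a non-decedent record may reuse a patient seen
        # within the lookback window (same id, age, LTC status)
        nondec_positions = np.nonzero(~is_dec)[0]
        nondec_days = day_idx[nondec_positions]
        n_nondec = len(nondec_positions)
        if n_nondec > 1 and config.repeat_visit_fraction > 0:
            reuse = rng.random(n_nondec) < config.repeat_visit_fraction
            reuse[0] = False
            for r in np.nonzero(reuse)[0]:
                low = int(
                    np.searchsorted(
                        nondec_days, nondec_days[r] - config.reuse_lookback_days
                    )
                )
                if low >= r:
                    continue
                src = nondec_positions[int(rng.integers(low, r))]
                dst = nondec_positions[r]
                pids[dst] = pids[src]
                ages[dst] = ages[src]
                ltc[dst] = ltc[src]

        # per-patient record positions among non-decedent rows
        patient_rows: dict = {}
        for posn in nondec_positions:
            patient_rows.setdefault(pids[posn], []).append(posn)
        dates = s.dates[day_idx]
        death_date = np.full(total, np.datetime64("NaT"), dtype="datetime64[ns]")
        doa = np.zeros(total, dtype=np.int8)
        if n_dec:
            dec_positions = np.nonzero(is_dec)[0]
            # decedents adopt recently active patients: the adopted patient
            # has no visits after the decedent's (last) visit day, so the
            # last-visit death tally stays exact by construction
            by_last_day = sorted(
                (day_idx[rows[-1]], pid) for pid, rows in patient_rows.items()
            )
            pool: list[tuple[int, str]] = []
            consumed: set[str] = set()
            ptr = 0
            adopted: list[int] = []
            for p in dec_positions:
                t = int(day_idx[p])
                while ptr < len(by_last_day) and by_last_day[ptr][0] <= t:
                    pool.append(by_last_day[ptr])
                    ptr += 1
                if rng.random() >= config.decedent_history_fraction:
                    continue
                for _ in range(4):  # skim stale/consumed entries lazily
                    if not pool:
                        break
                    k = int(rng.integers(len(pool)))
                    last_day, pid0 = pool[k]
                    pool[k] = pool[-1]
                    pool.pop()
                    if pid0 in consumed or last_day < t - config.history_lookback_days:
                        continue
                    consumed.add(pid0)
                    src = patient_rows[pid0][-1]
                    pids[p] = pid0
                    ages[p] = ages[src]
                    ltc[p] = ltc[src]
                    adopted.append(p)
                    break
            offsets = rng.integers(0, 29, size=n_dec)
            is_doa = rng.random(n_dec) < config.doa_fraction
            offsets[is_doa] = 0
            death_date[dec_positions] = dates[dec_positions] + pd.to_timedelta(
                offsets, unit="D"
            )
            doa[dec_positions] = is_doa.astype(np.int8)
            # the death date is a patient-level attribute: propagate it onto
            # the adopted patient's earlier visit records
            for p in adopted:
                for q in patient_rows[pids[p]]:
                    death_date[q] = death_date[p]
        codes = _sample_codes(rng, total, config)
        for k in np.nonzero(doa)[0]:
            codes[k] = ""  # DOA/DBA visits carry no meaningful diagnosis
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids,
                    "visit_date": dates,
                    "age": ages,
                    "sex": stratum.sex,
                    "ltc": ltc,
                    "doa_dba": doa,
                    "covid_pcr": np.zeros(total, dtype=np.int8),
                    "icd9_codes": codes,
                    "death_date": death_date,
                }
            )
        )
    if not frames:
        raise ValueError("series contain no visits")
    records = pd.concat(frames, ignore_index=True)
    if config.covid_positive_count:
        if config.covid_positive_count > len(records):
            raise ValueError(
                f"covid_positive_count={config.covid_positive_count} exceeds "
                f"total record count {len(records)}"
            )
        flagged = rng.choice(
            len(records), size=config.covid_positive_count, replace=False
        )
        records.loc[flagged, "covid_pcr"] = np.int8(1)
    return records


def scale_config(config: SimulationConfig, factor: float) -> SimulationConfig:
    """Scale all baseline rates and wave shifts by ``factor`` (record-level
    work at reduced size; causal coefficients are untouched)."""
    strata = tuple(
        StratumParams(p.age_group, p.sex, p.visit_rate * factor, p.death_rate * factor, p.theta1)
        for p in config.strata
    )
    beta = {k: v * factor for k, v in config.beta_wave.items()}
    payload = config.to_dict()
    payload.pop("calendar")
    payload.pop("strata")
    payload.pop("beta_wave")
    payload["covid_positive_count"] = int(round(config.covid_positive_count * factor))
    return SimulationConfig(
        calendar=config.calendar, strata=strata, beta_wave=beta, **payload
    )
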