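"""Descriptive avoidance analytics: seasonally adjusted changes, DOA/DBA
breakdowns, and the individual-level incidence-rate comparison.

"Seasonally adjusted" here means a same-calendar-window comparison: counts in
a period are compared against the mean of counts in the identical month-day
window over the 2016-2019 baseline years (Feb 29 excluded), which removes
within-year seasonality without any model fitting.

The individual-level analysis follows DOA/DBA decedents aged >=65: each
eligible decedent (at least two visits in the control period) is assigned to
exactly one of three categories - incidence-rate increase, no visits in the
treatment period, or incidence-rate reduction - and category shares are
compared across the pandemic and pre-pandemic groups with a pooled
two-proportion z test.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import WaveCalendar, periods_by_year
from .etl import mark_28day_death_records, validate_records

logger = logging.getLogger(__name__)

CATEGORIES = ("increase", "no_visits", "reduction")


@dataclass(frozen=True)
class Period:
    """Closed calendar-date interval."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"period start {self.start} after end {self.end}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def overlaps(self, other: "Period") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class PeriodChange:
    """A count in a period versus its same-window multi-year baseline."""

    label: str
    baseline: float
    current: float
    change: float
    pct_change: float | None  # None when the baseline is zero

    @classmethod
    def from_counts(cls, label: str, baseline: float, current: float) -> "PeriodChange":
        change = current - baseline
        if baseline > 0:
            pct = 100.0 * change / baseline
        else:
            pct = None
            logger.warning("%s: zero baseline, percent change undefined", label)
        return cls(label, baseline, current, change, pct)


@dataclass(frozen=True)
class GroupSpec:
    """Definition of one DOA/DBA decedent group for the longitudinal analysis."""

    label: str
    doa_window: Period  # window in which the DOA/DBA visit occurred
    control: Period
    treatment: Period
    min_age: int = 65
    min_control_visits: int = 2

    def __post_init__(self) -> None:
        if self.control.overlaps(self.treatment):
            raise ValueError("control and treatment periods overlap")


@dataclass
class GroupCategorization:
    spec: GroupSpec
    eligible: int
    counts: dict[str, int]  # category -> decedent count
    rates: pd.DataFrame  # per-patient control/treatment incidence rates


@dataclass
class IncidenceRateComparison:
    group1: GroupCategorization
    group2: GroupCategorization
    z: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# counting helpers


@dataclass(frozen=True)
class RecordFilter:
    """Row filters shared by all tabulations."""

    min_age: int | None = None
    max_age: int | None = None
    sex: str | None = None
    ltc: bool | None = None
    doa_dba: bool | None = None

    def apply(self, records: pd.DataFrame) -> pd.DataFrame:
        mask = pd.Series(True, index=records.index)
        if self.min_age is not None:
            mask &= records["age"] >= self.min_age
        if self.max_age is not None:
            mask &= records["age"] <= self.max_age
        if self.sex is not None:
            mask &= records["sex"] == self.sex
        if self.ltc is not None:
            mask &= records["ltc"].astype(bool) == self.ltc
        if self.doa_dba is not None:
            mask &= records["doa_dba"].astype(bool) == self.doa_dba
        return records.loc[mask]


def daily_event_counts(
    records: pd.DataFrame,
    what: str = "visits",
    filters: RecordFilter | None = None,
) -> pd.Series:
    """Daily counts of visits or 28-day deaths (by last-visit date).

    Death marking happens after filtering, so the "last visit" is the last
    visit *within the filtered subset*, matching stratified tallies.
    """
    validate_records(records)
    if filters is not None:
        records = filters.apply(records)
    if what == "visits":
        counted = records["visit_date"]
    elif what == "deaths28":
        flag = mark_28day_death_records(records)
        counted = records.loc[flag, "visit_date"]
    else:
        raise ValueError("what must be 'visits' or 'deaths28'")
    return counted.value_counts().sort_index()


def _window_count(daily: pd.Series, days: pd.DatetimeIndex) -> float:
    return float(daily.reindex(days, fill_value=0).sum())


def _baseline_days(days: pd.DatetimeIndex, year: int) -> pd.DatetimeIndex:
    """The same month-day window mapped into ``year``; Feb 29 is dropped."""
    keep = ~((days.month == 2) & (days.day == 29))
    days = days[keep]
    return pd.DatetimeIndex(
        [pd.Timestamp(year=year, month=d.month, day=d.day) for d in days]
    )


def seasonally_adjusted_change(
    records: pd.DataFrame,
    period: Period | pd.DatetimeIndex,
    baseline_years: Sequence[int] = (2016, 2017, 2018, 2019),
    filters: RecordFilter | None = None,
    what: str = "visits",
    label: str = "",
) -> PeriodChange:
    """Period count vs the mean same-calendar-window count over baseline years."""
    days = period.dates() if isinstance(period, Period) else period
    if len(days) == 0:
        raise ValueError("empty period")
    vmin, vmax = records["visit_date"].min(), records["visit_date"].max()
    if pd.isna(vmin) or days.min() > vmax or days.max() < vmin:
        raise ValueError("period lies outside the data")
    daily = daily_event_counts(records, what=what, filters=filters)
    current = _window_count(daily, days)
    baseline = float(
        np.mean([_window_count(daily, _baseline_days(days, y)) for y in baseline_years])
    )
    return PeriodChange.from_counts(label or what, baseline, current)


def change_from_counts(label: str, baseline: float, current: float) -> PeriodChange:
    """Direct change computation on externally supplied counts."""
    return PeriodChange.from_counts(label, baseline, current)


# ---------------------------------------------------------------------------
# DOA/DBA breakdown by wave/non-wave period


def doa_breakdown(
    records: pd.DataFrame,
    calendar: WaveCalendar,
    years: Sequence[int] = (2020, 2021),
    baseline_years: Sequence[int] = (2016, 2017, 2018, 2019),
    min_age: int = 65,
) -> pd.DataFrame:
    """28-day deaths among >=``min_age``, split DOA/DBA x wave/nonwave x year,
    each versus its same-calendar-window baseline average."""
    period_days = periods_by_year(calendar, years)
    rows = []
    for (year, phase), days in sorted(period_days.items()):
        for doa_flag in (False, True):
            filt = RecordFilter(min_age=min_age, doa_dba=doa_flag)
            change = seasonally_adjusted_change(
                records,
                days,
                baseline_years=baseline_years,
                filters=filt,
                what="deaths28",
                label=f"{year} {'DOA/DBA' if doa_flag else 'non-DOA/DBA'} {phase}",
            )
            rows.append(
                {
                    "year": year,
                    "phase": phase,
                    "doa_dba": doa_flag,
                    "n_days": len(days),
                    "baseline": change.baseline,
                    "current": change.current,
                    "change": change.change,
                    "pct_change": change.pct_change,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual-level incidence rates


def incidence_rate(visit_dates: Sequence, period: Period) -> float:
    """Visits per day within ``period`` for one patient."""
    dates = pd.DatetimeIndex(pd.to_datetime(list(visit_dates)))
    start, end = pd.Timestamp(period.start), pd.Timestamp(period.end)
    n = int(((dates >= start) & (dates <= end)).sum())
    return n / period.n_days


def categorize_decedents(records: pd.DataFrame, spec: GroupSpec) -> GroupCategorization:
    """Assign each eligible DOA/DBA decedent to exactly one rate category.

    Eligibility: a DOA/DBA visit within the group window at age >= min_age,
    and at least ``min_control_visits`` visits in the control period.
    Categories partition the eligible set: ``no_visits`` iff zero
    treatment-period visits; else ``increase`` iff treatment rate strictly
    exceeds control rate; else ``reduction`` (ties land in reduction).
    """
    validate_records(records)
    doa = records[
        records["doa_dba"].astype(bool)
        & (records["age"] >= spec.min_age)
        & (records["visit_date"] >= pd.Timestamp(spec.doa_window.start))
        & (records["visit_date"] <= pd.Timestamp(spec.doa_window.end))
        & records["death_date"].notna()
    ]
    decedent_ids = doa["patient_id"].unique()
    by_patient = records[records["patient_id"].isin(decedent_ids)].groupby("patient_id")
    rows = []
    counts = {c: 0 for c in CATEGORIES}
    for pid, grp in by_patient:
        visits = grp["visit_date"]
        control_visits = int(
            (
                (visits >= pd.Timestamp(spec.control.start))
                & (visits <= pd.Timestamp(spec.control.end))
            ).sum()
        )
        if control_visits < spec.min_control_visits:
            continue
        treat_visits = int(
            (
                (visits >= pd.Timestamp(spec.treatment.start))
                & (visits <= pd.Timestamp(spec.treatment.end))
            ).sum()
        )
        control_rate = control_visits / spec.control.n_days
        treat_rate = treat_visits / spec.treatment.n_days
        if treat_visits == 0:
            category = "no_visits"
        elif treat_rate > control_rate:
            category = "increase"
        else:
            category = "reduction"
        counts[category] += 1
        rows.append(
            {
                "patient_id": pid,
                "control_rate": control_rate,
                "treatment_rate": treat_rate,
                "category": category,
            }
        )
    rates = pd.DataFrame(rows, columns=["patient_id", "control_rate", "treatment_rate", "category"])
    return GroupCategorization(
        spec=spec, eligible=len(rates), counts=counts, rates=rates
    )


def two_sample_z(
    count1: int, total1: int, count2: int, total2: int, pooled: bool = True
) -> tuple[float, float]:
    """Two-proportion z test (pooled variance by default), two-sided p.

    Returns ``(nan, nan)`` with a warning when the pooled proportion is
    degenerate (0 or 1), where the statistic is undefined.
    """
    if total1 <= 0 or total2 <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= count1 <= total1 and 0 <= count2 <= total2):
        raise ValueError("counts must lie within their totals")
    p1, p2 = count1 / total1, count2 / total2
    if pooled:
        p_hat = (count1 + count2) / (total1 + total2)
        var = p_hat * (1 - p_hat) * (1 / total1 + 1 / total2)
    else:
        var = p1 * (1 - p1) / total1 + p2 * (1 - p2) / total2
    if var == 0:
        _warnings.warn("degenerate proportions: z test undefined", stacklevel=2)
        return (math.nan, math.nan)
    z = (p1 - p2) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return (float(z), p)


def compare_incidence_groups(
    group1: GroupCategorization, group2: GroupCategorization
) -> IncidenceRateComparison:
    """Per-category pooled two-proportion z tests across the two groups."""
    result = IncidenceRateComparison(group1, group2)
    for cat in CATEGORIES:
        z, p = two_sample_z(
            group1.counts[cat], group1.eligible, group2.counts[cat], group2.eligible
        )
        result.z[cat] = z
        result.p[cat] = p
    return result


def default_group_specs() -> tuple[GroupSpec, GroupSpec]:
    """Pandemic and pre-pandemic DOA/DBA decedent groups (>=65)."""
    covid = GroupSpec(
        label="covid",
        doa_window=Period(date(2020, 7, 1), date(2021, 7, 1)),
        control=Period(date(2019, 1, 1), date(2020, 1, 24)),
        treatment=Period(date(2020, 1, 25), date(2020, 6, 30)),
    )
    pre_covid = GroupSpec(
        label="pre_covid",
        doa_window=Period(date(2018, 7, 1), date(2019, 7, 1)),
        control=Period(date(2017, 1, 1), date(2017, 6, 30)),
        treatment=Period(date(2018, 1, 1), date(2018, 6, 30)),
    )
    return covid, pre_covid
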