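"""Cohort ETL: visit-level records to per-stratum daily series.

The causal model consumes, for each age x sex stratum, two aligned daily
vectors over the study window: the number of ED visits (the exposure) and the
number of 28-day deaths *tallied by the decedent's last visit date* (the
outcome).  This module applies the cohort rules:

* COVID-PCR-positive visits are excluded up front.
* A 28-day death is a death registered 0-28 days (inclusive at both ends)
  after a visit.
* Each decedent contributes at most one 28-day death, assigned to their last
  visit day within the tallied subset; every visit still counts toward the
  visit tally.
* Strata whose mean daily 28-day mortality over the full window is <= 1 are
  excluded from causal fitting (model instability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Age bins partitioning [0, inf): label -> (low, high inclusive; None = open).
AGE_BINS: dict[str, tuple[int, int | None]] = {
    "0-17": (0, 17),
    "18-34": (18, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55-64": (55, 64),
    ">=65": (65, None),
}
SEXES = ("M", "F")

RECORD_COLUMNS = [
    "patient_id",
    "visit_date",
    "age",
    "sex",
    "ltc",
    "doa_dba",
    "covid_pcr",
    "icd9_codes",
    "death_date",
]


@dataclass(frozen=True, order=True)
class Stratum:
    """One age-group x sex cell of the cohort."""

    age_group: str
    sex: str

    def __post_init__(self) -> None:
        if self.age_group not in AGE_BINS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")

    @property
    def label(self) -> str:
        return f"{self.age_group}/{self.sex}"

    def contains_age(self, age: int) -> bool:
        low, high = AGE_BINS[self.age_group]
        return age >= low and (high is None or age <= high)


def all_strata() -> list[Stratum]:
    return [Stratum(a, s) for a in AGE_BINS for s in SEXES]


def age_group_of(age: int) -> str:
    for label, (low, high) in AGE_BINS.items():
        if age >= low and (high is None or age <= high):
            return label
    raise ValueError(f"age {age} outside all bins")


@dataclass
class DailyStratumSeries:
    """Aligned daily visit and 28-day-death counts for one stratum.

    ``deaths28[t]`` counts distinct patients whose last visit fell on day t
    and who died within 28 days of it.
    """

    stratum: Stratum
    dates: pd.DatetimeIndex
    visits: np.ndarray
    deaths28: np.ndarray

    def __post_init__(self) -> None:
        self.visits = np.asarray(self.visits, dtype=np.int64)
        self.deaths28 = np.asarray(self.deaths28, dtype=np.int64)
        n = len(self.dates)
        if len(self.visits) != n or len(self.deaths28) != n:
            raise ValueError("dates, visits and deaths28 must be equal length")
        if n > 1 and not (np.diff(self.dates.to_numpy()) == np.timedelta64(1, "D")).all():
            raise ValueError("dates must be consecutive calendar days")
        if (self.visits < 0).any() or (self.deaths28 < 0).any():
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def mean_daily_deaths(self) -> float:
        return float(self.deaths28.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "visits": self.visits, "deaths28": self.deaths28}
        )

    @classmethod
    def from_frame(cls, stratum: Stratum, frame: pd.DataFrame) -> "DailyStratumSeries":
        frame = frame.sort_values("date")
        return cls(
            stratum=stratum,
            dates=pd.DatetimeIndex(pd.to_datetime(frame["date"])),
            visits=frame["visits"].to_numpy(),
            deaths28=frame["deaths28"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# record I/O


def read_visit_records(path) -> pd.DataFrame:
    """Read the visit-record CSV dialect (ISO dates, flags as 0/1)."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "icd9_codes": str},
        parse_dates=["visit_date", "death_date"],
        keep_default_na=True,
    )
    df["icd9_codes"] = df["icd9_codes"].fillna("")
    for flag in ("ltc", "doa_dba", "covid_pcr"):
        df[flag] = df[flag].astype(np.int8)
    return validate_records(df)


def write_visit_records(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["visit_date"] = pd.to_datetime(out["visit_date"]).dt.strftime("%Y-%m-%d")
    out["death_date"] = pd.to_datetime(out["death_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if (df["age"] < 0).any():
        raise ValueError("ages must be nonnegative")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"invalid sex values: {df.loc[bad_sex, 'sex'].unique()}")
    has_death = df["death_date"].notna()
    early = has_death & (df["death_date"] < df["visit_date"])
    if early.any():
        raise ValueError(
            f"{int(early.sum())} records have death_date before visit_date"
        )
    return df


# ---------------------------------------------------------------------------
# cohort rules


def exclude_covid_positive(records: pd.DataFrame) -> pd.DataFrame:
    """Drop COVID-PCR-positive visits; the removal count is logged."""
    positive = records["covid_pcr"].astype(bool)
    n = int(positive.sum())
    if n:
        logger.info("excluded %d COVID-PCR-positive visit records", n)
    return records.loc[~positive].copy()


def flag_28day_death(visit_date, death_date) -> bool:
    """True iff a death date exists and falls 0-28 days (inclusive) after the visit."""
    if death_date is None or pd.isna(death_date):
        return False
    delta = (pd.Timestamp(death_date) - pd.Timestamp(visit_date)).days
    if delta < 0:
        raise ValueError("death_date precedes visit_date")
    return delta <= 28


def mark_28day_death_records(records: pd.DataFrame) -> pd.Series:
    """Boolean column: this record is its patient's last visit (within the
    given subset) and the patient died within 28 days of it.

    At most one record per patient is marked; a last-visit-day tie marks a
    single record of that day.  Summing the column by visit date yields the
    ``deaths28`` tally.
    """
    validate_records(records)
    flag = pd.Series(False, index=records.index)
    dead = records[records["death_date"].notna()]
    if dead.empty:
        return flag
    # last visit per decedent within this subset
    idx_last = dead.groupby("patient_id")["visit_date"].idxmax()
    last = records.loc[idx_last]
    within = (last["death_date"] - last["visit_date"]).dt.days <= 28
    flag.loc[idx_last[within.to_numpy()]] = True
    return flag


def tally_daily(
    records: pd.DataFrame,
    stratum: Stratum,
    study_start: date,
    study_end: date,
) -> DailyStratumSeries:
    """Tally one stratum's daily visits and 28-day deaths over the window.

    Records outside the study window are rejected (the error lists the
    offending rows).  Days without events appear with zero counts.
    """
    validate_records(records)
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)
    outside = (records["visit_date"] < start) | (records["visit_date"] > end)
    if outside.any():
        offenders = records.loc[outside, ["patient_id", "visit_date"]].head(20)
        raise ValueError(
            f"{int(outside.sum())} records outside study window "
            f"[{study_start}, {study_end}]; first offenders:\n{offenders}"
        )
    in_stratum = records["sex"].eq(stratum.sex) & records["age"].map(
        stratum.contains_age
    )
    sub = records.loc[in_stratum]
    dates = pd.date_range(start, end, freq="D")
    visits = (
        sub.groupby("visit_date").size().reindex(dates, fill_value=0).to_numpy()
    )
    death_flag = mark_28day_death_records(sub) if len(sub) else pd.Series(dtype=bool)
    deaths = (
        sub.loc[death_flag.reindex(sub.index, fill_value=False), "visit_date"]
        .value_counts()
        .reindex(dates, fill_value=0)
        .to_numpy()
        if len(sub)
        else np.zeros(len(dates), dtype=np.int64)
    )
    return DailyStratumSeries(stratum, dates, visits, deaths)


def tally_all_strata(
    records: pd.DataFrame, study_start: date, study_end: date
) -> dict[Stratum, DailyStratumSeries]:
    return {
        stratum: tally_daily(records, stratum, study_start, study_end)
        for stratum in all_strata()
    }


def apply_stratum_exclusion(
    series: Mapping[Stratum, DailyStratumSeries], threshold: float = 1.0
) -> tuple[dict[Stratum, DailyStratumSeries], list[Stratum]]:
    """Drop strata whose mean daily 28-day mortality is <= ``threshold``.

    The inclusive comparison mirrors the cohort rule: a stratum averaging
    exactly one death per day is still considered too sparse for a stable
    daily regression.
    """
    retained: dict[Stratum, DailyStratumSeries] = {}
    dropped: list[Stratum] = []
    for stratum, s in series.items():
        if s.mean_daily_deaths <= threshold:
            dropped.append(stratum)
        else:
            retained[stratum] = s
    if dropped:
        logger.info(
            "excluded %d strata with mean daily 28-day deaths <= %s: %s",
            len(dropped),
            threshold,
            [d.label for d in dropped],
        )
    return retained, dropped


def write_series_csv(series: Iterable[DailyStratumSeries], path) -> None:
    frames = []
    for s in series:
        frame = s.to_frame()
        frame.insert(0, "age_group", s.stratum.age_group)
        frame.insert(1, "sex", s.stratum.sex)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_series_csv(path) -> dict[Stratum, DailyStratumSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out: dict[Stratum, DailyStratumSeries] = {}
    for (age_group, sex), grp in df.groupby(["age_group", "sex"]):
        stratum = Stratum(age_group, sex)
        out[stratum] = DailyStratumSeries.from_frame(stratum, grp)
    return out
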