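"""Wave calendars: labeled pandemic-wave date intervals and instrument indicators.

A :class:`WaveCalendar` holds the closed date intervals of the COVID-19 waves
inside a study window.  From it we derive the five binary instruments used by
the causal model: one indicator per wave (1 on days inside the wave, inclusive
of both endpoints) and an *after-wave* indicator that is 1 on every non-wave
day strictly after the end of the first wave.  Days before the first wave are
the pre-pandemic reference and carry all-zero instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

WAVE_LABELS = ("wave1", "wave2", "wave3", "wave4")
AFTER_WAVE = "after_wave"
#: Instrument column order used throughout the package.
INSTRUMENT_LABELS = (AFTER_WAVE,) + WAVE_LABELS


@dataclass(frozen=True)
class WaveCalendar:
    """Study window plus labeled, non-overlapping wave intervals.

    Parameters
    ----------
    study_start, study_end
        Closed bounds of the study window.
    waves
        Mapping from wave label to a closed ``(start, end)`` date interval.
        Intervals must be chronologically ordered, pairwise disjoint and lie
        inside the study window.
    """

    study_start: date
    study_end: date
    waves: Mapping[str, tuple[date, date]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        prev_end: date | None = None
        for label, (start, end) in self.waves.items():
            if start > end:
                raise ValueError(f"{label}: start {start} after end {end}")
            if start < self.study_start or end > self.study_end:
                raise ValueError(f"{label}: interval outside study window")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{label}: overlaps or precedes previous wave")
            prev_end = end

    @property
    def wave_labels(self) -> tuple[str, ...]:
        return tuple(self.waves)

    @property
    def first_wave_end(self) -> date | None:
        if not self.waves:
            return None
        return min(end for _, end in self.waves.values())

    def dates(self) -> pd.DatetimeIndex:
        """All consecutive calendar days of the study window."""
        return pd.date_range(self.study_start, self.study_end, freq="D")

    def instrument_frame(self, dates: pd.DatetimeIndex | None = None) -> pd.DataFrame:
        """Binary instrument columns (after_wave, wave1..wave4) for ``dates``.

        Wave indicators are 1 within the closed wave interval; ``after_wave``
        is 1 on non-wave days strictly after the first wave's end.  The wave
        columns plus ``after_wave`` are mutually exclusive by construction.
        """
        if dates is None:
            dates = self.dates()
        frame = pd.DataFrame(0, index=dates, columns=list(INSTRUMENT_LABELS), dtype=np.int8)
        in_any_wave = np.zeros(len(dates), dtype=bool)
        for label, (start, end) in self.waves.items():
            mask = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
            frame[label] = mask.astype(np.int8)
            in_any_wave |= np.asarray(mask)
        first_end = self.first_wave_end
        if first_end is not None:
            after = np.asarray(dates > pd.Timestamp(first_end)) & ~in_any_wave
            frame[AFTER_WAVE] = after.astype(np.int8)
        return frame

    def wave_mask(self, dates: pd.DatetimeIndex, year: int | None = None) -> np.ndarray:
        """Boolean mask of days inside any wave, optionally restricted to ``year``."""
        frame = self.instrument_frame(dates)
        mask = frame[list(self.wave_labels)].to_numpy().any(axis=1)
        if year is not None:
            mask &= np.asarray(dates.year == year)
        return mask

    def to_dict(self) -> dict:
        return {
            "study_start": self.study_start.isoformat(),
            "study_end": self.study_end.isoformat(),
            "waves": {
                label: [start.isoformat(), end.isoformat()]
                for label, (start, end) in self.waves.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "WaveCalendar":
        waves = {
            label: (date.fromisoformat(str(lo)), date.fromisoformat(str(hi)))
            for label, (lo, hi) in payload["waves"].items()
        }
        return cls(
            study_start=date.fromisoformat(str(payload["study_start"])),
            study_end=date.fromisoformat(str(payload["study_end"])),
            waves=waves,
        )

    @classmethod
    def from_yaml(cls, path) -> "WaveCalendar":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def default_calendar() -> WaveCalendar:
    """Illustrative four-wave calendar over the 2016-2021 study window.

    The interval endpoints are illustrative stand-ins shaped like Hong Kong's
    four 2020-2021 waves (the fourth wave receding 2021-02-18); real analyses
    should supply the calendar actually used to time government actions.
    """
    return WaveCalendar(
        study_start=date(2016, 1, 1),
        study_end=date(2021, 12, 31),
        waves={
            "wave1": (date(2020, 1, 25), date(2020, 2, 23)),
            "wave2": (date(2020, 3, 17), date(2020, 4, 30)),
            "wave3": (date(2020, 7, 5), date(2020, 9, 6)),
            "wave4": (date(2020, 11, 15), date(2021, 2, 18)),
        },
    )


def periods_by_year(
    calendar: WaveCalendar, years: Sequence[int]
) -> dict[tuple[int, str], pd.DatetimeIndex]:
    """Partition each requested year into its wave and non-wave day sets."""
    out: dict[tuple[int, str], pd.DatetimeIndex] = {}
    for year in years:
        days = pd.date_range(
            max(pd.Timestamp(year, 1, 1), pd.Timestamp(calendar.study_start)),
            min(pd.Timestamp(year, 12, 31), pd.Timestamp(calendar.study_end)),
            freq="D",
        )
        wave = calendar.wave_mask(days)
        out[(year, "wave")] = days[wave]
        out[(year, "nonwave")] = days[~wave]
    return out
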