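import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ed_avoidance.calendars import WaveCalendar
from ed_avoidance.etl import RECORD_COLUMNS
from ed_avoidance.synthetic import SimulationConfig, StratumParams


def rec(
    pid,
    visit,
    age=70,
    sex="F",
    ltc=0,
    doa=0,
    covid=0,
    codes="",
    death=None,
):
    """One visit-record row for hand-built fixtures."""
    return {
        "patient_id": pid,
        "visit_date": pd.Timestamp(visit),
        "age": age,
        "sex": sex,
        "ltc": ltc,
        "doa_dba": doa,
        "covid_pcr": covid,
        "icd9_codes": codes,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
    }


def frame(rows):
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@pytest.fixture
def tiny_calendar():
    """One-quarter window with a single wave."""
    return WaveCalendar(
        dt.date(2020, 1, 1),
        dt.date(2020, 3, 31),
        {"wave1": (dt.date(2020, 2, 1), dt.date(2020, 2, 20))},
    )


@pytest.fixture
def tiny_config(tiny_calendar):
    return SimulationConfig(
        seed=7,
        calendar=tiny_calendar,
        strata=(
            StratumParams(">=65", "F", 60.0, 4.0, -0.02),
            StratumParams("0-17", "M", 40.0, 0.2, 0.0),
        ),
        beta_wave={"wave1": -20.0},
        confound_rho=0.4,
        comorbidity_prevalence={"renal_disease": 0.3, "diabetes": 0.2},
    )


@pytest.fixture
def four_wave_calendar():
    """Two-year window containing all four waves (keeps designs full rank)."""
    return WaveCalendar(
        dt.date(2019, 1, 1),
        dt.date(2020, 12, 31),
        {
            "wave1": (dt.date(2020, 1, 25), dt.date(2020, 2, 23)),
            "wave2": (dt.date(2020, 3, 17), dt.date(2020, 4, 30)),
            "wave3": (dt.date(2020, 7, 5), dt.date(2020, 9, 6)),
            "wave4": (dt.date(2020, 11, 15), dt.date(2020, 12, 20)),
        },
    )


def random_design(rng, n=None, q=5, p=4):
    """A small random full-rank IV design for oracle-equivalence checks."""
    from ed_avoidance.etl import Stratum
    from ed_avoidance.iv import IVDesign

    n = n or int(rng.integers(40, 90))
    while True:
        z = (rng.random((n, q)) < 0.3).astype(float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), z])) == q + 1:
            break
    s = rng.standard_normal((n, p))
    a = 50 + z @ rng.normal(-8, 2, q) + s @ rng.normal(1, 0.5, p) + rng.standard_normal(n)
    d = 5 - 0.05 * a + s @ rng.normal(0.2, 0.1, p) + rng.standard_normal(n)
    return IVDesign(
        stratum=Stratum(">=65", "F"),
        dates=pd.date_range("2020-01-01", periods=n, freq="D"),
        Z=z,
        S=s,
        A=a,
        D=d,
        lag=0,
        instrument_names=tuple(f"z{i}" for i in range(q)),
        seasonal_names=tuple(f"s{i}" for i in range(p)),
    )
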