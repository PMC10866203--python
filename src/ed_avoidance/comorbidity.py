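"""Deyo-Charlson comorbidity mapping and per-comorbidity change tables.

ICD-9-CM diagnosis codes are mapped to the 17 Deyo (1992 ICD-9-CM adaptation
of Charlson) comorbidity categories using a code table shipped with the
package (``data/deyo_icd9.csv``: category, pattern, match type).  Codes are
normalized by stripping dots and upper-casing; patterns match either exactly
or as prefixes of the undotted code (so pattern ``428`` matches ``4280``).
Categories are independent multi-label flags - no Charlson score weighting is
applied.  Hierarchy note for scoring contexts: severe liver disease subsumes
mild liver disease and metastatic tumor subsumes malignancy; both flags are
still reported.

Range boundaries retained from the published list: malignancy covers
140-172 and 174-195.8 (prefix 195 only reaches 195.8 in ICD-9-CM) plus
200-208; metastatic tumor covers 196-199.1 (196-198 as prefixes, 199.0/199.1
and bare 199 explicitly, so 199.2 does not match).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .avoidance import RecordFilter, seasonally_adjusted_change
from .calendars import WaveCalendar, periods_by_year

logger = logging.getLogger(__name__)

DEYO_CATEGORIES = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatologic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes",
    "diabetes_with_complications",
    "hemiplegia_paraplegia",
    "renal_disease",
    "malignancy",
    "severe_liver_disease",
    "metastatic_tumor",
    "aids",
)


@dataclass(frozen=True)
class DeyoProfile:
    """17 boolean comorbidity flags, deterministic in the code list."""

    myocardial_infarction: bool = False
    congestive_heart_failure: bool = False
    peripheral_vascular_disease: bool = False
    cerebrovascular_disease: bool = False
    dementia: bool = False
    chronic_pulmonary_disease: bool = False
    rheumatologic_disease: bool = False
    peptic_ulcer_disease: bool = False
    mild_liver_disease: bool = False
    diabetes: bool = False
    diabetes_with_complications: bool = False
    hemiplegia_paraplegia: bool = False
    renal_disease: bool = False
    malignancy: bool = False
    severe_liver_disease: bool = False
    metastatic_tumor: bool = False
    aids: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(name for name, on in self.as_dict().items() if on)

    def any(self) -> bool:
        return bool(self.active)


class DeyoTable:
    """Compiled category -> (exact codes, prefixes) lookup."""

    def __init__(self, frame: pd.DataFrame):
        unknown = set(frame["category"]) - set(DEYO_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown Deyo categories in table: {sorted(unknown)}")
        self.exact: dict[str, set[str]] = {c: set() for c in DEYO_CATEGORIES}
        self.prefixes: dict[str, tuple[str, ...]] = {}
        by_cat: dict[str, list[str]] = {c: [] for c in DEYO_CATEGORIES}
        for row in frame.itertuples(index=False):
            pattern = normalize_icd9(row.pattern)
            if row.match_type == "exact":
                self.exact[row.category].add(pattern)
            elif row.match_type == "prefix":
                by_cat[row.category].append(pattern)
            else:
                raise ValueError(f"unknown match_type {row.match_type!r}")
        for cat, pats in by_cat.items():
            self.prefixes[cat] = tuple(sorted(pats))

    def categories_of(self, code: str) -> tuple[str, ...]:
        norm = normalize_icd9(code)
        hits = []
        for cat in DEYO_CATEGORIES:
            if norm in self.exact[cat] or norm.startswith(self.prefixes[cat]):
                hits.append(cat)
        return tuple(hits)


_default_table: DeyoTable | None = None


def normalize_icd9(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def load_deyo_table() -> DeyoTable:
    global _default_table
    if _default_table is None:
        path = resources.files("ed_avoidance").joinpath("data/deyo_icd9.csv")
        with resources.as_file(path) as fp:
            _default_table = DeyoTable(pd.read_csv(fp, dtype=str))
    return _default_table


def map_icd9_to_deyo(
    codes: Iterable[str], table: DeyoTable | None = None
) -> DeyoProfile:
    """Map a visit's ICD-9-CM code list to Deyo comorbidity flags.

    Unrecognized codes are ignored (logged at debug level), never fatal.
    Idempotent and invariant under permutation or duplication of codes.
    """
    if table is None:
        table = load_deyo_table()
    flags: dict[str, bool] = {}
    for code in codes:
        if not str(code).strip():
            continue
        cats = table.categories_of(code)
        if not cats:
            logger.debug("unrecognized ICD-9-CM code ignored: %r", code)
        for cat in cats:
            flags[cat] = True
    return DeyoProfile(**flags)


def profile_records(records: pd.DataFrame, table: DeyoTable | None = None) -> pd.Series:
    """Per-record frozenset of Deyo categories (cached per unique code string)."""
    if table is None:
        table = load_deyo_table()
    cache: dict[str, frozenset[str]] = {}

    def lookup(joined: str) -> frozenset[str]:
        if joined not in cache:
            codes = [c for c in str(joined).split(";") if c.strip()]
            cache[joined] = frozenset(map_icd9_to_deyo(codes, table).active)
        return cache[joined]

    return records["icd9_codes"].fillna("").map(lookup)


def comorbidity_change_table(
    records: pd.DataFrame,
    calendar: WaveCalendar,
    year: int = 2020,
    baseline_years: Sequence[int] = (2016, 2017, 2018, 2019),
    min_age: int = 65,
    table: DeyoTable | None = None,
) -> pd.DataFrame:
    """Per-comorbidity visit and 28-day-death changes among older non-DOA/DBA
    patients, wave and non-wave periods separately.

    Records are multi-label: a visit coded for both diabetes and renal disease
    contributes to both category subsets.  Categories with no members in the
    data are omitted (logged).  The emitted frame carries a
    ``visit_pct == death_pct`` reference diagonal for plotting.
    """
    eligible = records[
        (records["age"] >= min_age) & (~records["doa_dba"].astype(bool))
    ].copy()
    cats = profile_records(eligible, table)
    period_days = periods_by_year(calendar, [year])
    rows = []
    for cat in DEYO_CATEGORIES:
        member = cats.map(lambda s: cat in s)
        sub = eligible.loc[member]
        if sub.empty:
            logger.info("comorbidity %s: no members, omitted", cat)
            continue
        for (yr, phase), days in sorted(period_days.items()):
            row: dict = {"category": cat, "year": yr, "phase": phase}
            for what, prefix in (("visits", "visit"), ("deaths28", "death")):
                change = seasonally_adjusted_change(
                    sub,
                    days,
                    baseline_years=baseline_years,
                    filters=RecordFilter(),
                    what=what,
                    label=f"{cat} {yr} {phase} {what}",
                )
                row[f"{prefix}_baseline"] = change.baseline
                row[f"{prefix}_current"] = change.current
                row[f"{prefix}_pct"] = change.pct_change
            row["diagonal_pct"] = row["visit_pct"]  # 1:1 visit/death reference
            rows.append(row)
    return pd.DataFrame(rows)
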