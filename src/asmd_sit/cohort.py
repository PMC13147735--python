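"""Patient-chart domain types, delimited-text I/O and descriptive statistics.

A cohort is a table of chart reviews: one row per patient with the group
label (case / control / non_case), ASMD subtype for cases, sex, ages and a
tri-state indicator (present / absent / unknown) per catalogued symptom.
Missing chart findings stay ``unknown`` — they are never coerced to absent;
downstream modules decide how to handle them.

File format: UTF-8 CSV with columns
``patient_id,group,subtype,sex,age_onset_years,age_current_years,<symptom_id>...``
where symptoms are coded 1 (present), 0 (absent) or empty (unknown).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, SymptomCatalog

logger = logging.getLogger(__name__)

GROUPS = ("case", "control", "non_case")
SUBTYPES = ("A", "AB", "B", "none")
SEXES = ("male", "female")

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"

_META_COLUMNS = [
    "patient_id",
    "group",
    "subtype",
    "sex",
    "age_onset_years",
    "age_current_years",
]


class CohortError(ValueError):
    """Raised for malformed cohort data."""


@dataclass(frozen=True)
class PatientRecord:
    """One chart row."""

    patient_id: str
    group: str
    sex: str
    subtype: str = "none"
    age_onset_years: float | None = None
    age_current_years: float | None = None
    symptoms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"group label {self.group!r} not one of {GROUPS}")
        if self.subtype not in SUBTYPES:
            raise CohortError(f"subtype {self.subtype!r} not one of {SUBTYPES}")
        if self.subtype != "none" and self.group != "case":
            raise CohortError(
                f"patient {self.patient_id!r}: subtype {self.subtype!r} requires group 'case'"
            )
        if self.sex not in SEXES:
            raise CohortError(f"sex {self.sex!r} not one of {SEXES}")
        for age_name in ("age_onset_years", "age_current_years"):
            v = getattr(self, age_name)
            if v is not None and (math.isnan(v) or v < 0):
                if v is not None and not math.isnan(v):
                    raise CohortError(
                        f"patient {self.patient_id!r}: negative {age_name} {v}"
                    )
        for sid, state in self.symptoms.items():
            if state not in (PRESENT, ABSENT, UNKNOWN):
                raise CohortError(
                    f"patient {self.patient_id!r}: bad symptom state {state!r} for {sid!r}"
                )


class Cohort:
    """A set of patient records with its symptom catalogue.

    Internally the cohort is a :class:`pandas.DataFrame` (one row per patient,
    symptoms as nullable Int8: 1 present, 0 absent, <NA> unknown), which makes
    the screening, modelling and resampling modules vectorisable; records are
    materialised on demand.
    """

    def __init__(self, records: Iterable[PatientRecord] | pd.DataFrame,
                 catalog: SymptomCatalog = DEFAULT_CATALOG):
        self.catalog = catalog
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = _records_to_frame(list(records), catalog)
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise CohortError(f"cohort frame lacks columns {missing}")
        unknown_cols = [
            c for c in df.columns
            if c not in _META_COLUMNS and c not in catalog
        ]
        if unknown_cols:
            raise CohortError(f"unrecognized symptom columns {unknown_cols}")
        for sid in catalog.symptom_ids:
            if sid not in df.columns:
                df[sid] = pd.array([pd.NA] * len(df), dtype="Int8")
            else:
                df[sid] = df[sid].astype("Int8")
        df = df[_META_COLUMNS + catalog.symptom_ids].reset_index(drop=True)
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicate patient_id {dup.iloc[0]!r}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise CohortError(f"group label {sorted(bad)[0]!r} not one of {GROUPS}")
        self._df = df

    # -- basic accessors ---------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying patient table (copy-on-write view)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def group_counts(self) -> dict[str, int]:
        vc = self._df["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in GROUPS}

    @property
    def n_total(self) -> int:
        return len(self._df)

    def group_codes(self, order: tuple[str, ...] = GROUPS) -> np.ndarray:
        """Integer class labels in the given group order."""
        mapping = {g: i for i, g in enumerate(order)}
        return self._df["group"].map(mapping).to_numpy(dtype=np.int64)

    def symptom_matrix(self, symptom_ids: list[str] | None = None) -> np.ndarray:
        """Float matrix of symptom indicators; unknown becomes NaN."""
        ids = symptom_ids or self.catalog.symptom_ids
        return self._df[ids].to_numpy(dtype="float64", na_value=np.nan)

    def records(self) -> list[PatientRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            d = row._asdict()
            symptoms = {}
            for sid in self.catalog.symptom_ids:
                v = d[sid]
                symptoms[sid] = (
                    UNKNOWN if pd.isna(v) else (PRESENT if v == 1 else ABSENT)
                )
            out.append(PatientRecord(
                patient_id=str(d["patient_id"]),
                group=d["group"],
                subtype=d["subtype"],
                sex=d["sex"],
                age_onset_years=None if pd.isna(d["age_onset_years"]) else float(d["age_onset_years"]),
                age_current_years=None if pd.isna(d["age_current_years"]) else float(d["age_current_years"]),
                symptoms=symptoms,
            ))
        return out

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self._df.loc[np.asarray(mask)].reset_index(drop=True), self.catalog)


def _records_to_frame(records: list[PatientRecord], catalog: SymptomCatalog) -> pd.DataFrame:
    rows = []
    for r in records:
        bad = set(r.symptoms) - set(catalog.symptom_ids)
        if bad:
            raise CohortError(
                f"patient {r.patient_id!r}: symptoms {sorted(bad)} not in catalog"
            )
        row: dict = {
            "patient_id": r.patient_id,
            "group": r.group,
            "subtype": r.subtype,
            "sex": r.sex,
            "age_onset_years": np.nan if r.age_onset_years is None else r.age_onset_years,
            "age_current_years": np.nan if r.age_current_years is None else r.age_current_years,
        }
        for sid in catalog.symptom_ids:
            state = r.symptoms.get(sid, UNKNOWN)
            row[sid] = pd.NA if state == UNKNOWN else (1 if state == PRESENT else 0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_META_COLUMNS + catalog.symptom_ids)
    for sid in catalog.symptom_ids:
        df[sid] = df[sid].astype("Int8")
    return df


# -- I/O -------------------------------------------------------------------

def read_cohort(path, catalog: SymptomCatalog = DEFAULT_CATALOG) -> Cohort:
    """Read a cohort CSV.

    Unrecognised symptom columns are rejected; empty symptom fields become
    ``unknown``; empty ages become missing. Raises :class:`CohortError` with
    the offending line number for malformed rows.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True)
    required = ["patient_id", "group", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: header lacks required columns {missing}")
    if "subtype" not in df.columns:
        df["subtype"] = "none"
    df["subtype"] = df["subtype"].fillna("none")
    for c in ("age_onset_years", "age_current_years"):
        if c not in df.columns:
            df[c] = np.nan
        df[c] = pd.to_numeric(df[c], errors="coerce")
        neg = df.index[df[c] < 0]
        if len(neg):
            raise CohortError(
                f"{path}: line {neg[0] + 2}: negative {c} value {df.loc[neg[0], c]}"
            )
    symptom_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown_cols = [c for c in symptom_cols if c not in catalog]
    if unknown_cols:
        raise CohortError(f"{path}: unrecognized symptom columns {unknown_cols}")
    for c in symptom_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.notna() & ~vals.isin([0, 1])]
        if len(bad):
            raise CohortError(
                f"{path}: line {bad[0] + 2}: symptom {c!r} value "
                f"{df.loc[bad[0], c]!r} is not 0/1/empty"
            )
        df[c] = vals.astype("Int8")
    # group / sex / subtype validity and duplicate ids are checked by Cohort
    bad_rows = df.index[~df["group"].isin(GROUPS)]
    if len(bad_rows):
        raise CohortError(
            f"{path}: line {bad_rows[0] + 2}: group label "
            f"{df.loc[bad_rows[0], 'group']!r} not one of {GROUPS}"
        )
    for r in df.itertuples(index=False):
        # route through PatientRecord invariants cheaply for subtype/sex checks
        if r.subtype not in SUBTYPES:
            raise CohortError(f"{path}: subtype {r.subtype!r} not one of {SUBTYPES}")
        if r.subtype != "none" and r.group != "case":
            raise CohortError(
                f"{path}: patient {r.patient_id!r}: subtype {r.subtype!r} "
                "requires group 'case'"
            )
        if r.sex not in SEXES:
            raise CohortError(f"{path}: sex {r.sex!r} not one of {SEXES}")
    return Cohort(df, catalog)


def write_cohort(cohort: Cohort, path):
    """Write a cohort to CSV in the canonical schema; returns the path."""
    df = cohort.frame.copy()
    for sid in cohort.catalog.symptom_ids:
        df[sid] = df[sid].astype("Int8")
    df.to_csv(path, index=False)
    return path


# -- descriptive statistics ------------------------------------------------

@dataclass
class CohortSummary:
    """Per-group demographic summary (counts, percents, age statistics)."""

    n: dict[str, int]
    sex_counts: dict[str, dict[str, int]]
    sex_percents: dict[str, dict[str, float]]
    age_stats: dict[str, dict[str, dict[str, float]]]
    family_history_counts: dict[str, int]
    missing_age_counts: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "sex_counts": self.sex_counts,
            "sex_percents": self.sex_percents,
            "age_stats": self.age_stats,
            "family_history_counts": self.family_history_counts,
            "missing_age_counts": self.missing_age_counts,
        }


_AGE_VARS = ("age_onset_years", "age_current_years")


def describe_cohort(cohort: Cohort) -> CohortSummary:
    """Demographic summary per group.

    Age statistics (min, Q1, median, mean, SD, Q3, max) are computed over
    non-missing values; the number of skipped missing values is reported and
    logged. Percents are rounded to whole numbers for display; underlying
    counts are exact.
    """
    if len(cohort) == 0:
        raise CohortError("cannot describe an empty cohort")
    df = cohort.frame
    n = cohort.group_counts
    sex_counts: dict[str, dict[str, int]] = {}
    sex_percents: dict[str, dict[str, float]] = {}
    age_stats: dict[str, dict[str, dict[str, float]]] = {}
    fh: dict[str, int] = {}
    miss: dict[str, dict[str, int]] = {}
    for g in GROUPS:
        sub = df[df["group"] == g]
        ng = len(sub)
        sc = {s: int((sub["sex"] == s).sum()) for s in SEXES}
        sex_counts[g] = sc
        sex_percents[g] = {
            s: (round(100.0 * c / ng) if ng else 0.0) for s, c in sc.items()
        }
        age_stats[g] = {}
        miss[g] = {}
        for v in _AGE_VARS:
            vals = sub[v].dropna()
            miss[g][v] = int(ng - len(vals))
            if miss[g][v]:
                logger.info("describe_cohort: %d missing %s in group %s", miss[g][v], v, g)
            if len(vals):
                age_stats[g][v] = {
                    "min": float(vals.min()),
                    "q1": float(vals.quantile(0.25)),
                    "median": float(vals.median()),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "q3": float(vals.quantile(0.75)),
                    "max": float(vals.max()),
                }
            else:
                age_stats[g][v] = {}
        if "family_history_asmd" in cohort.catalog:
            fh[g] = int((sub["family_history_asmd"] == 1).sum())
        else:
            fh[g] = 0
    return CohortSummary(
        n=n, sex_counts=sex_counts, sex_percents=sex_percents,
        age_stats=age_stats, family_history_counts=fh, missing_age_counts=miss,
    )
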