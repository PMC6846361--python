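"""Cohort ingestion, validation, inclusion filtering, and summaries.

A cohort is one row per creatinine/measured-GFR pair with demographics,
treating center, diagnosis group and measurement dates.  The inclusion rules
applied by :func:`apply_inclusion_filters` mirror a multicenter GFR-model
validation design: adults only, serum creatinine between 0.20 and 4.5 mg/dL
(inclusive), and the creatinine drawn within 30 days of the measured-GFR
date.  :func:`select_first_mgfr` keeps the earliest measured GFR per patient.

The in-memory container is a pandas DataFrame wrapped with provenance, a
per-rule filter audit log, and the rejects collected during ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import Sex, creatinine_to_mgdl, dubois_bsa

__all__ = [
    "COLUMNS",
    "Cohort",
    "FilterLogEntry",
    "EmptyCohortError",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_filters",
    "select_first_mgfr",
    "summarize_cohort",
]

#: canonical record columns, in file order
COLUMNS = [
    "patient_id",
    "center",
    "diagnosis_group",
    "sex",
    "race_black",
    "age",
    "height_cm",
    "weight_kg",
    "creatinine_mgdl",
    "creatinine_date",
    "mgfr_ml_min",
    "tracer",
    "mgfr_date",
]

DIAGNOSIS_GROUPS = ("solid_cancer", "hematological_cancer", "noncancer")
TRACERS = ("cr51_edta", "tc99m_dtpa")

#: creatinine inclusion bounds, mg/dL, both ends inclusive
CREATININE_BOUNDS = (0.20, 4.5)
#: adult age threshold, years
ADULT_AGE = 18.0
#: maximum |creatinine date - mGFR date|, days, two-sided
DATE_WINDOW_DAYS = 30


class EmptyCohortError(ValueError):
    """Raised when an operation requires at least one record."""


@dataclass(frozen=True)
class FilterLogEntry:
    rule: str
    excluded: int


@dataclass
class Cohort:
    """Ordered patient records plus provenance and a filter audit trail."""

    records: pd.DataFrame
    provenance: str = ""
    filter_log: list[FilterLogEntry] = field(default_factory=list)
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: pd.DataFrame, log: list[FilterLogEntry] | None = None) -> "Cohort":
        return Cohort(
            records=records,
            provenance=self.provenance,
            filter_log=self.filter_log + (log or []),
            rejects=self.rejects,
        )


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    low = s.astype(str).str.strip().str.lower()
    ok = low.isin(_TRUE | _FALSE)
    return low.isin(_TRUE), ok


def read_cohort(path, schema_config: dict | None = None, delimiter: str | None = None) -> Cohort:
    """Read a delimiter-separated cohort table into a typed :class:`Cohort`.

    The file carries a header row; creatinine arrives as a value/unit column
    pair (``creatinine_value``, ``creatinine_unit`` with unit ``mg_dl`` or
    ``umol_l``) and is converted to mg/dL on ingest.  ``schema_config`` maps
    canonical column names to the file's column names for non-default
    headers.  Malformed rows are not silently dropped: they are collected in
    ``cohort.rejects`` with a per-row reason.

    Parameters
    ----------
    path : file path
    schema_config : optional mapping canonical name -> source column name
    delimiter : ``","`` (default) or ``"\\t"``; sniffed from the header when
        None
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if delimiter is None:
        delimiter = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    source_cols = ["patient_id", "center", "diagnosis_group", "sex", "race_black",
                   "age", "height_cm", "weight_kg", "creatinine_value",
                   "creatinine_unit", "creatinine_date", "mgfr_ml_min", "tracer",
                   "mgfr_date"]
    mapping = {c: c for c in source_cols}
    if schema_config:
        mapping.update(schema_config)
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    df = raw[[mapping[c] for c in source_cols]].copy()
    df.columns = source_cols

    reason = pd.Series("", index=df.index)

    def flag(bad: pd.Series, msg: str) -> None:
        nonlocal reason
        reason = reason.mask(bad & (reason == ""), msg)

    num_cols = ["age", "height_cm", "weight_kg", "creatinine_value", "mgfr_ml_min"]
    parsed_num = {}
    for col in num_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.isna(), f"unparseable number in {col}")
        flag(~vals.isna() & ~np.isfinite(vals), f"non-finite {col}")
        flag(vals <= 0, f"non-positive {col}")
        parsed_num[col] = vals

    parsed_date = {}
    for col in ["creatinine_date", "mgfr_date"]:
        vals = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        flag(vals.isna(), f"unparseable date in {col}")
        parsed_date[col] = vals

    flag(~df["diagnosis_group"].isin(DIAGNOSIS_GROUPS), "unknown diagnosis_group")
    flag(~df["sex"].isin([s.value for s in Sex]), "unknown sex")
    flag(~df["tracer"].isin(TRACERS), "unknown tracer")
    flag(~df["creatinine_unit"].isin(["mg_dl", "umol_l"]), "unknown creatinine unit")
    race, race_ok = _parse_bool(df["race_black"])
    flag(~race_ok, "unparseable race_black")
    flag(df["patient_id"].str.strip() == "", "empty patient_id")

    bad = reason != ""
    rejects = raw.loc[bad].copy()
    rejects.insert(0, "reason", reason[bad])
    rejects.insert(0, "row", rejects.index)
    rejects = rejects.reset_index(drop=True)

    good = ~bad
    scr = parsed_num["creatinine_value"].where(
        df["creatinine_unit"] == "mg_dl",
        parsed_num["creatinine_value"] / 88.42,
    )
    records = pd.DataFrame(
        {
            "patient_id": df["patient_id"][good],
            "center": df["center"][good],
            "diagnosis_group": df["diagnosis_group"][good],
            "sex": df["sex"][good],
            "race_black": race[good],
            "age": parsed_num["age"][good],
            "height_cm": parsed_num["height_cm"][good],
            "weight_kg": parsed_num["weight_kg"][good],
            "creatinine_mgdl": scr[good],
            "creatinine_date": parsed_date["creatinine_date"][good],
            "mgfr_ml_min": parsed_num["mgfr_ml_min"][good],
            "tracer": df["tracer"][good],
            "mgfr_date": parsed_date["mgfr_date"][good],
        }
    ).reset_index(drop=True)
    return Cohort(records=records, provenance=str(path), rejects=rejects)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort to the same delimiter-separated format read_cohort reads.

    Creatinine is written in mg/dL; valid rows round-trip losslessly.
    """
    df = cohort.records.copy()
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "center": df["center"],
            "diagnosis_group": df["diagnosis_group"],
            "sex": df["sex"],
            "race_black": df["race_black"].map({True: "true", False: "false"}),
            "age": df["age"],
            "height_cm": df["height_cm"],
            "weight_kg": df["weight_kg"],
            "creatinine_value": df["creatinine_mgdl"],
            "creatinine_unit": "mg_dl",
            "creatinine_date": pd.to_datetime(df["creatinine_date"]).dt.strftime("%Y-%m-%d"),
            "mgfr_ml_min": df["mgfr_ml_min"],
            "tracer": df["tracer"],
            "mgfr_date": pd.to_datetime(df["mgfr_date"]).dt.strftime("%Y-%m-%d"),
        }
    )
    out.to_csv(path, sep=delimiter, index=False)


def apply_inclusion_filters(cohort: Cohort) -> Cohort:
    """Apply the study inclusion rules, logging per-rule exclusion counts.

    Rules, in order: age >= 18 years; creatinine in [0.20, 4.5] mg/dL
    (inclusive); |creatinine date - mGFR date| <= 30 days (two-sided).
    Idempotent: a second application excludes nothing.
    """
    df = cohort.records
    log: list[FilterLogEntry] = []

    keep = df["age"] >= ADULT_AGE
    log.append(FilterLogEntry("adult_age_ge_18", int((~keep).sum())))
    df = df[keep]

    lo, hi = CREATININE_BOUNDS
    keep = (df["creatinine_mgdl"] >= lo) & (df["creatinine_mgdl"] <= hi)
    log.append(FilterLogEntry("creatinine_0.20_to_4.5_mgdl", int((~keep).sum())))
    df = df[keep]

    delta = (pd.to_datetime(df["creatinine_date"]) - pd.to_datetime(df["mgfr_date"])).dt.days.abs()
    keep = delta <= DATE_WINDOW_DAYS
    log.append(FilterLogEntry("creatinine_within_30d_of_mgfr", int((~keep).sum())))
    df = df[keep]

    return cohort.with_records(df.reset_index(drop=True), log)


def select_first_mgfr(cohort: Cohort) -> Cohort:
    """Keep one record per patient: the earliest mGFR date.

    Same-date ties are broken by first occurrence in input order (stable).
    """
    df = cohort.records
    if df.empty:
        return cohort.with_records(df, [FilterLogEntry("first_mgfr_per_patient", 0)])
    # idxmin returns the first occurrence of the minimum -> stable tie-break
    idx = df.groupby("patient_id", sort=False)["mgfr_date"].idxmin()
    kept = df.loc[sorted(idx)].reset_index(drop=True)
    return cohort.with_records(
        kept, [FilterLogEntry("first_mgfr_per_patient", len(df) - len(kept))]
    )


def summarize_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Continuous and categorical summary tables for a cohort.

    Returns ``{"continuous": ..., "categorical": ...}``.  The continuous
    table reports mean, SD, min, Q1, median, Q3, max for measured GFR,
    creatinine, age, weight, height and DuBois BSA; quantiles use linear
    interpolation between order statistics and SD is the population SD
    (a single record yields SD 0).  The categorical table counts diagnosis
    groups, female patients and black patients per center with a total row.

    Raises :class:`EmptyCohortError` on an empty cohort.
    """
    df = cohort.records
    if df.empty:
        raise EmptyCohortError("cannot summarize an empty cohort")

    bsa = dubois_bsa(df["weight_kg"].to_numpy(float), df["height_cm"].to_numpy(float))
    cont_vars = {
        "gfr_ml_min": df["mgfr_ml_min"].to_numpy(float),
        "creatinine_mgdl": df["creatinine_mgdl"].to_numpy(float),
        "age_years": df["age"].to_numpy(float),
        "weight_kg": df["weight_kg"].to_numpy(float),
        "height_cm": df["height_cm"].to_numpy(float),
        "bsa_m2": np.asarray(bsa, float),
    }
    rows = []
    for name, x in cont_vars.items():
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        rows.append(
            {
                "variable": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x)),
                "min": float(np.min(x)),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(np.max(x)),
            }
        )
    continuous = pd.DataFrame(rows).set_index("variable")

    cats = []
    for center, grp in df.groupby("center", sort=True):
        cats.append(
            {
                "center": center,
                "total": len(grp),
                "solid_cancer": int((grp["diagnosis_group"] == "solid_cancer").sum()),
                "hematological_cancer": int(
                    (grp["diagnosis_group"] == "hematological_cancer").sum()
                ),
                "noncancer": int((grp["diagnosis_group"] == "noncancer").sum()),
                "female": int((grp["sex"] == Sex.FEMALE.value).sum()),
                "race_black": int(grp["race_black"].sum()),
            }
        )
    categorical = pd.DataFrame(cats).set_index("center")
    categorical.loc["Total"] = categorical.sum()
    return {"continuous": continuous, "categorical": categorical}
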