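"""Table readers/writers for the published two-file cohort layout.

``subjects.csv`` holds one row per sample (metadata, clinical scores,
lymphocyte count, cytokines); ``panels.csv`` holds the parent-relative subset
frequencies, one column per canonical subset name.  Both are comma-separated
UTF-8 with a case-sensitive header row; empty fields mean missing.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .phenotype import SUBSET_NAMES, PhenotypePanel, SchemaError, SubjectRecord
from .synthetic import SUBJECTS_COLUMNS

__all__ = [
    "read_subjects",
    "read_panels",
    "read_subjects_frame",
    "read_panels_frame",
    "panels_to_frame",
    "cohort_summary",
]

_CYTO_COLS = {
    "il6": "il6_pg_ml", "tnfa": "tnfa_pg_ml",
    "il10": "il10_pg_ml", "il8": "il8_pg_ml", "crp": "crp_mg_ml",
}


def _opt(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def read_subjects_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUBJECTS_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SUBJECTS_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"subjects table schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    for col in SUBJECTS_COLUMNS:
        if col in ("subject_id", "group", "sex"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Load subjects.csv into typed records (empty fields -> None)."""
    df = read_subjects_frame(path)
    out = []
    for _, row in df.iterrows():
        sep = _opt(row["sepsis"])
        tp = _opt(row["timepoint_day"])
        out.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            timepoint_day=None if tp is None else int(tp),
            age=_opt(row["age_years"]), sex=_opt(row["sex"]),
            iss=_opt(row["iss"]), niss=_opt(row["niss"]),
            apache2=_opt(row["apache2"]), sofa=_opt(row["sofa"]),
            saps2=_opt(row["saps2"]),
            sepsis=None if sep is None else bool(int(sep)),
            icu_los=_opt(row["icu_los_days"]),
            hospital_los=_opt(row["hospital_los_days"]),
            ventilator_days=_opt(row["ventilator_days"]),
            lymphocyte_count=_opt(row["lymphocytes_1e9_per_L"]),
            cytokines={
                k: row[c] for k, c in _CYTO_COLS.items() if _opt(row[c]) is not None
            },
        ))
    return out


def read_panels_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError("panels table lacks a subject_id column")
    unknown = [c for c in df.columns if c != "subject_id" and c not in SUBSET_NAMES]
    if unknown:
        raise SchemaError(f"unknown subset columns in panels table: {unknown}")
    return df


def read_panels(path: str | Path) -> list[PhenotypePanel]:
    """Load panels.csv into per-sample panels (empty fields -> NaN)."""
    df = read_panels_frame(path)
    freq_cols = [c for c in df.columns if c != "subject_id"]
    return [
        PhenotypePanel(str(row["subject_id"]),
                       {c: float(row[c]) for c in freq_cols})
        for _, row in df.iterrows()
    ]


def panels_to_frame(panels: list[PhenotypePanel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": p.subject_id, **p.frequencies} for p in panels]
    )


def cohort_summary(subjects: pd.DataFrame | list[SubjectRecord]) -> dict:
    """Demographics roll-up: n per arm/timepoint and the sepsis percentage.

    The sepsis fraction is computed over recruited trauma *subjects* (each
    counted once regardless of how many timepoints they contributed).
    """
    from . import stats as _stats

    if isinstance(subjects, list):
        df = pd.DataFrame([
            {"subject_id": r.subject_id, "group": r.group,
             "timepoint_day": r.timepoint_day, "sepsis": r.sepsis}
            for r in subjects
        ])
    else:
        df = subjects
    trauma = df[df["group"] == "trauma"].copy()
    trauma["person"] = trauma["subject_id"].astype(str).str.split("_").str[0]
    persons = trauma.drop_duplicates("person")
    n_trauma = len(persons)
    n_sepsis = int(persons["sepsis"].fillna(0).astype(float).astype(int).sum())
    per_tp = (
        trauma.groupby("timepoint_day")["subject_id"].count().astype(int).to_dict()
        if len(trauma) else {}
    )
    return {
        "n_controls": int((df["group"] == "HC").sum()),
        "n_trauma_subjects": n_trauma,
        "n_trauma_samples": int(len(trauma)),
        "samples_per_timepoint": {int(k): int(v) for k, v in per_tp.items()},
        "n_sepsis_subjects": n_sepsis,
        "sepsis_percent": (
            _stats.sepsis_percent(n_sepsis, n_trauma) if n_trauma else None
        ),
    }
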