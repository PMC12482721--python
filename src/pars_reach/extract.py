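"""Reading and writing the three-table EHR extract.

Schemas (CSV, UTF-8, header required):

* ``visits.csv``    — visit_id, patient_id, clinic_id, provider_id,
  service_date (ISO 8601), age_at_visit
* ``diagnoses.csv`` — visit_id, source (problem_list|encounter), code
  (dotted or undotted ICD-10-CM)
* ``referrals.csv`` — visit_id, referral_code
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "Extract", "load_extract", "write_extract",
           "VISITS_COLUMNS", "DIAGNOSES_COLUMNS", "REFERRALS_COLUMNS"]

VISITS_COLUMNS = ["visit_id", "patient_id", "clinic_id", "provider_id", "service_date", "age_at_visit"]
DIAGNOSES_COLUMNS = ["visit_id", "source", "code"]
REFERRALS_COLUMNS = ["visit_id", "referral_code"]

DX_SOURCES = ("problem_list", "encounter")


class SchemaError(ValueError):
    """An input table does not conform to the documented schema."""


@dataclass
class Extract:
    visits: pd.DataFrame
    diagnoses: pd.DataFrame
    referrals: pd.DataFrame


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def _read(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{name}: empty file {path}") from exc
    _check_columns(df, required, name)
    return df


def load_extract(directory: str | Path | None = None, *,
                 visits_path: str | Path | None = None,
                 diagnoses_path: str | Path | None = None,
                 referrals_path: str | Path | None = None) -> Extract:
    """Load the three tables from a directory (conventional filenames) or
    from explicit paths. Everything is read as text; the eligibility layer
    owns type coercion so that bad dates/ages surface as per-record
    warnings, not load failures."""
    if directory is not None:
        d = Path(directory)
        visits_path = visits_path or d / "visits.csv"
        diagnoses_path = diagnoses_path or d / "diagnoses.csv"
        referrals_path = referrals_path or d / "referrals.csv"
    if visits_path is None or diagnoses_path is None or referrals_path is None:
        raise SchemaError("load_extract needs a directory or all three table paths")
    visits = _read(visits_path, VISITS_COLUMNS, "visits")
    if visits["visit_id"].duplicated().any():
        dupes = visits.loc[visits["visit_id"].duplicated(), "visit_id"].head(5).tolist()
        raise SchemaError(f"visits: duplicate visit_id values, e.g. {dupes}")
    diagnoses = _read(diagnoses_path, DIAGNOSES_COLUMNS, "diagnoses")
    bad_src = ~diagnoses["source"].isin(DX_SOURCES)
    if bad_src.any():
        rows = (diagnoses.index[bad_src] + 2).tolist()[:5]
        raise SchemaError(f"diagnoses: invalid source values at rows {rows} (expected problem_list|encounter)")
    # duplicate (visit, code, source) rows are collapsed on load
    diagnoses = diagnoses.drop_duplicates(subset=DIAGNOSES_COLUMNS, ignore_index=True)
    referrals = _read(referrals_path, REFERRALS_COLUMNS, "referrals")
    return Extract(visits=visits, diagnoses=diagnoses, referrals=referrals)


def write_extract(extract: Extract, directory: str | Path) -> dict[str, Path]:
    """Write the three CSVs into ``directory``; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": d / "visits.csv",
        "diagnoses": d / "diagnoses.csv",
        "referrals": d / "referrals.csv",
    }
    extract.visits.to_csv(paths["visits"], index=False)
    extract.diagnoses.to_csv(paths["diagnoses"], index=False)
    extract.referrals.to_csv(paths["referrals"], index=False)
    return paths
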