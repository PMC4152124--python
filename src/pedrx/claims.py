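"""Claims-style data model: readers, validation, study-population filtering
and prescription–diagnosis linkage.

Datasets are plain pandas DataFrames bundled in :class:`ClaimsDataset`:

* patients(patient_id, birth_date, gender)
* prescriptions(rx_id, patient_id, atc_code, dispense_date)
* diagnoses(patient_id, icd_code, year, quarter)

Diagnoses carry (year, quarter) rather than a full date, mirroring the
quarterly granularity of German ambulatory claims.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from typing import Literal

GENDERS = ("male", "female")


class ClaimsValidationError(ValueError):
    """Raised when input tables violate the claims-data contract."""


class AnalysisConfig(BaseModel):
    """Analysis-wide knobs, serialised alongside every output.

    coverage_fraction
        Share of the regional child population covered by the insurance
        scheme behind the claims data; the period-prevalence denominator is
        population × coverage_fraction. Default 0.85.
    ppr_scale
        Prevalence rates are reported per this many children (default 10,000).
    inclusion_threshold_ppr
        A drug enters the analysis only if its unstratified PPR in
        ``inclusion_year`` is at least this value (default 0.1 per 10,000,
        boundary inclusive).
    linkage_window
        How diagnoses are joined to prescriptions: the billing quarter of
        the dispense date (default) or the whole calendar year.
    missing_diagnosis_policy
        What a prescription with no linked diagnosis counts as:
        ``indeterminate`` (default, reported as its own column), ``on_label``
        or ``off_label_indication``.
    """

    coverage_fraction: float = Field(default=0.85, gt=0.0, le=1.0)
    ppr_scale: float = Field(default=10_000.0, gt=0.0)
    inclusion_threshold_ppr: float = Field(default=0.1, ge=0.0)
    inclusion_year: int | None = None
    linkage_window: Literal["same_quarter", "same_year"] = "same_quarter"
    missing_diagnosis_policy: Literal[
        "indeterminate", "on_label", "off_label_indication"
    ] = "indeterminate"
    study_years: tuple[int, int] = (2004, 2008)
    max_age_years: int = 18
    random_seed: int = 0

    @model_validator(mode="after")
    def _fill_inclusion_year(self) -> "AnalysisConfig":
        if self.study_years[0] > self.study_years[1]:
            raise ValueError("study_years must be (first, last) with first <= last")
        if self.inclusion_year is None:
            object.__setattr__(self, "inclusion_year", self.study_years[1])
        return self

    @property
    def years(self) -> range:
        return range(self.study_years[0], self.study_years[1] + 1)


class PatientRecord(BaseModel):
    patient_id: str
    birth_date: dt.date
    gender: str

    @field_validator("gender")
    @classmethod
    def _check_gender(cls, v: str) -> str:
        if v not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {v!r}")
        return v


class PrescriptionEvent(BaseModel):
    rx_id: str
    patient_id: str
    atc_code: str
    dispense_date: dt.date


class DiagnosisEvent(BaseModel):
    patient_id: str
    icd_code: str
    year: int
    quarter: int = Field(ge=1, le=4)


@dataclass
class ClaimsDataset:
    """The three claims tables, referentially consistent."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame

    def __post_init__(self) -> None:
        validate_dataset(self)


def validate_dataset(ds: ClaimsDataset) -> None:
    pat = ds.patients
    if pat["patient_id"].duplicated().any():
        dupes = pat.loc[pat["patient_id"].duplicated(), "patient_id"].tolist()
        raise ClaimsValidationError(f"duplicate patient_id(s): {dupes[:5]}")
    if ds.prescriptions["rx_id"].duplicated().any():
        dupes = ds.prescriptions.loc[
            ds.prescriptions["rx_id"].duplicated(), "rx_id"
        ].tolist()
        raise ClaimsValidationError(f"duplicate rx_id(s): {dupes[:5]}")
    known = set(pat["patient_id"])
    orphan_rx = ds.prescriptions.loc[
        ~ds.prescriptions["patient_id"].isin(known), "rx_id"
    ]
    if len(orphan_rx):
        raise ClaimsValidationError(
            f"prescriptions reference unknown patients: rx_id(s) {orphan_rx.tolist()[:5]}"
        )
    orphan_dx = ds.diagnoses.loc[~ds.diagnoses["patient_id"].isin(known)]
    if len(orphan_dx):
        raise ClaimsValidationError(
            f"diagnoses reference unknown patients: {orphan_dx['patient_id'].tolist()[:5]}"
        )
    bad_q = ds.diagnoses.loc[~ds.diagnoses["quarter"].isin([1, 2, 3, 4])]
    if len(bad_q):
        raise ClaimsValidationError(f"quarter outside 1-4 in diagnoses rows {bad_q.index.tolist()[:5]}")


def _read_csv_dates(path: Path, date_cols: list[str], dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=dtypes)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ClaimsValidationError(f"{path}: {exc}") from exc
    for col in date_cols:
        try:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d").dt.date
        except (ValueError, KeyError) as exc:
            raise ClaimsValidationError(f"{path}: column {col!r}: {exc}") from exc
    return df


def read_claims(
    patients_path: str | Path,
    prescriptions_path: str | Path,
    diagnoses_path: str | Path,
) -> ClaimsDataset:
    """Read and validate the three claims tables (CSV, ISO-8601 dates)."""
    patients = _read_csv_dates(
        Path(patients_path), ["birth_date"], {"patient_id": str, "gender": str}
    )
    prescriptions = _read_csv_dates(
        Path(prescriptions_path),
        ["dispense_date"],
        {"rx_id": str, "patient_id": str, "atc_code": str},
    )
    diagnoses = _read_csv_dates(
        Path(diagnoses_path), [], {"patient_id": str, "icd_code": str}
    )
    if len(diagnoses) == 0 and "icd_code" not in diagnoses.columns:
        diagnoses = pd.DataFrame(columns=["patient_id", "icd_code", "year", "quarter"])
    bad_gender = patients.loc[~patients["gender"].isin(GENDERS)]
    if len(bad_gender):
        raise ClaimsValidationError(
            f"invalid gender values: {bad_gender['gender'].unique().tolist()}"
        )
    ds = ClaimsDataset(patients, prescriptions, diagnoses)
    return ds


def write_claims(ds: ClaimsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables back to CSV; inverse of :func:`read_claims`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "prescriptions": out / "prescriptions.csv",
        "diagnoses": out / "diagnoses.csv",
    }
    ds.patients.to_csv(paths["patients"], index=False)
    ds.prescriptions.to_csv(paths["prescriptions"], index=False)
    ds.diagnoses.to_csv(paths["diagnoses"], index=False)
    return paths


def read_population(path: str | Path) -> pd.DataFrame:
    """Read the year-end population table (year, age_years, gender, count)."""
    df = pd.read_csv(path, dtype={"gender": str})
    required = {"year", "age_years", "gender", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ClaimsValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(["year", "age_years", "gender"]).any():
        raise ClaimsValidationError(f"{path}: duplicate (year, age, gender) rows")
    return df


def compute_age(birth_date: dt.date, reference_date: dt.date) -> int:
    """Completed years of age at ``reference_date`` (birthday-adjusted)."""
    if reference_date < birth_date:
        raise ValueError(f"reference date {reference_date} before birth {birth_date}")
    age = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (birth_date.month, birth_date.day):
        age -= 1
    return age


def _ages_at(birth_dates: pd.Series, reference: pd.Series | dt.date) -> pd.Series:
    """Vectorised completed-years age; ``reference`` a date or aligned Series."""
    bd = pd.to_datetime(birth_dates)
    ref = pd.to_datetime(reference) if not isinstance(reference, pd.Series) else pd.to_datetime(reference)
    if isinstance(ref, pd.Timestamp):
        ref = pd.Series(ref, index=bd.index)
    age = ref.dt.year - bd.dt.year
    before_birthday = (ref.dt.month * 100 + ref.dt.day) < (bd.dt.month * 100 + bd.dt.day)
    return (age - before_birthday.astype(int)).astype(int)


def filter_study_population(ds: ClaimsDataset, config: AnalysisConfig) -> ClaimsDataset:
    """Keep prescriptions dispensed within the study years to children at
    most ``max_age_years`` old at dispense; keep diagnoses of retained
    patients; drop patients with no retained prescription."""
    rx = ds.prescriptions.merge(
        ds.patients[["patient_id", "birth_date"]], on="patient_id", how="left"
    )
    years = pd.to_datetime(rx["dispense_date"]).dt.year
    in_window = years.between(*config.study_years)
    age_ok = _ages_at(rx["birth_date"], rx["dispense_date"]) <= config.max_age_years
    kept_rx = ds.prescriptions.loc[(in_window & age_ok).to_numpy()].reset_index(drop=True)
    kept_ids = set(kept_rx["patient_id"])
    return ClaimsDataset(
        patients=ds.patients.loc[ds.patients["patient_id"].isin(kept_ids)].reset_index(drop=True),
        prescriptions=kept_rx,
        diagnoses=ds.diagnoses.loc[ds.diagnoses["patient_id"].isin(kept_ids)].reset_index(drop=True),
    )


def quarter_of(date: dt.date) -> int:
    return (date.month - 1) // 3 + 1


def link_diagnoses(
    rx: PrescriptionEvent | pd.Series,
    diagnoses: pd.DataFrame,
    window: str = "same_quarter",
) -> set[str]:
    """ICD codes of the prescription's patient documented in the linkage
    window (dispense quarter or dispense year)."""
    if isinstance(rx, PrescriptionEvent):
        patient_id, date = rx.patient_id, rx.dispense_date
    else:
        patient_id, date = rx["patient_id"], rx["dispense_date"]
    mask = (diagnoses["patient_id"] == patient_id) & (diagnoses["year"] == date.year)
    if window == "same_quarter":
        mask &= diagnoses["quarter"] == quarter_of(date)
    elif window != "same_year":
        raise ValueError(f"unknown linkage window {window!r}")
    return set(diagnoses.loc[mask, "icd_code"])
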