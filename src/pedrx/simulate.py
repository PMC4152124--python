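"""Synthetic claims generator with known ground truth.

Emulates a statutory-insurance paediatric cohort: children aged 0–18,
quarterly diagnosis coding, pharmacy-dispensed prescriptions for respiratory
compounds. Each drug block specifies an annual prescription rate per child
(Poisson counts), a diagnosis mixture over ICD-10 codes, and a
missing-diagnosis probability; the mixture component that fired for each
prescription is recorded in a sidecar truth table so downstream classifiers
can be validated against exact ground truth.

Ages are anchored at December 31 of the last simulated year, so children
with anchor age below the study span are born mid-study (a dynamic cohort)
and nobody ages past the paediatric limit. The emitted population table is
the realised year-end head count divided by the insurance coverage fraction,
which makes prevalence denominators internally consistent with the cohort.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .claims import ClaimsDataset, quarter_of

_POP_STREAM = 11
_DRUG_STREAM = 1009  # per-drug child seeds: seed + _DRUG_STREAM * (index + 1)


class DrugScenario(BaseModel):
    """Prescribing model for one compound."""

    model_config = {"frozen": True}

    atc_code: str
    annual_rx_rate_per_child: float = Field(ge=0.0)
    dx_mixture: tuple[tuple[str, float], ...]
    p_missing_dx: float = Field(ge=0.0, le=1.0, default=0.0)
    co_diagnosis_rate: float = Field(ge=0.0, le=1.0, default=0.0)

    @model_validator(mode="after")
    def _check_mixture(self) -> "DrugScenario":
        total = sum(p for _, p in self.dx_mixture) + self.p_missing_dx
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.atc_code}: dx_mixture probabilities + p_missing_dx must sum to 1, got {total}"
            )
        return self


class SimulationScenario(BaseModel):
    """Cohort-level simulation settings."""

    model_config = {"frozen": True}

    n_patients: int = Field(gt=0)
    age_weights: tuple[float, ...] = tuple([1.0] * 19)
    gender_split: float = Field(ge=0.0, le=1.0, default=0.51)  # fraction male
    drugs: tuple[DrugScenario, ...]
    years: tuple[int, int] = (2004, 2008)
    seed: int = 0

    @field_validator("age_weights")
    @classmethod
    def _check_weights(cls, v):
        if len(v) != 19:
            raise ValueError("age_weights must have 19 entries (ages 0-18)")
        if any(w < 0 for w in v) or sum(v) <= 0:
            raise ValueError("age_weights must be non-negative with positive sum")
        return v

    @model_validator(mode="after")
    def _check_years(self) -> "SimulationScenario":
        if self.years[0] > self.years[1]:
            raise ValueError("years must be (first, last)")
        return self


def default_scenario(n_patients: int = 8000, seed: int = 0) -> SimulationScenario:
    """A four-drug scenario spanning the label-rule space: an unrestricted
    broad-indication inhaled SABA, an age-restricted SABA, a narrow
    adults-only LAMA, and an oral fixed combination."""
    return SimulationScenario(
        n_patients=n_patients,
        seed=seed,
        drugs=(
            DrugScenario(
                atc_code="R03AC02",
                annual_rx_rate_per_child=0.30,
                dx_mixture=(("J45.9", 0.50), ("J20.9", 0.25), ("J06.9", 0.15)),
                p_missing_dx=0.10,
            ),
            DrugScenario(
                atc_code="R03AC04",
                annual_rx_rate_per_child=0.02,
                dx_mixture=(("J45.9", 0.70), ("J20.9", 0.20)),
                p_missing_dx=0.10,
            ),
            DrugScenario(
                atc_code="R03BB04",
                annual_rx_rate_per_child=0.001,
                dx_mixture=(("J44.9", 0.50), ("J45.9", 0.40)),
                p_missing_dx=0.10,
            ),
            DrugScenario(
                atc_code="R03CC63",
                annual_rx_rate_per_child=0.25,
                dx_mixture=(("J20.9", 0.35), ("J06.9", 0.40), ("J00", 0.05)),
                p_missing_dx=0.20,
                co_diagnosis_rate=0.10,
            ),
        ),
    )


def generate_population(
    scenario: SimulationScenario, coverage_fraction: float = 0.85
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample the patient cohort and derive the year-end population table.

    Returns (patients, population). Population counts are the realised
    cohort head count per (year, age, gender) divided by
    ``coverage_fraction`` and rounded, i.e. the notional total regional
    population of which the cohort is the insured share.
    """
    rng = np.random.default_rng(scenario.seed + _POP_STREAM)
    n = scenario.n_patients
    weights = np.asarray(scenario.age_weights, dtype=float)
    weights = weights / weights.sum()
    anchor_year = scenario.years[1]

    anchor_age = rng.choice(19, size=n, p=weights)
    male = rng.random(n) < scenario.gender_split
    birth_year = anchor_year - anchor_age
    birth_doy = rng.integers(0, 365, size=n)  # day within birth year

    birth_dates = [
        dt.date(int(by), 1, 1) + dt.timedelta(days=int(d))
        for by, d in zip(birth_year, birth_doy)
    ]
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "birth_date": birth_dates,
            "gender": np.where(male, "male", "female"),
        }
    )

    rows = []
    for year in range(scenario.years[0], scenario.years[1] + 1):
        age_at_year_end = year - birth_year  # birthday always passed by Dec 31
        for age in range(19):
            in_stratum = age_at_year_end == age
            for gender, gmask in (("male", male), ("female", ~male)):
                realized = int(np.sum(in_stratum & gmask))
                rows.append(
                    {
                        "year": year,
                        "age_years": age,
                        "gender": gender,
                        "count": int(round(realized / coverage_fraction)),
                    }
                )
    return patients, pd.DataFrame(rows)


def generate_claims(
    scenario: SimulationScenario, patients: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate prescriptions and quarterly diagnoses for the cohort.

    Returns (prescriptions, diagnoses, truth). The truth table has one row
    per prescription recording which diagnosis-mixture component fired
    (empty string when the diagnosis is missing) and any co-diagnosis drawn.
    """
    birth = pd.to_datetime(patients["birth_date"])
    birth_year = birth.dt.year.to_numpy()
    birth_doy = (birth.dt.dayofyear - 1).to_numpy()
    pid = patients["patient_id"].to_numpy()
    years = np.arange(scenario.years[0], scenario.years[1] + 1)

    rx_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    rx_counter = 0

    for d_idx, drug in enumerate(scenario.drugs):
        rng = np.random.default_rng(scenario.seed + _DRUG_STREAM * (d_idx + 1))
        icds = [c for c, _ in drug.dx_mixture]
        probs = np.array([p for _, p in drug.dx_mixture] + [drug.p_missing_dx])
        probs = probs / probs.sum()
        for year in years:
            alive = birth_year <= year
            counts = rng.poisson(drug.annual_rx_rate_per_child * alive)
            total = int(counts.sum())
            if total == 0:
                continue
            owner = np.repeat(np.arange(len(pid)), counts)
            # dispense day uniform within the year, at or after birth for newborns
            lo = np.where(birth_year[owner] == year, birth_doy[owner], 0)
            n_days = 366 if dt.date(int(year), 12, 31).timetuple().tm_yday == 366 else 365
            day = lo + rng.integers(0, np.maximum(n_days - lo, 1))
            comp = rng.choice(len(probs), size=total, p=probs)
            co = (
                rng.random(total) < drug.co_diagnosis_rate
                if drug.co_diagnosis_rate > 0
                else np.zeros(total, dtype=bool)
            )
            mix_p = probs[:-1] / probs[:-1].sum() if len(icds) else None
            co_comp = (
                rng.choice(len(icds), size=total, p=mix_p)
                if (drug.co_diagnosis_rate > 0 and icds)
                else np.zeros(total, dtype=int)
            )
            for k in range(total):
                date = dt.date(int(year), 1, 1) + dt.timedelta(days=int(day[k]))
                rx_id = f"RX{rx_counter:08d}"
                rx_counter += 1
                p = pid[owner[k]]
                rx_rows.append((rx_id, p, drug.atc_code, date.isoformat()))
                true_icd = icds[comp[k]] if comp[k] < len(icds) else ""
                co_icd = ""
                if true_icd:
                    dx_rows.append((p, true_icd, int(year), quarter_of(date)))
                    if co[k]:
                        co_icd = icds[int(co_comp[k])]
                        dx_rows.append((p, co_icd, int(year), quarter_of(date)))
                truth_rows.append((rx_id, p, drug.atc_code, int(year), true_icd, co_icd))

    prescriptions = pd.DataFrame(
        rx_rows, columns=["rx_id", "patient_id", "atc_code", "dispense_date"]
    )
    prescriptions["dispense_date"] = pd.to_datetime(prescriptions["dispense_date"]).dt.date
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "icd_code", "year", "quarter"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["rx_id", "patient_id", "atc_code", "year", "true_icd", "co_icd"],
    )
    return prescriptions, diagnoses, truth


def generate_dataset(
    scenario: SimulationScenario, coverage_fraction: float = 0.85
) -> tuple[ClaimsDataset, pd.DataFrame, pd.DataFrame]:
    """Full simulation: (claims dataset, population table, truth sidecar)."""
    patients, population = generate_population(scenario, coverage_fraction)
    prescriptions, diagnoses, truth = generate_claims(scenario, patients)
    if len(prescriptions) == 0:
        prescriptions = pd.DataFrame(
            columns=["rx_id", "patient_id", "atc_code", "dispense_date"]
        )
    if len(diagnoses) == 0:
        diagnoses = pd.DataFrame(columns=["patient_id", "icd_code", "year", "quarter"])
    return ClaimsDataset(patients, prescriptions, diagnoses), population, truth
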