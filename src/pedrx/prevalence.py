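"""Period prevalence rates with insurance-coverage correction.

The annual period prevalence rate (PPR) of a drug is the number of distinct
children with at least one prescription of it during the year, divided by
the year-end child population corrected for the insured share
(population × coverage_fraction), scaled per 10,000 children by default.
Stratum age is completed years at December 31 of the analysis year, matching
the year-end population denominator; this deliberately differs from the
dispense-date age used by the off-label classifier.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .claims import AnalysisConfig, ClaimsDataset, _ages_at


class PrevalenceError(ValueError):
    """Raised when a requested population stratum is missing."""


def _stratum_population(
    population: pd.DataFrame,
    year: int,
    age: int | None,
    gender: str | None,
    max_age: int,
) -> int:
    sub = population.loc[population["year"] == year]
    if age is not None:
        sub = sub.loc[sub["age_years"] == age]
    else:
        sub = sub.loc[sub["age_years"] <= max_age]
    if gender is not None:
        sub = sub.loc[sub["gender"] == gender]
    if len(sub) == 0:
        raise PrevalenceError(
            f"no population rows for (year={year}, age={'ALL' if age is None else age}, "
            f"gender={gender or 'ALL'})"
        )
    return int(sub["count"].sum())


def period_prevalence(
    ds: ClaimsDataset,
    population: pd.DataFrame,
    atc_code: str,
    year: int,
    strata: Sequence[str] = (),
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """PPR rows for one drug and year, optionally stratified.

    ``strata`` is a subset of {"age", "gender"}; an empty sequence gives the
    single unstratified row. Users whose year-end age exceeds
    ``max_age_years`` are excluded from the numerator (they are outside the
    paediatric year-end denominator population).
    """
    config = config or AnalysisConfig()
    if not set(strata) <= {"age", "gender"}:
        raise ValueError(f"strata must be within {{'age', 'gender'}}, got {strata!r}")
    rx = ds.prescriptions
    sub = rx.loc[
        (rx["atc_code"] == atc_code)
        & (pd.to_datetime(rx["dispense_date"]).dt.year == year)
    ]
    users = (
        sub[["patient_id"]]
        .drop_duplicates()
        .merge(ds.patients[["patient_id", "birth_date", "gender"]], on="patient_id")
    )
    if len(users):
        users = users.assign(
            age_years=_ages_at(users["birth_date"], dt.date(year, 12, 31))
        )
        users = users.loc[
            (users["age_years"] >= 0) & (users["age_years"] <= config.max_age_years)
        ]

    age_levels: list[int | None] = (
        sorted(
            population.loc[
                (population["year"] == year)
                & (population["age_years"] <= config.max_age_years),
                "age_years",
            ].unique()
        )
        if "age" in strata
        else [None]
    )
    gender_levels: list[str | None] = (
        sorted(population.loc[population["year"] == year, "gender"].unique())
        if "gender" in strata
        else [None]
    )
    if "age" in strata and not age_levels:
        raise PrevalenceError(f"no population rows for year {year}")

    rows = []
    for age in age_levels:
        for gender in gender_levels:
            n_users = len(users)
            if len(users):
                mask = pd.Series(True, index=users.index)
                if age is not None:
                    mask &= users["age_years"] == age
                if gender is not None:
                    mask &= users["gender"] == gender
                n_users = int(mask.sum())
            pop = _stratum_population(population, year, age, gender, config.max_age_years)
            denom = pop * config.coverage_fraction
            ppr = config.ppr_scale * n_users / denom if n_users else 0.0
            if n_users and denom == 0:
                raise PrevalenceError(
                    f"stratum (year={year}, age={age}, gender={gender}) has users but zero population"
                )
            rows.append(
                {
                    "atc_code": atc_code,
                    "year": year,
                    "age_years": "ALL" if age is None else age,
                    "gender": gender or "ALL",
                    "n_users": n_users,
                    "population": pop,
                    "corrected_denominator": denom,
                    "ppr": ppr,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PPRChange:
    """PPR change between two years; relative and fold measures are None
    (n.a.) on a zero baseline."""

    absolute: float
    relative_pct: float | None
    fold: float | None


def ppr_change(ppr_a: float, ppr_b: float) -> PPRChange:
    if ppr_a < 0 or ppr_b < 0:
        raise ValueError("PPRs must be non-negative")
    absolute = ppr_b - ppr_a
    if ppr_a == 0:
        return PPRChange(absolute=absolute, relative_pct=None, fold=None)
    return PPRChange(
        absolute=absolute,
        relative_pct=100.0 * absolute / ppr_a,
        fold=ppr_b / ppr_a,
    )


def drug_inclusion_filter(
    ppr_rows: pd.DataFrame, config: AnalysisConfig | None = None
) -> set[str]:
    """ATC codes whose unstratified PPR meets the inclusion threshold
    (boundary inclusive)."""
    config = config or AnalysisConfig()
    if len(ppr_rows) == 0:
        return set()
    sub = ppr_rows
    if "age_years" in sub.columns:
        sub = sub.loc[(sub["age_years"] == "ALL") & (sub["gender"] == "ALL")]
    return set(sub.loc[sub["ppr"] >= config.inclusion_threshold_ppr, "atc_code"])
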