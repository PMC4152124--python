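"""Off-label classification of prescriptions and Table-style aggregation.

A prescription is checked against its compound's effective label on two
axes:

* **age** — the child's completed age at the dispense date must be at least
  the label's minimum age;
* **indication** — at least one diagnosis documented in the linkage window
  (billing quarter by default) must match an approved indication prefix.

The any-match convention on indications means a prescription is off-label by
indication only when *every* linked diagnosis is non-approved. Prescriptions
with no linked diagnosis are governed by the missing-diagnosis policy
(default: a separate INDETERMINATE bucket).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .claims import AnalysisConfig, ClaimsDataset, ClaimsValidationError, _ages_at, quarter_of
from .labels import DiagnosisCategoryMap, EffectiveLabel, match_icd


class OffLabelStatus(str, enum.Enum):
    ON_LABEL = "on_label"
    OFF_AGE = "off_age"
    OFF_INDICATION = "off_indication"
    OFF_AGE_AND_INDICATION = "off_age_and_indication"
    INDETERMINATE = "indeterminate"


OFFLABEL_STATUSES = (
    OffLabelStatus.OFF_AGE,
    OffLabelStatus.OFF_INDICATION,
    OffLabelStatus.OFF_AGE_AND_INDICATION,
)
# statuses entering the indication-breakdown denominator
INDICATION_OFFLABEL = (
    OffLabelStatus.OFF_INDICATION,
    OffLabelStatus.OFF_AGE_AND_INDICATION,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_prescription(
    age_at_dispense: int,
    linked_codes: Iterable[str],
    label: EffectiveLabel,
    policy: str = "indeterminate",
) -> OffLabelStatus:
    """Classify one prescription against an effective label."""
    codes = set(linked_codes)
    age_ok = age_at_dispense >= label.min_age_years
    if not codes:
        if policy == "indeterminate":
            return OffLabelStatus.INDETERMINATE
        if policy == "on_label":
            ind_ok = True
        elif policy == "off_label_indication":
            ind_ok = False
        else:
            raise ValueError(f"unknown missing-diagnosis policy {policy!r}")
    else:
        ind_ok = any(match_icd(c, label.indication_codes) for c in codes)
    if age_ok and ind_ok:
        return OffLabelStatus.ON_LABEL
    if not age_ok and ind_ok:
        return OffLabelStatus.OFF_AGE
    if age_ok:
        return OffLabelStatus.OFF_INDICATION
    return OffLabelStatus.OFF_AGE_AND_INDICATION


def classify_claims(
    ds: ClaimsDataset,
    labels: Mapping[str, EffectiveLabel],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Classify every prescription in the dataset.

    Returns one row per prescription: rx_id, patient_id, atc_code,
    compound_name, compound_class, year, age_at_dispense, linked_codes and
    offlabel_codes (semicolon-joined, sorted), status.
    """
    config = config or AnalysisConfig()
    rx = ds.prescriptions
    unknown = sorted(set(rx["atc_code"]) - set(labels))
    if unknown:
        raise ClaimsValidationError(f"ATC codes not in the label KB: {unknown}")
    if len(rx) == 0:
        return pd.DataFrame(
            columns=[
                "rx_id", "patient_id", "atc_code", "compound_name", "compound_class",
                "year", "age_at_dispense", "linked_codes", "offlabel_codes", "status",
            ]
        )

    merged = rx.merge(ds.patients[["patient_id", "birth_date"]], on="patient_id")
    ages = _ages_at(merged["birth_date"], merged["dispense_date"]).to_numpy()
    dates = merged["dispense_date"].tolist()

    # diagnosis lookup keyed per the linkage window
    by_quarter: dict[tuple, set[str]] = {}
    for p, icd, y, q in ds.diagnoses[["patient_id", "icd_code", "year", "quarter"]].itertuples(index=False):
        key = (p, int(y)) if config.linkage_window == "same_year" else (p, int(y), int(q))
        by_quarter.setdefault(key, set()).add(icd)

    rows = []
    for i, (rx_id, patient_id, atc) in enumerate(
        merged[["rx_id", "patient_id", "atc_code"]].itertuples(index=False)
    ):
        date = dates[i]
        key = (
            (patient_id, date.year)
            if config.linkage_window == "same_year"
            else (patient_id, date.year, quarter_of(date))
        )
        linked = by_quarter.get(key, set())
        label = labels[atc]
        status = classify_prescription(
            int(ages[i]), linked, label, config.missing_diagnosis_policy
        )
        offlabel = sorted(c for c in linked if not match_icd(c, label.indication_codes))
        rows.append(
            (
                rx_id, patient_id, atc, label.compound_name, label.compound_class,
                date.year, int(ages[i]), ";".join(sorted(linked)),
                ";".join(offlabel), status.value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rx_id", "patient_id", "atc_code", "compound_name", "compound_class",
            "year", "age_at_dispense", "linked_codes", "offlabel_codes", "status",
        ],
    )


def summarize_counts(
    n_all: int,
    n_age_only: int,
    n_indication_only: int,
    n_age_and_indication: int,
    n_indeterminate: int = 0,
) -> dict:
    """Off-label partition arithmetic for one group of prescriptions."""
    n_off = n_age_only + n_indication_only + n_age_and_indication
    if n_off + n_indeterminate > n_all:
        raise ValueError("off-label + indeterminate counts exceed n_all")
    return {
        "n_all": n_all,
        "n_offlabel_overall": n_off,
        "pct_offlabel": 100.0 * n_off / n_all if n_all else 0.0,
        "n_age_only": n_age_only,
        "n_indication_only": n_indication_only,
        "n_age_and_indication": n_age_and_indication,
        "n_indeterminate": n_indeterminate,
    }


_GROUP_COLS = {"compound": "atc_code", "class": "compound_class"}


def summarize_offlabel(
    classified: pd.DataFrame, grouping: str = "compound"
) -> pd.DataFrame:
    """Aggregate classified prescriptions into off-label summary rows.

    ``grouping``: "compound" (per ATC code), "class" (per compound class) or
    "total". A grand-total row labelled TOTAL is always appended. The
    partition identity n_all = on + off_age + off_ind + off_both +
    indeterminate holds on every row by construction.
    """

    def _one(group_label: str, sub: pd.DataFrame) -> dict:
        counts = sub["status"].value_counts()
        row = summarize_counts(
            n_all=len(sub),
            n_age_only=int(counts.get(OffLabelStatus.OFF_AGE.value, 0)),
            n_indication_only=int(counts.get(OffLabelStatus.OFF_INDICATION.value, 0)),
            n_age_and_indication=int(
                counts.get(OffLabelStatus.OFF_AGE_AND_INDICATION.value, 0)
            ),
            n_indeterminate=int(counts.get(OffLabelStatus.INDETERMINATE.value, 0)),
        )
        return {"group": group_label, **row}

    rows = []
    if grouping != "total":
        col = _GROUP_COLS.get(grouping)
        if col is None:
            raise ValueError(f"unknown grouping {grouping!r}")
        for key in sorted(classified[col].unique()):
            rows.append(_one(str(key), classified.loc[classified[col] == key]))
    rows.append(_one("TOTAL", classified))
    return pd.DataFrame(
        rows,
        columns=[
            "group", "n_all", "n_offlabel_overall", "pct_offlabel",
            "n_age_only", "n_indication_only", "n_age_and_indication", "n_indeterminate",
        ],
    )


def breakdown_offlabel_indications(
    classified: pd.DataFrame,
    category_map: DiagnosisCategoryMap,
    top_k: int = 3,
    min_n: int = 0,
) -> pd.DataFrame:
    """Per-compound off-label indication categories with multiple counting.

    The denominator per compound is the number of prescriptions off-label
    due to indication or to age&indication with at least one linked
    diagnosis; every off-label code on each such prescription increments its
    category, so percentages may sum above 100. Rows are sorted by count
    descending and truncated to ``top_k`` per compound. Compounds with fewer
    than ``min_n`` total prescriptions are dropped.
    """
    off = classified.loc[
        classified["status"].isin([s.value for s in INDICATION_OFFLABEL])
        & (classified["linked_codes"] != "")
    ]
    rows = []
    for atc in sorted(classified["atc_code"].unique()):
        n_total = int((classified["atc_code"] == atc).sum())
        if n_total < min_n:
            continue
        sub = off.loc[off["atc_code"] == atc]
        denom = len(sub)
        if denom == 0:
            continue
        counts: dict[str, int] = {}
        for codes in sub["offlabel_codes"]:
            for code in codes.split(";"):
                if code:
                    cat = category_map.categorize(code)
                    counts[cat] = counts.get(cat, 0) + 1
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        name = sub["compound_name"].iloc[0]
        for cat, n in ordered:
            rows.append(
                {
                    "atc_code": atc,
                    "compound_name": name,
                    "category_label": cat,
                    "n_category": n,
                    "n_offlabel_indication": denom,
                    "pct_of_offlabel": 100.0 * n / denom,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "atc_code", "compound_name", "category_label", "n_category",
            "n_offlabel_indication", "pct_of_offlabel",
        ],
    )


@dataclass(frozen=True)
class TrendResult:
    """Change in a count between two years; relative change is undefined
    (None, reported as n.a.) when the baseline is zero."""

    absolute: int
    relative_pct: float | None


def offlabel_trend(n_year_a: int, n_year_b: int) -> TrendResult:
    """Absolute and relative change in an off-label prescription count."""
    if n_year_a < 0 or n_year_b < 0:
        raise ValueError("counts must be non-negative")
    absolute = n_year_b - n_year_a
    relative = 100.0 * absolute / n_year_a if n_year_a > 0 else None
    return TrendResult(absolute=absolute, relative_pct=relative)


def trend_table(classified: pd.DataFrame, year_a: int, year_b: int) -> pd.DataFrame:
    """Per-compound off-label counts in two years with trend deltas."""
    rows = []
    for atc in sorted(classified["atc_code"].unique()):
        sub = classified.loc[classified["atc_code"] == atc]
        off = sub.loc[sub["status"].isin([s.value for s in OFFLABEL_STATUSES])]
        n_a = int((off["year"] == year_a).sum())
        n_b = int((off["year"] == year_b).sum())
        t = offlabel_trend(n_a, n_b)
        rows.append(
            {
                "atc_code": atc,
                "year_a": year_a,
                "year_b": year_b,
                "n_offlabel_a": n_a,
                "n_offlabel_b": n_b,
                "absolute_change": t.absolute,
                "relative_change_pct": t.relative_pct if t.relative_pct is not None else "n.a.",
            }
        )
    return pd.DataFrame(rows)
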