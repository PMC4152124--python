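"""Drug-label knowledge base: age restrictions, approved indications, and
the diagnosis-category map used for reporting.

The knowledge base encodes, for each respiratory compound (7-character ATC
code), the lowest approved age and the set of approved indications expressed
as ICD-10-GM code *prefixes* (block-level semantics: the prefix ``J45``
covers every terminal asthma code ``J45.x``). Labels may exist in several
versions (different market years, different devices); ``resolve_effective_label``
collapses them with the lowest age restriction and the widest (union)
indication set, which is the permissive convention used when a compound is
marketed under more than one summary of product characteristics.
"""

from __future__ import annotations

import csv
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
# lexical shape of an ICD-10 code after normalisation: letter, two digits,
# optional further alphanumerics (ICD-10-GM terminal codes go to 5 chars)
ICD_CODE_PATTERN = re.compile(r"^[A-Z]\d{2}[0-9A-Z]{0,3}$")

COMPOUND_CLASSES = frozenset(
    {
        "inhaled_saba",
        "inhaled_saba_combination",
        "inhaled_laba",
        "inhaled_laba_ics",
        "sama",
        "lama",
        "ics",
        "oral_b2a",
        "oral_b2a_combination",
        "other",
    }
)


class LabelKBError(ValueError):
    """Raised when the label knowledge base fails validation."""


def normalize_icd(code: str) -> str:
    """Normalise an ICD-10 code or prefix: uppercase, dots and spaces removed."""
    return code.replace(".", "").replace(" ", "").strip().upper()


class LabelRecord(BaseModel):
    """One label snapshot for one compound.

    ``min_age_years == 0`` encodes "no age restriction".
    """

    model_config = {"frozen": True}

    atc_code: str
    compound_name: str
    compound_class: str
    min_age_years: int = Field(ge=0, le=18)
    indication_codes: frozenset[str]
    source_year: int
    device_or_product_note: str | None = None

    @field_validator("atc_code")
    @classmethod
    def _check_atc(cls, v: str) -> str:
        v = v.strip().upper()
        if not ATC_PATTERN.match(v):
            raise ValueError(f"malformed ATC code: {v!r}")
        return v

    @field_validator("compound_class")
    @classmethod
    def _check_class(cls, v: str) -> str:
        if v not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class: {v!r}")
        return v

    @field_validator("indication_codes", mode="before")
    @classmethod
    def _normalize_indications(cls, v) -> frozenset[str]:
        codes = frozenset(normalize_icd(c) for c in v if str(c).strip())
        if not codes:
            raise ValueError("indication_codes must be non-empty")
        return codes


class EffectiveLabel(BaseModel):
    """A compound's label after multi-record resolution (lowest age, widest
    indications)."""

    model_config = {"frozen": True}

    atc_code: str
    compound_name: str
    compound_class: str
    min_age_years: int
    indication_codes: frozenset[str]
    n_source_records: int = 1


def resolve_effective_label(
    records: Sequence[LabelRecord | EffectiveLabel],
) -> EffectiveLabel:
    """Collapse all label records for one ATC code into the effective label.

    Takes the minimum age restriction and the union of indication sets, the
    permissive reading applied when several label versions coexist.
    """
    if not records:
        raise LabelKBError("cannot resolve an empty record collection")
    atcs = {r.atc_code for r in records}
    if len(atcs) != 1:
        raise LabelKBError(f"records mix ATC codes: {sorted(atcs)}")
    indications: frozenset[str] = frozenset().union(
        *(r.indication_codes for r in records)
    )
    return EffectiveLabel(
        atc_code=records[0].atc_code,
        compound_name=records[0].compound_name,
        compound_class=records[0].compound_class,
        min_age_years=min(r.min_age_years for r in records),
        indication_codes=indications,
        n_source_records=sum(getattr(r, "n_source_records", 1) for r in records),
    )


def build_effective_labels(
    records: Iterable[LabelRecord],
) -> dict[str, EffectiveLabel]:
    """Resolve every ATC code in ``records`` to its effective label."""
    by_atc: dict[str, list[LabelRecord]] = {}
    for rec in records:
        by_atc.setdefault(rec.atc_code, []).append(rec)
    return {atc: resolve_effective_label(recs) for atc, recs in by_atc.items()}


def match_icd(code: str, prefixes: Iterable[str]) -> bool:
    """True iff the normalised code starts with any normalised prefix.

    Codes that do not look like ICD-10 after normalisation are logged and
    never match.
    """
    norm = normalize_icd(code)
    if not ICD_CODE_PATTERN.match(norm):
        logger.warning("code %r fails the ICD-10 lexical pattern; treated as no match", code)
        return False
    return any(norm.startswith(normalize_icd(p)) for p in prefixes)


class DiagnosisCategoryMap(BaseModel):
    """Ordered ICD-prefix → reporting-category grouper; first match wins.

    Prefix strings must be pairwise distinct across categories; nested
    prefixes (a broad catch-all after specific blocks) are resolved by order.
    """

    model_config = {"frozen": True}

    categories: tuple[tuple[str, frozenset[str]], ...]
    fallback_label: str = "Non-respiratory diseases"

    @field_validator("categories", mode="before")
    @classmethod
    def _normalize(cls, v):
        out = []
        seen: set[str] = set()
        for label, prefixes in v:
            norm = frozenset(normalize_icd(p) for p in prefixes)
            dup = norm & seen
            if dup:
                raise ValueError(f"prefixes {sorted(dup)} appear in more than one category")
            seen |= norm
            out.append((label, norm))
        return tuple(out)

    def categorize(self, code: str) -> str:
        norm = normalize_icd(code)
        for label, prefixes in self.categories:
            if any(norm.startswith(p) for p in prefixes):
                return label
        return self.fallback_label


def categorize_diagnosis(code: str, category_map: DiagnosisCategoryMap) -> str:
    """First-match category label for ``code``, or the map's fallback."""
    return category_map.categorize(code)


def load_label_kb(path: str | Path) -> list[LabelRecord]:
    """Read a label knowledge base CSV into validated records.

    Columns: atc_code, compound_name, compound_class, min_age_years,
    indication_prefixes (semicolon-separated), source_year,
    device_or_product_note.
    """
    path = Path(path)
    records: list[LabelRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LabelKBError(f"{path}: empty file, no header row")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    LabelRecord(
                        atc_code=row["atc_code"],
                        compound_name=row["compound_name"].strip(),
                        compound_class=row["compound_class"].strip(),
                        min_age_years=int(row["min_age_years"]),
                        indication_codes=row["indication_prefixes"].split(";"),
                        source_year=int(row["source_year"]),
                        device_or_product_note=(row.get("device_or_product_note") or None),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise LabelKBError(f"{path}, row {i}: {exc}") from exc
    if not records:
        raise LabelKBError(f"{path}: no label records")
    return records


def load_category_map(path: str | Path) -> DiagnosisCategoryMap:
    """Read an ordered category-map CSV (category_label, icd_prefixes)."""
    path = Path(path)
    cats: list[tuple[str, frozenset[str]]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cats.append(
                (row["category_label"].strip(), frozenset(row["icd_prefixes"].split(";")))
            )
    if not cats:
        raise LabelKBError(f"{path}: no category rows")
    return DiagnosisCategoryMap(categories=tuple(cats))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pedrx").joinpath("data", name)))


def default_label_kb() -> list[LabelRecord]:
    """The shipped knowledge base: 24 respiratory compounds, 2004 and 2008
    label snapshots."""
    return load_label_kb(_data_path("label_kb.csv"))


def default_category_map() -> DiagnosisCategoryMap:
    """The shipped ICD-10 J-chapter grouper used for indication breakdowns."""
    return load_category_map(_data_path("diagnosis_categories.csv"))
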