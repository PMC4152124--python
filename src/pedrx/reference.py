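"""Arithmetic checks against the reported counts of the source
drug-utilisation study.

The study's raw claims database is not public, but the compound-level
counts it reports (total prescriptions, off-label counts by type, top
off-label indication categories, and year-on-year changes, all for the 2008
analysis year) are printed, and every percentage, partition sum and trend
delta is an arithmetic consequence of those counts. The tables below
transcribe the printed counts; :func:`render_reference_checks` recomputes
the derived quantities through the package's own aggregation functions and
compares them with the printed values at one-decimal display rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import offlabel_trend, round_half_up, summarize_counts

# Compound-level 2008 counts: (atc, compound, class_tag, n_all, n_age_only,
# n_indication_only, n_age_and_indication)
TABLE2_ROWS: tuple[tuple[str, str, str, int, int, int, int], ...] = (
    ("R03AC02", "Salbutamol (inhaled)", "inhaled_saba", 159_655, 0, 67_084, 0),
    ("R03AC04", "Fenoterol", "inhaled_saba", 1_452, 6, 367, 10),
    ("R03AC03", "Terbutaline (inhaled)", "inhaled_saba", 184, 0, 33, 1),
    ("R03AK03", "Ipratropium/Fenoterol", "inhaled_saba_combination", 3_998, 0, 1_722, 0),
    ("R03AK05", "Reproterol/Cromoglicic acid", "inhaled_saba_combination", 8_729, 0, 2_538, 0),
    ("R03AC12", "Salmeterol", "inhaled_laba", 522, 9, 75, 2),
    ("R03AC13", "Formoterol", "inhaled_laba", 4_931, 88, 730, 21),
    ("R03AK06", "Salmeterol/Fluticasone", "inhaled_laba_ics", 27_600, 368, 3_734, 176),
    ("R03AK27", "Formoterol/Beclomethasone", "inhaled_laba_ics", 2_515, 11, 827, 10),
    ("R03AK28", "Formoterol/Budesonide", "inhaled_laba_ics", 13_833, 113, 2_412, 59),
    ("R03BB01", "Ipratropium", "sama", 21_822, 0, 10_910, 0),
    ("R03BB04", "Tiotropium", "lama", 97, 9, 11, 76),
    ("R03BA02", "Budesonide", "ics", 42_067, 0, 3_166, 0),
    ("R03BA01", "Beclomethasone", "ics", 24_185, 0, 1_922, 0),
    ("R03BA05", "Fluticasone", "ics", 17_097, 1_917, 2_370, 1_073),
    ("R03BA08", "Ciclesonide", "ics", 326, 35, 60, 15),
    ("R03CC02", "Salbutamol (oral)", "oral_b2a", 19_475, 0, 5_544, 0),
    ("R03CC03", "Terbutaline (oral)", "oral_b2a", 6_940, 0, 2_012, 0),
    ("R03CC11", "Tulobuterol", "oral_b2a", 1_201, 32, 292, 6),
    ("R03CC13", "Clenbuterol", "oral_b2a", 113, 0, 67, 0),
    ("R03CC63", "Clenbuterol/Ambroxol", "oral_b2a_combination", 91_385, 0, 18_897, 0),
    ("R03DA04", "Theophylline", "other", 1_184, 7, 419, 25),
    ("R03DC03", "Montelukast", "other", 33_501, 304, 11_831, 691),
    ("R03BC01", "Cromoglicic acid", "other", 5_087, 110, 2_724, 413),
)

# Reported class-level and grand-total rows: label → (class tags, n_all,
# n_age, n_ind, n_both, printed off-label pct)
CLASS_ROLLUPS: dict[str, tuple[tuple[str, ...], int, int, int, int, float]] = {
    "inhaled_saba_incl_combination": (
        ("inhaled_saba", "inhaled_saba_combination"), 174_018, 6, 71_744, 11, 41.2
    ),
    "inhaled_laba_incl_combination": (
        ("inhaled_laba", "inhaled_laba_ics"), 49_401, 589, 7_778, 268, 17.5
    ),
    "muscarinic_antagonists": (("sama", "lama"), 21_919, 9, 10_921, 76, 50.2),
    "inhaled_bronchodilatives": (
        ("inhaled_saba", "inhaled_saba_combination", "inhaled_laba",
         "inhaled_laba_ics", "sama", "lama"),
        245_338, 604, 90_443, 355, 37.3,
    ),
    "ics": (("ics",), 83_675, 1_952, 7_518, 1_088, 12.6),
    "oral_b2a_incl_combination": (
        ("oral_b2a", "oral_b2a_combination"), 119_114, 32, 26_812, 6, 22.5
    ),
    "others": (("other",), 39_772, 421, 14_974, 1_129, 41.5),
}

ALL_DRUGS_TOTAL = (487_899, 3_009, 139_747, 2_578, 29.8)

# Printed per-compound off-label percentages (2008).
COMPOUND_PCT: dict[str, float] = {
    "R03AC02": 42.0, "R03AC04": 26.4, "R03AC03": 18.5, "R03AK03": 43.1,
    "R03AK05": 29.1, "R03AC12": 16.5, "R03AC13": 17.0, "R03AK06": 15.5,
    "R03AK27": 33.7, "R03AK28": 18.7, "R03BB01": 50.0, "R03BB04": 99.0,
    "R03BA02": 7.5, "R03BA01": 7.9, "R03BA05": 31.4, "R03BA08": 33.7,
    "R03CC02": 28.5, "R03CC03": 29.0, "R03CC11": 27.5, "R03CC13": 59.3,
    "R03CC63": 20.7, "R03DA04": 38.1, "R03DC03": 38.3, "R03BC01": 63.8,
}

# Indication-only share of all off-label prescriptions, as reported in the
# results text: group → (n_indication_only, n_offlabel_overall, printed pct).
INDICATION_ONLY_SHARES: dict[str, tuple[int, int, float]] = {
    "inhaled_bronchodilatives": (90_443, 91_402, 99.0),
    "inhaled_salbutamol": (67_084, 67_084, 100.0),
    "oral_b2a_incl_combination": (26_812, 26_850, 99.9),
    "clenbuterol_ambroxol": (18_897, 18_897, 100.0),
}

# Multiple-counting indication breakdown (2008): (compound key, category,
# n_category, denominator = off-label due to indication or age&indication,
# printed pct).
TABLE3_ENTRIES: tuple[tuple[str, str, int, int, float], ...] = (
    ("inhaled_salbutamol", "Acute bronchitis", 29_989, 67_084, 44.7),
    ("inhaled_salbutamol", "Acute upper respiratory infections", 23_827, 67_084, 35.5),
    ("inhaled_salbutamol", "Other diseases of upper respiratory tract", 13_267, 67_084, 19.8),
    ("clenbuterol_ambroxol", "Acute upper respiratory infections", 9_131, 18_897, 48.3),
    ("ipratropium", "Acute bronchitis", 5_779, 10_910, 53.0),
)

# Off-label count changes 2004→2008 reported in the results text:
# key → (n_2008, absolute change, printed relative pct).
TREND_ENTRIES: dict[str, tuple[int, int, float]] = {
    "inhaled_salbutamol": (67_084, 21_841, 48.3),
    "oral_salbutamol": (5_544, 5_422, 4_444.3),
    "cromoglicic_acid": (3_247, -10_195, -75.8),
    "clenbuterol_ambroxol": (18_897, -6_196, -24.7),
}

# Reported PPR extremes (per 10,000 children): inhaled salbutamol rose from
# 378 to 527 over the study period, an absolute change of +149.
PPR_SALBUTAMOL_RANGE = (378.0, 527.0, 149.0)


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    ok: bool


def _check(name: str, computed: float, expected: float) -> Check:
    return Check(name=name, computed=computed, expected=expected, ok=computed == expected)


def render_reference_checks() -> list[Check]:
    """Recompute every derived quantity from the transcribed counts and
    compare with the printed value at display rounding."""
    checks: list[Check] = []

    # per-compound off-label percentages
    for atc, _, _, n_all, n_age, n_ind, n_both in TABLE2_ROWS:
        row = summarize_counts(n_all, n_age, n_ind, n_both)
        checks.append(
            _check(
                f"offlabel_pct_{atc}",
                round_half_up(row["pct_offlabel"]),
                COMPOUND_PCT[atc],
            )
        )

    # class rollups: sums of compound counts must equal the printed subtotals,
    # and the recomputed percentage must match
    for key, (tags, n_all, n_age, n_ind, n_both, pct) in CLASS_ROLLUPS.items():
        sums = [
            sum(r[i] for r in TABLE2_ROWS if r[2] in tags) for i in (3, 4, 5, 6)
        ]
        checks.append(_check(f"rollup_n_all_{key}", sums[0], n_all))
        row = summarize_counts(*sums)
        checks.append(
            _check(f"rollup_partition_{key}", row["n_offlabel_overall"], n_age + n_ind + n_both)
        )
        checks.append(_check(f"rollup_pct_{key}", round_half_up(row["pct_offlabel"]), pct))

    # grand total
    n_all, n_age, n_ind, n_both, pct = ALL_DRUGS_TOTAL
    total_all = sum(r[3] for r in TABLE2_ROWS)
    checks.append(_check("total_prescriptions", total_all, n_all))
    total = summarize_counts(total_all, sum(r[4] for r in TABLE2_ROWS),
                             sum(r[5] for r in TABLE2_ROWS), sum(r[6] for r in TABLE2_ROWS))
    checks.append(_check("total_offlabel_partition", total["n_offlabel_overall"],
                         n_age + n_ind + n_both))
    checks.append(_check("total_offlabel_pct", round_half_up(total["pct_offlabel"]), pct))

    # indication-only shares of off-label prescriptions
    for key, (n_ind_only, n_off, printed) in INDICATION_ONLY_SHARES.items():
        checks.append(
            _check(
                f"indication_only_share_{key}",
                round_half_up(100.0 * n_ind_only / n_off),
                printed,
            )
        )

    # multiple-counting indication breakdown percentages
    for key, category, n_cat, denom, printed in TABLE3_ENTRIES:
        slug = category.lower().replace(" ", "_")
        checks.append(
            _check(
                f"breakdown_pct_{key}_{slug}",
                round_half_up(100.0 * n_cat / denom),
                printed,
            )
        )

    # trend deltas: 2004 counts recovered from 2008 count and absolute change
    for key, (n_2008, delta, printed) in TREND_ENTRIES.items():
        t = offlabel_trend(n_2008 - delta, n_2008)
        checks.append(_check(f"trend_abs_{key}", t.absolute, delta))
        checks.append(
            _check(f"trend_rel_pct_{key}", round_half_up(t.relative_pct), printed)
        )

    # PPR absolute change for inhaled salbutamol
    a, b, delta = PPR_SALBUTAMOL_RANGE
    checks.append(_check("ppr_abs_change_inhaled_salbutamol",
                         round_half_up(b - a, 0), delta))

    return checks
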