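"""Off-label classifier: rule logic, summaries, breakdowns, trends."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pedrx
from pedrx.classify import (
    OffLabelStatus,
    breakdown_offlabel_indications,
    classify_prescription,
    offlabel_trend,
    round_half_up,
    summarize_counts,
    summarize_offlabel,
)
from pedrx.labels import EffectiveLabel


def _label(min_age=0, ind=("J43", "J44", "J45", "J46"), atc="R03AC02"):
    return EffectiveLabel(
        atc_code=atc, compound_name="x", compound_class="inhaled_saba",
        min_age_years=min_age, indication_codes=frozenset(ind),
    )


class TestClassifyPrescription:
    @pytest.mark.parametrize(
        "age,codes,min_age,ind,expected",
        [
            (10, {"J45.0"}, 18, ("J44",), OffLabelStatus.OFF_AGE_AND_INDICATION),
            (3, {"J45.9"}, 0, ("J43", "J44", "J45", "J46"), OffLabelStatus.ON_LABEL),
            (3, {"J20.9"}, 0, ("J43", "J44", "J45", "J46"), OffLabelStatus.OFF_INDICATION),
            (2, {"J45.0"}, 4, ("J43", "J44", "J45", "J46"), OffLabelStatus.OFF_AGE),
            (4, {"J45.0"}, 4, ("J45",), OffLabelStatus.ON_LABEL),  # age boundary inclusive
        ],
    )
    def test_rule_matrix(self, age, codes, min_age, ind, expected):
        assert classify_prescription(age, codes, _label(min_age, ind)) == expected

    def test_any_match_convention(self):
        """One approved diagnosis among several off-label ones keeps the
        prescription on-label by indication."""
        assert (
            classify_prescription(8, {"J20.9", "J06.9", "J45.9"}, _label())
            == OffLabelStatus.ON_LABEL
        )

    @pytest.mark.parametrize(
        "policy,age,expected",
        [
            ("indeterminate", 8, OffLabelStatus.INDETERMINATE),
            ("indeterminate", 1, OffLabelStatus.INDETERMINATE),
            ("on_label", 8, OffLabelStatus.ON_LABEL),
            ("on_label", 1, OffLabelStatus.OFF_AGE),
            ("off_label_indication", 8, OffLabelStatus.OFF_INDICATION),
            ("off_label_indication", 1, OffLabelStatus.OFF_AGE_AND_INDICATION),
        ],
    )
    def test_missing_diagnosis_policies(self, policy, age, expected):
        assert classify_prescription(age, set(), _label(min_age=4), policy) == expected


class TestSummaries:
    def test_ten_prescription_arithmetic(self):
        rows = (
            [{"atc_code": "X", "compound_class": "c", "status": s.value, "linked_codes": "J20"}
             for s in [OffLabelStatus.OFF_AGE] * 2
             + [OffLabelStatus.OFF_INDICATION] * 3
             + [OffLabelStatus.OFF_AGE_AND_INDICATION] * 1
             + [OffLabelStatus.ON_LABEL] * 4]
        )
        out = summarize_offlabel(pd.DataFrame(rows), "total")
        row = out.iloc[0]
        assert row["n_offlabel_overall"] == 6
        assert row["pct_offlabel"] == 60.0

    def test_empty_input_gives_zero_total_row(self):
        out = summarize_offlabel(
            pd.DataFrame(columns=["atc_code", "compound_class", "status", "linked_codes"]),
            "total",
        )
        assert out.iloc[0]["n_all"] == 0 and out.iloc[0]["pct_offlabel"] == 0.0

    def test_partition_overflow_rejected(self):
        with pytest.raises(ValueError):
            summarize_counts(5, 2, 2, 2)

    @given(
        st.lists(
            st.sampled_from([s.value for s in OffLabelStatus]), min_size=1, max_size=200
        )
    )
    def test_partition_identity(self, statuses):
        """Every summary row partitions its prescriptions exactly."""
        df = pd.DataFrame(
            {"atc_code": ["A"] * len(statuses), "compound_class": ["c"] * len(statuses),
             "status": statuses, "linked_codes": ["J20"] * len(statuses)}
        )
        for grouping in ("compound", "class", "total"):
            for _, row in summarize_offlabel(df, grouping).iterrows():
                n_on = row["n_all"] - row["n_offlabel_overall"] - row["n_indeterminate"]
                assert n_on == sum(1 for s in statuses if s == "on_label")
                assert (
                    row["n_offlabel_overall"]
                    == row["n_age_only"] + row["n_indication_only"] + row["n_age_and_indication"]
                )


class TestBreakdown:
    def test_multiple_counting(self, category_map):
        df = pd.DataFrame(
            [{
                "atc_code": "R03AC02", "compound_name": "Salbutamol",
                "status": OffLabelStatus.OFF_INDICATION.value,
                "linked_codes": "J06.9;J20.9", "offlabel_codes": "J06.9;J20.9",
            }]
        )
        out = breakdown_offlabel_indications(df, category_map)
        assert set(out["category_label"]) == {
            "Acute bronchitis", "Acute upper respiratory infections"
        }
        assert (out["n_offlabel_indication"] == 1).all()
        assert (out["pct_of_offlabel"] == 100.0).all()

    def test_no_offlabel_no_rows(self, category_map):
        df = pd.DataFrame(
            [{"atc_code": "A", "compound_name": "a",
              "status": OffLabelStatus.ON_LABEL.value,
              "linked_codes": "J45", "offlabel_codes": ""}]
        )
        assert len(breakdown_offlabel_indications(df, category_map)) == 0

    def test_top_k_truncation(self, category_map):
        rows = [
            {"atc_code": "A", "compound_name": "a",
             "status": OffLabelStatus.OFF_INDICATION.value,
             "linked_codes": c, "offlabel_codes": c}
            for c in ["J06.9", "J06.9", "J20.9", "J20.9", "J30.1", "J40"]
        ]
        out = breakdown_offlabel_indications(pd.DataFrame(rows), category_map, top_k=2)
        assert len(out) == 2
        assert out["n_category"].tolist() == [2, 2]


class TestTrend:
    def test_no_change(self):
        t = offlabel_trend(50, 50)
        assert (t.absolute, t.relative_pct) == (0, 0.0)

    def test_zero_baseline_flagged(self):
        t = offlabel_trend(0, 5)
        assert t.absolute == 5 and t.relative_pct is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            offlabel_trend(-1, 5)


class TestMonotonicity:
    """Relaxing a label never creates off-label prescriptions."""

    def _classified(self, labels, small_dataset):
        ds, _, _ = small_dataset
        cfg = pedrx.AnalysisConfig()
        return pedrx.classify_claims(pedrx.filter_study_population(ds, cfg), labels, cfg)

    def test_min_age_zero_removes_age_offlabel(self, labels, small_dataset):
        base = self._classified(labels, small_dataset)
        relaxed_labels = {
            atc: lab.model_copy(update={"min_age_years": 0}) for atc, lab in labels.items()
        }
        relaxed = self._classified(relaxed_labels, small_dataset)
        merged = base.merge(relaxed, on="rx_id", suffixes=("_base", "_rel"))
        moved = {
            OffLabelStatus.OFF_AGE.value: OffLabelStatus.ON_LABEL.value,
            OffLabelStatus.OFF_AGE_AND_INDICATION.value: OffLabelStatus.OFF_INDICATION.value,
        }
        for _, row in merged.iterrows():
            assert row["status_rel"] == moved.get(row["status_base"], row["status_base"])

    def test_widening_indications_never_increases_offlabel(self, labels, small_dataset):
        base = self._classified(labels, small_dataset)
        wide_labels = {
            atc: lab.model_copy(
                update={"indication_codes": lab.indication_codes | {"J20", "J06"}}
            )
            for atc, lab in labels.items()
        }
        wide = self._classified(wide_labels, small_dataset)

        def n_off(df):
            return df["status"].isin(
                [s.value for s in pedrx.classify.OFFLABEL_STATUSES]
            ).sum()

        assert n_off(wide) <= n_off(base)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(42.0169, 42.0), (20.678, 20.7), (0.05, 0.1), (-75.84, -75.8), (-0.05, -0.1)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_up(value) == expected
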