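"""Label knowledge base: loading, resolution, ICD matching, categorisation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import pedrx
from pedrx.labels import (
    ATC_PATTERN,
    LabelKBError,
    LabelRecord,
    categorize_diagnosis,
    match_icd,
    normalize_icd,
    resolve_effective_label,
)


class TestShippedKB:
    def test_covers_all_compounds_for_both_snapshot_years(self, kb_records):
        atcs = {r.atc_code for r in kb_records}
        assert len(atcs) == 24
        for year in (2004, 2008):
            assert {r.atc_code for r in kb_records if r.source_year == year} == atcs

    def test_tiotropium_is_adult_copd_only(self, labels):
        lab = labels["R03BB04"]
        assert lab.min_age_years == 18
        assert lab.indication_codes == frozenset({"J44"})

    def test_inhaled_salbutamol_has_no_age_restriction(self, labels):
        assert labels["R03AC02"].min_age_years == 0

    def test_all_atcs_lexically_valid(self, kb_records):
        assert all(ATC_PATTERN.match(r.atc_code) for r in kb_records)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "kb.csv"
        p.write_text("")
        with pytest.raises(LabelKBError):
            pedrx.load_label_kb(p)

    @pytest.mark.parametrize(
        "bad_field",
        [
            {"atc_code": "XYZ"},
            {"indication_prefixes": ""},
            {"compound_class": "nonsense"},
        ],
    )
    def test_malformed_row_named_in_error(self, tmp_path, bad_field):
        row = {
            "atc_code": "R03AC02", "compound_name": "x", "compound_class": "inhaled_saba",
            "min_age_years": "0", "indication_prefixes": "J45", "source_year": "2008",
            "device_or_product_note": "",
        }
        row.update(bad_field)
        p = tmp_path / "kb.csv"
        p.write_text(",".join(row) + "\n" + ",".join(row.values()) + "\n")
        with pytest.raises(LabelKBError, match="row 2"):
            pedrx.load_label_kb(p)


def _rec(atc="R03AC02", age=0, ind=("J45",), year=2008):
    return LabelRecord(
        atc_code=atc, compound_name="x", compound_class="inhaled_saba",
        min_age_years=age, indication_codes=ind, source_year=year,
    )


class TestResolveEffectiveLabel:
    def test_lowest_age_widest_indications(self):
        eff = resolve_effective_label([_rec(age=4, ind=("J45",)), _rec(age=6, ind=("J45", "J44"))])
        assert eff.min_age_years == 4
        assert eff.indication_codes == frozenset({"J45", "J44"})
        assert eff.n_source_records == 2

    def test_single_record_identity(self):
        eff = resolve_effective_label([_rec(age=5, ind=("J44",))])
        assert (eff.min_age_years, eff.indication_codes) == (5, frozenset({"J44"}))

    def test_zero_age_wins(self):
        assert resolve_effective_label([_rec(age=0), _rec(age=12)]).min_age_years == 0

    def test_mixed_atcs_rejected(self):
        with pytest.raises(LabelKBError):
            resolve_effective_label([_rec(atc="R03AC02"), _rec(atc="R03AC04")])

    def test_empty_rejected(self):
        with pytest.raises(LabelKBError):
            resolve_effective_label([])

    def test_idempotent(self):
        eff = resolve_effective_label([_rec(age=4), _rec(age=6, ind=("J44", "J45"))])
        again = resolve_effective_label([eff])
        assert again == eff

    @given(
        ages=st.lists(st.integers(0, 18), min_size=1, max_size=6),
        extra_age=st.integers(0, 18),
        extra_ind=st.sets(st.sampled_from(["J20", "J41", "J44", "J45"]), min_size=1),
    )
    def test_adding_a_record_is_monotone(self, ages, extra_age, extra_ind):
        """More label versions can only lower the age bar and widen indications."""
        recs = [_rec(age=a) for a in ages]
        base = resolve_effective_label(recs)
        grown = resolve_effective_label(recs + [_rec(age=extra_age, ind=tuple(extra_ind))])
        assert grown.min_age_years <= base.min_age_years
        assert grown.indication_codes >= base.indication_codes


class TestMatchICD:
    @pytest.mark.parametrize(
        "code,prefixes,expected",
        [
            ("J45.9", {"J45"}, True),
            ("J20.5", {"J45", "J46"}, False),
            ("j459", {"J45"}, True),
            ("J45", {"J45"}, True),
            ("???", {"J45"}, False),
        ],
    )
    def test_prefix_semantics(self, code, prefixes, expected):
        assert match_icd(code, prefixes) is expected

    @given(st.sampled_from(["J45.9", "j45.9", "J459", " j459 "]))
    def test_normalisation_invariance(self, variant):
        assert normalize_icd(variant) == "J459"
        assert match_icd(variant, {"J45"})


class TestCategorize:
    @pytest.mark.parametrize(
        "code,label",
        [
            ("J20.9", "Acute bronchitis"),
            ("J06.9", "Acute upper respiratory infections"),
            ("J30.1", "Other diseases of upper respiratory tract"),
            ("J40", "Bronchitis nec"),
            ("J21.0", "Acute lower respiratory infections"),
            ("J45.9", "Other respiratory diseases"),
            ("A09.9", "Non-respiratory diseases"),
        ],
    )
    def test_default_map(self, category_map, code, label):
        assert categorize_diagnosis(code, category_map) == label

    @given(st.sampled_from(["J20.9", "j209", "J20.9 "]))
    def test_formatting_invariance(self, variant):
        cmap = pedrx.default_category_map()
        assert categorize_diagnosis(variant, cmap) == "Acute bronchitis"

    def test_duplicate_prefix_rejected(self):
        with pytest.raises(ValueError):
            pedrx.DiagnosisCategoryMap(
                categories=(("a", frozenset({"J20"})), ("b", frozenset({"J20"})))
            )
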