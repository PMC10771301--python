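"""Cleaning rules: dedup, role selection, indication removal, strata."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faers_signals.ingest import (
    FormatError,
    assign_strata,
    build_reports,
    clean_bundle,
    convert_age_years,
    convert_weight_kg,
    deduplicate,
    exclude_indication_pts,
    read_bundle,
    select_target_reports,
)
from tests.conftest import SYNONYMS


def _demo(rows):
    return pd.DataFrame(rows, columns=["PRIMARYID", "CASEID", "FDA_DT"])


class TestDeduplicate:
    def test_most_recent_fda_dt_wins(self):
        demo = _demo([("11", "1", "20200101"), ("12", "1", "20200301")])
        out = deduplicate(demo)
        assert list(out["PRIMARYID"]) == ["12"]

    def test_equal_fda_dt_higher_primaryid_wins(self):
        demo = _demo([("10001", "1", "20200301"), ("10002", "1", "20200301")])
        out = deduplicate(demo)
        assert list(out["PRIMARYID"]) == ["10002"]

    def test_distinct_cases_untouched(self):
        demo = _demo([("11", "1", "20200101"), ("21", "2", "20200301")])
        out = deduplicate(demo)
        assert sorted(out["PRIMARYID"]) == ["11", "21"]

    def test_unparseable_date_ranks_lowest(self):
        demo = _demo([("19", "1", ""), ("11", "1", "19990101")])
        out = deduplicate(demo)
        assert list(out["PRIMARYID"]) == ["11"]

    def test_idempotent(self):
        demo = _demo([("11", "1", "20200101"), ("12", "1", "20200301"),
                      ("21", "2", "20200101")])
        once = deduplicate(demo)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_recovers_generator_survivors(self, bundle, dataset):
        _, truth = bundle
        surv = set(dataset.reports["primaryid"])
        for _, row in truth.duplicates.iterrows():
            assert str(row["survivor_primaryid"]) in surv
            # all discarded versions of the case are gone
            case_pids = {str(int(row["caseid"]) * 10 + 1 + v)
                         for v in range(1 + int(row["n_versions"]))}
            assert case_pids & surv == {str(row["survivor_primaryid"])}


class TestTargetSelection:
    def _drugs(self, rows):
        return pd.DataFrame(rows, columns=["PRIMARYID", "DRUG_SEQ",
                                           "ROLE_COD", "DRUGNAME", "PROD_AI"])

    def test_synonym_ps_selected(self):
        d = self._drugs([("1", "1", "PS", "NUCALA", "")])
        assert select_target_reports(d, SYNONYMS) == {"1"}

    def test_concomitant_role_not_selected(self):
        d = self._drugs([("1", "1", "C", "MEPOLIZUMAB", "MEPOLIZUMAB")])
        assert select_target_reports(d, SYNONYMS) == frozenset()

    def test_no_substring_matching(self):
        d = self._drugs([("1", "1", "PS", "NUCALA 100MG", "")])
        assert select_target_reports(d, SYNONYMS) == frozenset()

    def test_prod_ai_and_case_folding(self):
        d = self._drugs([("1", "1", "PS", "BRANDED", " mepolizumab ")])
        assert select_target_reports(d, SYNONYMS) == {"1"}

    def test_empty_synonyms_rejected(self):
        with pytest.raises(ValueError):
            select_target_reports(self._drugs([]), [])

    @given(extra=st.lists(st.sampled_from(["COMPARATOR_01", "COMPARATOR_02",
                                           "OTHER"]), max_size=3))
    @settings(max_examples=25, deadline=None)
    def test_selection_monotone_in_synonym_list(self, extra):
        d = self._drugs([("1", "1", "PS", "NUCALA", ""),
                         ("2", "1", "PS", "COMPARATOR_01", ""),
                         ("3", "1", "PS", "OTHER", "")])
        base = select_target_reports(d, SYNONYMS)
        bigger = select_target_reports(d, list(SYNONYMS) + extra)
        assert base <= bigger


class TestIndicationRemoval:
    def test_indication_pt_removed_for_target_reports(self):
        events = pd.DataFrame({"PRIMARYID": ["1", "1", "2"],
                               "PT": ["Asthma", "Pneumonia", "Asthma"]})
        out, removed = exclude_indication_pts(events, {"ASTHMA"}, frozenset({"1"}))
        assert removed == 1
        assert list(out.itertuples(index=False, name=None)) == [
            ("1", "Pneumonia"), ("2", "Asthma")]  # comparator report kept

    def test_empty_indication_set_is_noop(self):
        events = pd.DataFrame({"PRIMARYID": ["1"], "PT": ["Asthma"]})
        out, removed = exclude_indication_pts(events, set(), frozenset({"1"}))
        assert removed == 0 and len(out) == 1


class TestStrata:
    @pytest.mark.parametrize("age,expected", [
        (17.9, "<18"), (18, "18-64"), (40, "18-64"), (64, "18-64"),
        (64.1, ">64"), (None, "unknown")])
    def test_age_boundaries(self, age, expected):
        rep = pd.DataFrame({"age_years": [float(age) if age is not None
                                          else float("nan")],
                            "weight_kg": [float("nan")]})
        assert assign_strata(rep)["age_group"].iloc[0] == expected

    @pytest.mark.parametrize("wt,expected", [
        (79.9, "<80"), (80, "80-100"), (100, "80-100"), (100.5, ">100"),
        (None, "unknown")])
    def test_weight_boundaries(self, wt, expected):
        rep = pd.DataFrame({"age_years": [float("nan")],
                            "weight_kg": [float(wt) if wt is not None
                                          else float("nan")]})
        assert assign_strata(rep)["weight_group"].iloc[0] == expected


@pytest.mark.parametrize("age,cod,years", [
    ("5", "DEC", 50.0), ("30", "YR", 30.0), ("24", "MON", 2.0),
    ("", "YR", None), ("abc", "YR", None)])
def test_age_unit_conversion(age, cod, years):
    got = convert_age_years(age, cod)
    if years is None:
        assert got != got  # NaN
    else:
        assert got == pytest.approx(years)


def test_weight_lbs_conversion():
    assert convert_weight_kg("220", "LBS") == pytest.approx(99.79, abs=0.01)
    assert convert_weight_kg("80", "KG") == 80.0


class TestReadBundle:
    def test_row_with_missing_field_raises_with_line_number(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text(
            "PRIMARYID$CASEID$FDA_DT\n1$1$20200101\n2$2\n")
        with pytest.raises(FormatError, match="line 3"):
            read_bundle({"DEMO": tmp_path / "DEMO.txt"})

    def test_wrong_delimiter_detected(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("PRIMARYID,CASEID,FDA_DT\n")
        with pytest.raises(FormatError, match="delimited"):
            read_bundle({"DEMO": tmp_path / "DEMO.txt"})

    def test_missing_mandatory_column_named(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("PRIMARYID$FDA_DT\n")
        with pytest.raises(FormatError, match="CASEID"):
            read_bundle({"DEMO": tmp_path / "DEMO.txt"})

    def test_empty_body_is_fine(self, tmp_path):
        for name in ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC"):
            (tmp_path / f"{name}.txt").write_text(
                "$".join(["PRIMARYID", "CASEID", "FDA_DT", "DRUG_SEQ",
                          "ROLE_COD", "DRUGNAME", "PT", "DSG_DRUG_SEQ",
                          "START_DT", "INDI_PT", "OUTC_COD"]) + "\n")
        tables = read_bundle(tmp_path)
        assert len(tables["DEMO"]) == 0


def test_clean_bundle_referential_integrity(dataset):
    ids = set(dataset.reports["primaryid"])
    for child in (dataset.drugs, dataset.events, dataset.therapies,
                  dataset.indications, dataset.outcomes):
        assert set(child["PRIMARYID"]) <= ids
    assert dataset.target_ids <= ids


def test_clean_bundle_counts_logged(dataset, bundle_cfg):
    log = dataset.log
    assert log["reports_after_dedup"] == bundle_cfg.n_reports
    assert log["demo_rows_raw"] > bundle_cfg.n_reports  # duplicates present
    assert log["target_reports"] == len(dataset.target_ids)


def test_indication_terms_exclude_unknown_placeholder(dataset):
    assert "PRODUCT USED FOR UNKNOWN INDICATION" not in dataset.log["indication_terms"]
    assert "ASTHMA" in dataset.log["indication_terms"]
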