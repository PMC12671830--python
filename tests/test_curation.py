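import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tnfvigil.curation import (CurationConfig, DrugDictionary, apply_pt_filters,
                               assign_stratum, curate, deduplicate, map_drug,
                               reporter_class, select_pediatric, to_years)
from tnfvigil.ingest import read_quarter
from tnfvigil.synthetic import DEFAULT_PT_SOC


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        demo = _demo([("P1", "C1", "20100101"), ("P2", "C1", "20110101")])
        assert deduplicate(demo) == {"P2"}

    def test_tie_broken_by_highest_primaryid_numerically(self):
        demo = _demo([("P3", "C1", "20110101"), ("P9", "C1", "20110101")])
        assert deduplicate(demo) == {"P9"}
        # numeric, not lexicographic: 10 > 9
        demo = _demo([("9", "C1", "20110101"), ("10", "C1", "20110101")])
        assert deduplicate(demo) == {"10"}

    def test_deleted_cases_removed(self):
        demo = _demo([("P3", "C1", "20110101"), ("P9", "C1", "20110101")])
        assert deduplicate(demo, deleted={"C1"}) == set()

    def test_partial_dates_compare_at_available_precision(self):
        # bare year sorts below any fully-dated report of the same year
        demo = _demo([("P1", "C1", "2011"), ("P2", "C1", "20110101")])
        assert deduplicate(demo) == {"P2"}

    def test_idempotent_and_duplication_stable(self):
        rows = [("1", "A", "20100101"), ("2", "A", "20100401"),
                ("7", "B", "2012"), ("3", "B", "201201")]
        once = deduplicate(_demo(rows))
        survivors_demo = _demo([r for r in rows if r[0] in once])
        assert deduplicate(survivors_demo) == once          # idempotence
        assert deduplicate(_demo(rows * 2)) == once          # multiset stable
        assert deduplicate(_demo(rows[::-1])) == once        # order invariant

    def test_empty_input(self):
        assert deduplicate(_demo([])) == set()


@pytest.mark.parametrize("value, code, expected", [
    (6, "MON", 0.5),
    (17, "YR", 17.0),
    (730.5, "DY", 2.0),
    (1, "DEC", 10.0),
    (365.25 / 7, "WK", 1.0),
    (8766, "HR", 1.0),
])
def test_to_years_conversions(value, code, expected):
    assert to_years(value, code) == pytest.approx(expected)


@pytest.mark.parametrize("value, code", [
    (-1, "YR"), ("abc", "YR"), (5, "??"), (None, "YR"), (float("nan"), "YR"),
])
def test_to_years_rejects_implausible(value, code):
    assert to_years(value, code) is None


def test_select_pediatric_boundaries_and_tallies():
    keep, tally = select_pediatric([17.99, 18.0, None, 150.0, 0.0])
    assert keep == [True, False, False, False, True]
    assert tally == {"missing": 1, "implausible": 1, "adult": 1, "retained": 2}


@pytest.mark.parametrize("age, stratum", [
    (0.0, "0-3"), (3.9, "0-3"), (4.0, "4-11"), (11.99, "4-11"),
    (12.0, "12-17"), (17.99, "12-17"),
])
def test_assign_stratum_boundaries(age, stratum):
    assert assign_stratum(age) == stratum


@given(st.floats(min_value=0, max_value=18, exclude_max=True,
                 allow_nan=False))
@settings(derandomize=True, max_examples=200)
def test_assign_stratum_partitions_pediatric_range(age):
    assert assign_stratum(age) in ("0-3", "4-11", "12-17")


def test_assign_stratum_faults_outside_range():
    for age in (-0.1, 18.0, 25.0):
        with pytest.raises(ValueError):
            assign_stratum(age)


class TestMapDrug:
    dictionary = DrugDictionary.default()

    @pytest.mark.parametrize("name, agent", [
        ("HUMIRA", "adalimumab"),
        ("REMICADE 100MG", "infliximab"),
        ("humira (adalimumab) 40 mg", "adalimumab"),
        ("CERTOLIZUMAB PEGOL", "certolizumab"),
        ("ASPIRIN", None),
        ("", None),
        ("HUMIRAX", None),  # whole-token match only
    ])
    def test_examples(self, name, agent):
        assert map_drug(name, self.dictionary) == agent

    def test_ambiguous_multi_agent_name_maps_to_none(self):
        assert map_drug("ENBREL / HUMIRA COMBO", self.dictionary) is None


@pytest.mark.parametrize("code, cls", [
    ("MD", "Physician"), ("PH", "Pharmacist"), ("OT", "Other health professional"),
    ("RN", "Other health professional"), ("HP", "Other health professional"),
    ("CN", "Consumer"), ("LW", "Unknown/other"), ("", "Unknown/other"),
])
def test_reporter_class_collapse(code, cls):
    assert reporter_class(code) == cls


class TestPtFilters:
    config = CurationConfig()

    def test_indication_pts_dropped_per_pt(self):
        kept, reason = apply_pt_filters(
            ["Crohn's disease", "Pyrexia"], "infliximab", self.config,
            DEFAULT_PT_SOC)
        assert kept == ["Pyrexia"] and reason is None

    def test_all_indication_pts_excludes_report(self):
        kept, reason = apply_pt_filters(
            ["Crohn's disease"], "infliximab", self.config, DEFAULT_PT_SOC)
        assert kept == [] and reason == "indication_only"

    def test_product_issues_only_excluded(self):
        kept, reason = apply_pt_filters(
            ["Device leakage"], "etanercept", self.config, DEFAULT_PT_SOC)
        assert reason == "product_issues_only"

    def test_product_issue_plus_medical_pt_retained(self):
        kept, reason = apply_pt_filters(
            ["Device leakage", "Pyrexia"], "etanercept", self.config,
            DEFAULT_PT_SOC)
        assert kept == ["Device leakage", "Pyrexia"] and reason is None

    def test_offlabel_only_report_retained(self):
        kept, reason = apply_pt_filters(
            ["Off-label use"], "golimumab", self.config, DEFAULT_PT_SOC)
        assert kept == ["Off-label use"] and reason is None


def test_curate_tiny_quarter(tiny_quarter_dir):
    bundle = read_quarter(tiny_quarter_dir, "2012Q3")
    result = curate([bundle], DEFAULT_PT_SOC)
    assert result.conserved()
    by_pid = {c.primaryid: c for c in result.cases}
    assert set(by_pid) == {"1001", "1002", "1003"}
    c = by_pid["1001"]
    assert c.agent == "adalimumab"       # PS=HUMIRA; C=ASPIRIN ignored
    assert c.age_years == 12.0 and c.stratum == "12-17"
    assert c.outcomes == {"HO", "LT"}
    assert str(c.therapy_start) == "2012-06-01"
    assert by_pid["1002"].age_years == pytest.approx(0.5)  # 6 months
    assert by_pid["1002"].agent == "infliximab"
    assert by_pid["1003"].reporter_class == "Other health professional"


def test_curate_pre_approval_reports_dropped(tmp_path):
    q = tmp_path / "2008Q4"
    q.mkdir()
    (q / "DEMO08Q4.txt").write_text(
        "PRIMARYID$CASEID$FDA_DT$EVENT_DT$AGE$AGE_COD$SEX$OCCP_COD\n"
        "1$1$20081101$$10$YR$F$MD\n")
    (q / "DRUG08Q4.txt").write_text(
        "PRIMARYID$CASEID$DRUG_SEQ$ROLE_COD$DRUGNAME\n1$1$1$PS$SIMPONI\n")
    (q / "REAC08Q4.txt").write_text("PRIMARYID$CASEID$PT\n1$1$Pyrexia\n")
    bundle = read_quarter(q, "2008Q4")
    result = curate([bundle], DEFAULT_PT_SOC)
    assert result.attrition["pre_approval"] == 1
    assert result.cases == [] and result.conserved()


def test_curate_report_without_ps_target_excluded(tmp_path):
    q = tmp_path / "2010Q1"
    q.mkdir()
    (q / "DEMO10Q1.txt").write_text(
        "PRIMARYID$CASEID$FDA_DT$EVENT_DT$AGE$AGE_COD$SEX$OCCP_COD\n"
        "1$1$20100101$$10$YR$F$MD\n")
    (q / "DRUG10Q1.txt").write_text(
        "PRIMARYID$CASEID$DRUG_SEQ$ROLE_COD$DRUGNAME\n"
        "1$1$1$PS$ASPIRIN\n1$1$2$C$REMICADE\n")
    (q / "REAC10Q1.txt").write_text("PRIMARYID$CASEID$PT\n1$1$Pyrexia\n")
    result = curate([read_quarter(q, "2010Q1")], DEFAULT_PT_SOC)
    assert result.attrition["no_ps_target_agent"] == 1
    assert result.cases == []
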