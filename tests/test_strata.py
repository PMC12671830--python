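import random

import pytest

from tnfvigil.curation import CaseReport
from tnfvigil.dispro import CLASS_LABEL, SignalResult
from tnfvigil.ingest import ParsedDate
from tnfvigil.reporting import proportion, round_half_away
from tnfvigil.strata import (demographics_table, onset_analysis, onset_days,
                             onset_summary, soc_aggregate, stratum_compare)


def _case(agent="infliximab", sex="F", age=10.0, stratum="4-11",
          reporter="Physician", outcomes=(), pts=("Pyrexia",),
          socs=("General disorders and administration site conditions",),
          start=None, event=None):
    return CaseReport(primaryid="1", caseid="1", fda_dt=None,
                      event_dt=event, age_years=age, stratum=stratum,
                      sex=sex, reporter_class=reporter, agent=agent,
                      pts=list(pts), socs=list(socs), outcomes=set(outcomes),
                      therapy_start=start)


class TestDemographics:
    def test_sex_percentages(self):
        cases = [_case(sex="F"), _case(sex="F"), _case(sex="M"),
                 _case(sex="UNK")]
        summary = demographics_table(cases)
        assert summary.counts.loc[("gender", "F"), CLASS_LABEL] == 2
        assert summary.percents.loc[("gender", "F"), CLASS_LABEL] == 50.0

    def test_multi_outcome_case_counts_in_each_category(self):
        summary = demographics_table([_case(outcomes={"HO", "LT"})])
        assert summary.counts.loc[("outcome", "Hospitalization"), CLASS_LABEL] == 1
        assert summary.counts.loc[("outcome", "Life-Threatening"), CLASS_LABEL] == 1
        assert summary.counts.loc[("severe", "Severe outcome"), CLASS_LABEL] == 1

    def test_no_outcome_counts_as_unknown(self):
        summary = demographics_table([_case(outcomes=())])
        assert summary.counts.loc[("outcome", "Unknown"), CLASS_LABEL] == 1
        assert summary.counts.loc[("severe", "Severe outcome"), CLASS_LABEL] == 0

    def test_empty_cohort_all_zero(self):
        summary = demographics_table([])
        assert (summary.counts.to_numpy() == 0).all()

    def test_percent_blocks_rederive_from_counts(self):
        cases = [_case(sex=s) for s in ["F"] * 7 + ["M"] * 5 + ["UNK"]]
        summary = demographics_table(cases)
        for (block, cat), row in summary.counts.iterrows():
            n = row[CLASS_LABEL]
            assert summary.percents.loc[(block, cat), CLASS_LABEL] == \
                proportion(int(n), 13, 1)


class TestSocAggregate:
    def _sig(self, pt, drug, n=5, flag=True):
        return SignalResult(drug=drug, pt=pt, soc="", n=n, ror=2.0,
                            ci_low=1.5, ci_high=3.0, chi2=9.0, is_signal=flag)

    def test_groups_signal_pts_by_soc(self):
        mapping = {"a": "SOC1", "b": "SOC1", "c": "SOC1"}
        out = soc_aggregate([self._sig(p, "d1") for p in "abc"], mapping)
        row = out.set_index("soc").loc["SOC1"]
        assert row["distinct_signal_pts"] == 3 and row["signal_rows"] == 3

    def test_unmapped_pt_bucket(self):
        out = soc_aggregate([self._sig("mystery", "d1")], {})
        assert list(out["soc"]) == ["UNMAPPED"]

    def test_same_pt_flagged_by_two_drugs(self):
        out = soc_aggregate([self._sig("a", "d1"), self._sig("a", "d2")],
                            {"a": "SOC1"})
        row = out.set_index("soc").loc["SOC1"]
        assert row["signal_rows"] == 2 and row["distinct_signal_pts"] == 1

    def test_unflagged_rows_ignored(self):
        out = soc_aggregate([self._sig("a", "d1", flag=False)], {"a": "SOC1"})
        assert out.empty


class TestStratumCompare:
    def _cohort(self):
        cases = ([_case(stratum="4-11", socs=("Gastro",), pts=("p1",))] * 4
                 + [_case(stratum="4-11", socs=("Infect",), pts=("p2",))] * 6
                 + [_case(stratum="12-17", socs=("Gastro",), pts=("p1",))] * 3)
        return cases

    def test_soc_proportions(self):
        soc_table, _ = stratum_compare(self._cohort())
        row = soc_table.set_index(["stratum", "soc"]).loc[("4-11", "Gastro")]
        assert row["case_count"] == 4 and row["proportion_pct"] == 40.0

    def test_top_ranking_short_list_no_padding(self):
        _, top = stratum_compare(self._cohort())
        sub = top[top["stratum"] == "4-11"]
        assert list(sub["pt"]) == ["p2", "p1"]  # 6 > 4, no padding to 10

    def test_order_invariance(self):
        cohort = self._cohort()
        shuffled = cohort[:]
        random.Random(1).shuffle(shuffled)
        a, _ = stratum_compare(cohort)
        b, _ = stratum_compare(shuffled)
        assert a.equals(b)


class TestOnset:
    def test_day_difference(self):
        days, reason = onset_days(ParsedDate(2010, 4, 1), ParsedDate(2010, 4, 11))
        assert days == 10 and reason is None

    def test_partial_precision_is_missing_timeline(self):
        assert onset_days(ParsedDate(2010, 4), ParsedDate(2010, 4, 11)) == \
            (None, "missing_timeline")
        assert onset_days(None, ParsedDate(2010, 4, 11)) == \
            (None, "missing_timeline")

    def test_event_before_start_is_implausible(self):
        days, reason = onset_days(ParsedDate(2010, 4, 11), ParsedDate(2010, 4, 1))
        assert days is None and reason == "implausible"

    def test_summary_median_quartiles(self):
        s = onset_summary([1, 2, 3, 4, 100])
        assert s.median == 3 and s.q1 == 2 and s.q3 == 4

    def test_summary_bins(self):
        s = onset_summary([10, 400])
        assert s.bins["(0,30]"] == 1 and s.bins["(360,inf)"] == 1
        assert sum(s.bins.values()) == s.n_with_onset

    def test_empty_summary(self):
        s = onset_summary([])
        assert s.n_with_onset == 0 and s.median is None

    def test_analysis_exclusion_accounting(self):
        cases = [
            _case(start=ParsedDate(2010, 1, 1), event=ParsedDate(2010, 3, 1)),
            _case(start=ParsedDate(2010, 1), event=ParsedDate(2010, 3, 1)),
            _case(start=ParsedDate(2010, 5, 1), event=ParsedDate(2010, 3, 1)),
        ]
        pooled = onset_analysis(cases)[0]
        assert pooled.n_with_onset == 1
        assert pooled.excluded == {"missing_timeline": 1, "implausible": 1}
        assert (pooled.n_with_onset + sum(pooled.excluded.values())
                == len(cases))


class TestRounding:
    @pytest.mark.parametrize("num, den, dec, expected", [
        (852, 4520, 2, 18.85),
        (206, 266, 1, 77.4),
        (0, 7, 1, 0.0),
        (1, 8, 1, 12.5),
        (1, 1000, 1, 0.1),   # 0.05 exactly -> away from zero
    ])
    def test_proportion(self, num, den, dec, expected):
        assert proportion(num, den, dec) == expected

    def test_half_away_from_zero_both_signs(self):
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(-0.05, 1) == -0.1
        assert round_half_away(2.345, 2) == 2.35

    def test_zero_denominator_undefined(self):
        with pytest.raises(ValueError):
            proportion(1, 0)
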