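import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from tnfvigil.dispro import (CLASS_LABEL, ContingencyTable, SignalCriteria,
                             SignalResult, build_table, chi_square,
                             classify_signal, prioritize, ror_ci, rsr,
                             signal_table)


def _case(agent, pts):
    return SimpleNamespace(agent=agent, pts=list(pts))


class TestBuildTable:
    cases = ([_case("X", ["q", "r"]), _case("X", ["q"]), _case("X", ["r"])]
             + [_case("Y", ["q"])] + [_case("Y", ["r"])] * 2
             + [_case("Y", [])] * 2)

    def test_within_class_hand_enumeration(self):
        # 3 reports of X (2 with q), 5 of Y (1 with q)
        t = build_table(self.cases, "X", "q")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 4)

    def test_duplicate_pt_on_one_report_counts_once(self):
        t = build_table([_case("X", ["q", "q"]), _case("Y", ["r"])], "X", "q")
        assert t.a == 1

    def test_class_target_needs_external_background(self):
        with pytest.raises(ValueError, match="comparator"):
            build_table(self.cases, CLASS_LABEL, "q")
        t = build_table(self.cases, CLASS_LABEL, "q",
                        comparator_mode="external_background",
                        background=({"q": 30}, 1000))
        assert (t.a, t.b, t.c, t.d) == (3, 5, 30, 970)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestRorCi:
    def test_symmetric_table_is_null(self):
        ror, lo, hi, _ = ror_ci(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_computed_example(self):
        # se = sqrt(0.1 + 1/90 + 0.1 + 1/900) = 0.46067 -> factor 2.4669
        ror, lo, hi, reason = ror_ci(ContingencyTable(10, 90, 10, 900))
        assert reason is None
        assert ror == pytest.approx(10.0)
        assert lo == pytest.approx(4.054, abs=5e-3)
        assert hi == pytest.approx(24.67, abs=5e-2)

    def test_zero_cell_undefined_without_correction(self):
        ror, lo, hi, reason = ror_ci(ContingencyTable(0, 10, 5, 100))
        assert (ror, lo, hi) == (None, None, None)
        assert reason == "zero cell"

    def test_haldane_correction_behind_flag(self):
        ror, lo, hi, reason = ror_ci(ContingencyTable(0, 10, 5, 100),
                                     haldane=True)
        assert reason is None
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))


class TestChiSquare:
    def test_independent_table_is_zero(self):
        assert chi_square(ContingencyTable(5, 5, 5, 5))[0] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # 1010 * 8100^2 / (100 * 910 * 20 * 990)
        stat, reason = chi_square(ContingencyTable(10, 90, 10, 900))
        assert reason is None
        assert stat == pytest.approx(36.778, abs=1e-3)

    def test_transpose_invariance(self):
        t = ContingencyTable(7, 13, 2, 41)
        swapped = ContingencyTable(7, 2, 13, 41)
        assert chi_square(t)[0] == pytest.approx(chi_square(swapped)[0])

    def test_zero_margin_undefined(self):
        stat, reason = chi_square(ContingencyTable(0, 0, 5, 9))
        assert stat is None and reason == "zero margin"

    def test_matches_scipy_with_and_without_yates(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            obs = [[a, b], [c, d]]
            assert chi_square(t)[0] == pytest.approx(
                chi2_contingency(obs, correction=False)[0], rel=1e-10)
            assert chi_square(t, yates=True)[0] == pytest.approx(
                chi2_contingency(obs, correction=True)[0], rel=1e-10)


class TestProperties:
    rng = np.random.default_rng(11)

    def tables(self, n=200):
        for _ in range(n):
            a, b, c, d = self.rng.integers(1, 50, size=4)
            yield ContingencyTable(int(a), int(b), int(c), int(d))

    def test_reciprocity(self):
        for t in self.tables():
            ror_fwd = ror_ci(t)[0]
            ror_rev = ror_ci(ContingencyTable(t.c, t.d, t.a, t.b))[0]
            assert ror_fwd * ror_rev == pytest.approx(1.0, rel=1e-12)

    def test_ci_log_symmetry(self):
        for t in self.tables():
            ror, lo, hi, _ = ror_ci(t)
            assert (math.log(hi) - math.log(ror)
                    == pytest.approx(math.log(ror) - math.log(lo), rel=1e-9))

    def test_monotone_in_a(self):
        t = ContingencyTable(5, 40, 7, 80)
        rors = [ror_ci(ContingencyTable(a, t.b, t.c, t.d))[0]
                for a in range(1, 30)]
        assert all(x < y for x, y in zip(rors, rors[1:]))


class TestSignals:
    def _result(self, n, ror, ci_low, chi2):
        width = ror / ci_low if ci_low else 1.0
        return SignalResult(drug="x", pt="p", soc="s", n=n, ror=ror,
                            ci_low=ci_low,
                            ci_high=ror * width if ci_low else None,
                            chi2=chi2)

    def test_reported_top_signal_flags(self):
        # strongest reported pediatric injection-site signal
        assert classify_signal(self._result(3134, 10.09, 9.66, 3000.0))

    def test_min_cases_rule(self):
        assert not classify_signal(self._result(2, 50.0, 5.0, 100.0))

    def test_ci_rule(self):
        assert not classify_signal(self._result(100, 1.5, 0.99, 10.0))

    def test_undefined_never_flags(self):
        res = SignalResult(drug="x", pt="p", soc="s", n=10, ror=None,
                           ci_low=None, ci_high=None, chi2=None,
                           undefined_reason="zero cell")
        assert not classify_signal(res)

    def test_tightening_criteria_never_adds_signals(self):
        rng = np.random.default_rng(3)
        base = SignalCriteria()
        tighter = [SignalCriteria(min_cases=5),
                   SignalCriteria(require_chi2_gt=8.0),
                   SignalCriteria(require_ror_gt=2.0)]
        for _ in range(200):
            res = self._result(int(rng.integers(0, 10)),
                               float(rng.uniform(0.2, 5)),
                               float(rng.uniform(0.5, 3)),
                               float(rng.uniform(0, 10)))
            for crit in tighter:
                assert classify_signal(res, crit) <= classify_signal(res, base)


class TestRsr:
    def test_reported_pediatric_rsr(self):
        assert rsr(852, 4520) == pytest.approx(18.85, abs=5e-3)

    def test_zero_signals(self):
        assert rsr(0, 100) == 0.0

    def test_all_age_rsr(self):
        assert rsr(2944, 14002) == pytest.approx(21.03, abs=5e-3)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rsr(1, 0)


class TestPrioritize:
    def _sig(self, pt, drug, n, flag=True):
        return SignalResult(drug=drug, pt=pt, soc="s", n=n, ror=2.0,
                            ci_low=1.5, ci_high=3.0, chi2=9.0, is_signal=flag)

    def test_volume_is_primary_key(self):
        ranked = prioritize([self._sig("a", "d1", 5), self._sig("b", "d1", 10)])
        assert [s.pt for s in ranked] == ["b", "a"]

    def test_pan_class_recurrence_is_secondary_key(self):
        sigs = [self._sig("multi", "d1", 5), self._sig("multi", "d2", 5),
                self._sig("multi", "d3", 5), self._sig("solo", "d4", 5)]
        ranked = prioritize(sigs)
        assert [s.pt for s in ranked[:3]] == ["multi"] * 3

    def test_alphabetical_tiebreak(self):
        ranked = prioritize([self._sig("zeta", "d1", 5), self._sig("alpha", "d2", 5)])
        assert [s.pt for s in ranked] == ["alpha", "zeta"]


def test_signal_table_consistent_with_build_table():
    cases = ([_case("X", ["q", "r"])] * 4 + [_case("X", ["r"])] * 6
             + [_case("Y", ["q"])] * 2 + [_case("Y", ["s"])] * 8)
    rows = {(s.drug, s.pt): s for s in signal_table(cases, {"q": "SOC1"})}
    t = build_table(cases, "X", "q")
    s = rows[("X", "q")]
    assert (s.table.a, s.table.b, s.table.c, s.table.d) == (t.a, t.b, t.c, t.d)
    assert s.n == t.a and s.soc == "SOC1"
    assert rows[("Y", "s")].undefined_reason == "zero cell"
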