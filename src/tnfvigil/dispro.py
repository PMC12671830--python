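"""Disproportionality analysis: fourfold tables, ROR, 95% CI, chi-square, signals.

The reporting odds ratio ROR = (a*d)/(b*c) is computed on the 2x2 table

    =============  ============  =================
                   target event  all other events
    target drug         a               b
    comparators         c               d
    =============  ============  =================

with a Woolf (log-normal) confidence interval
``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` and a Pearson
chi-square on the same table.  Counting is report level: a report listing a
preferred term twice contributes one to ``a``.

A (drug, event) pair is flagged as a signal when it has at least
``min_cases`` reports, the lower CI bound exceeds 1 and chi-square exceeds 4
(both thresholds configurable; an optional ROR threshold is off by default).
Zero-cell tables are reported as undefined — no Haldane-Anscombe 0.5
correction unless explicitly requested.  No multiple-testing adjustment is
applied: flags are screening hypotheses, not confirmed associations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ContingencyTable",
    "SignalCriteria",
    "SignalResult",
    "build_table",
    "ror_ci",
    "chi_square",
    "classify_signal",
    "rsr",
    "prioritize",
    "signal_table",
    "signals_frame",
    "CLASS_LABEL",
]

#: label for pooled class-level questions (all five agents together)
CLASS_LABEL = "TNF-alpha inhibitors"


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold report counts for one (drug, event, comparator) question."""

    a: int  # target drug, target event
    b: int  # target drug, other events
    c: int  # comparator, target event
    d: int  # comparator, other events

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalCriteria:
    """Signal definition: n >= 3, lower 95% CI > 1 and chi-square > 4."""

    min_cases: int = 3
    require_ci_low_gt_1: bool = True
    require_chi2_gt: Optional[float] = 4.0
    require_ror_gt: Optional[float] = None


@dataclass
class SignalResult:
    """One drug x preferred-term row of the signal table."""

    drug: str
    pt: str
    soc: str
    n: int
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    chi2: Optional[float]
    is_signal: bool = False
    undefined_reason: Optional[str] = None
    table: Optional[ContingencyTable] = None


def build_table(cases: Iterable, drug: str, pt: str,
                comparator_mode: str = "within_class",
                background: Optional[tuple[Mapping[str, int], int]] = None
                ) -> ContingencyTable:
    """Count the fourfold table for one (drug, event) question.

    ``cases`` is any iterable of objects with ``agent`` and ``pts``
    attributes (curated :class:`~tnfvigil.curation.CaseReport` objects or
    lighter stand-ins).  With ``comparator_mode="within_class"`` the
    comparator universe is the curated reports of all other agents; with
    ``"external_background"`` it is a user-supplied ``({pt: event_count},
    total_count)`` pair, which is also the only way to ask class-level
    (pooled) questions.
    """
    if comparator_mode not in ("within_class", "external_background"):
        raise ValueError(f"unknown comparator_mode {comparator_mode!r}")
    is_class = drug == CLASS_LABEL
    a = b = c = d = 0
    for case in cases:
        target = is_class or case.agent == drug
        has_pt = pt in case.pts
        if target:
            if has_pt:
                a += 1
            else:
                b += 1
        elif comparator_mode == "within_class":
            if has_pt:
                c += 1
            else:
                d += 1
    if comparator_mode == "within_class":
        if is_class:
            raise ValueError(
                "class-level target has no within-class comparator; "
                "supply external background counts")
        if c + d == 0:
            raise ValueError("comparator universe is empty")
    else:
        if background is None:
            raise ValueError("external_background mode requires background")
        events, total = background
        c = int(events.get(pt, 0))
        d = int(total) - c
        if c + d <= 0:
            raise ValueError("comparator universe is empty")
    return ContingencyTable(a, b, c, d)


def ror_ci(table: ContingencyTable, z: float = 1.96,
           haldane: bool = False
           ) -> tuple[Optional[float], Optional[float], Optional[float], Optional[str]]:
    """Reporting odds ratio with Woolf CI; zero cells -> undefined.

    Returns ``(ror, ci_low, ci_high, undefined_reason)``.  With
    ``haldane=True`` a 0.5 continuity correction is added to every cell of a
    zero-cell table instead of declaring it undefined.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if table.has_zero_cell():
        if not haldane:
            return None, None, None, "zero cell"
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    return (ror, math.exp(log_ror - z * se), math.exp(log_ror + z * se), None)


def chi_square(table: ContingencyTable, yates: bool = False
               ) -> tuple[Optional[float], Optional[str]]:
    """Pearson chi-square on the 2x2 table: N(ad-bc)^2 / row/col margins.

    Undefined (None) when any margin is zero.  ``yates=True`` applies the
    continuity correction |ad-bc| -> max(|ad-bc| - N/2, 0).
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if n == 0 or min(margins) == 0:
        return None, "zero margin"
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])
    return stat, None


def classify_signal(result: SignalResult,
                    criteria: SignalCriteria = SignalCriteria()) -> bool:
    """Apply the signal definition; undefined ROR never flags."""
    if result.ror is None or result.ci_low is None:
        return False
    if result.n < criteria.min_cases:
        return False
    if criteria.require_ci_low_gt_1 and not result.ci_low > 1.0:
        return False
    if criteria.require_chi2_gt is not None:
        if result.chi2 is None or not result.chi2 > criteria.require_chi2_gt:
            return False
    if criteria.require_ror_gt is not None and not result.ror > criteria.require_ror_gt:
        return False
    return True


def rsr(signal_count: int, pt_count: int) -> float:
    """Risk-signal detection ratio: signal PTs / all observed PTs, in percent."""
    if pt_count <= 0:
        raise ValueError("pt_count must be positive")
    return 100.0 * signal_count / pt_count


def prioritize(signals: Sequence[SignalResult]) -> list[SignalResult]:
    """Rank signal rows for reporting.

    Primary key: report volume n (descending); secondary: how many agents
    flag the same preferred term (descending — pan-class recurrence);
    final tiebreak: preferred term alphabetical.  Stable and deterministic.
    """
    flags_per_pt: dict[str, int] = {}
    for s in signals:
        if s.is_signal:
            flags_per_pt[s.pt] = flags_per_pt.get(s.pt, 0) + 1
    return sorted(signals,
                  key=lambda s: (-s.n, -flags_per_pt.get(s.pt, 0), s.pt, s.drug))


def signal_table(cases: Sequence, pt_to_soc: Mapping[str, str],
                 criteria: SignalCriteria = SignalCriteria(),
                 comparator_mode: str = "within_class",
                 background: Optional[tuple[Mapping[str, int], int]] = None,
                 drugs: Optional[Sequence[str]] = None,
                 z: float = 1.96) -> list[SignalResult]:
    """Compute a SignalResult for every (drug, observed PT) pair.

    For each drug, the preferred-term universe is the set of PTs observed at
    least once on that drug's reports (rows Table-2 style).  Report-level
    counting throughout.
    """
    if drugs is None:
        drugs = sorted({c.agent for c in cases})
    # precount once: per drug, reports per pt and totals
    per_drug_pt: dict[str, dict[str, int]] = {dr: {} for dr in drugs}
    totals: dict[str, int] = {dr: 0 for dr in drugs}
    all_pt: dict[str, int] = {}
    grand_total = 0
    for case in cases:
        grand_total += 1
        for pt in set(case.pts):
            all_pt[pt] = all_pt.get(pt, 0) + 1
        if case.agent in per_drug_pt:
            totals[case.agent] += 1
            for pt in set(case.pts):
                per_drug_pt[case.agent][pt] = per_drug_pt[case.agent].get(pt, 0) + 1

    results: list[SignalResult] = []
    for drug in drugs:
        for pt, a in sorted(per_drug_pt[drug].items()):
            b = totals[drug] - a
            if comparator_mode == "within_class":
                c = all_pt.get(pt, 0) - a
                d = (grand_total - totals[drug]) - c
            else:
                if background is None:
                    raise ValueError("external_background mode requires background")
                events, total = background
                c = int(events.get(pt, 0))
                d = int(total) - c
            table = ContingencyTable(a, b, c, d)
            ror, lo, hi, reason = ror_ci(table, z=z)
            chi2, chi_reason = chi_square(table)
            res = SignalResult(drug=drug, pt=pt,
                               soc=pt_to_soc.get(pt, "UNMAPPED"),
                               n=a, ror=ror, ci_low=lo, ci_high=hi,
                               chi2=chi2,
                               undefined_reason=reason or chi_reason,
                               table=table)
            res.is_signal = classify_signal(res, criteria)
            results.append(res)
    return results


def signals_frame(signals: Sequence[SignalResult]) -> pd.DataFrame:
    """Tabular view of signal rows; undefined cells serialise as '/'."""
    rows = []
    for s in signals:
        rows.append({
            "drug": s.drug, "soc": s.soc, "pt": s.pt, "n": s.n,
            "ror": "/" if s.ror is None else round(s.ror, 4),
            "ci_low": "/" if s.ci_low is None else round(s.ci_low, 4),
            "ci_high": "/" if s.ci_high is None else round(s.ci_high, 4),
            "chi2": "/" if s.chi2 is None else round(s.chi2, 4),
            "is_signal": s.is_signal,
        })
    return pd.DataFrame(rows, columns=["drug", "soc", "pt", "n", "ror",
                                       "ci_low", "ci_high", "chi2",
                                       "is_signal"])
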