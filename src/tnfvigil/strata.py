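"""Descriptive summaries: demographics, SOC aggregation, age strata, onset times.

These mirror the standard reporting blocks of a spontaneous-report safety
study: a demographics/outcomes characteristics table (counts with percents
per agent and pooled), system-organ-class roll-ups of the signal table,
age-stratum comparisons with top-10 event rankings, and time-to-onset
(therapy start to event onset) medians, IQRs and 30-day histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import AGENTS, STRATA, CaseReport
from .dispro import CLASS_LABEL, SignalResult
from .ingest import ParsedDate
from .reporting import proportion

__all__ = [
    "DemographicsSummary",
    "OnsetSummary",
    "demographics_table",
    "soc_aggregate",
    "stratum_compare",
    "onset_days",
    "onset_summary",
    "onset_analysis",
    "ONSET_BIN_EDGES",
]

#: outcome-code -> reporting category (FAERS OUTC is multi-valued; the
#: categories are treated as non-exclusive counts over cases)
OUTCOME_CATEGORIES = (
    ("Death", ("DE",)),
    ("Life-Threatening", ("LT",)),
    ("Disability", ("DS",)),
    ("Hospitalization", ("HO",)),
    ("Other", ("CA", "RI", "OT")),
)
#: severe outcome definition: death, life-threatening, disability or
#: hospitalization
SEVERE_CODES = frozenset({"DE", "LT", "DS", "HO"})

REPORTER_ORDER = ("Physician", "Pharmacist", "Other health professional",
                  "Consumer", "Unknown/other")

#: 30-day onset bins up to 360 days, then an open tail
ONSET_BIN_EDGES = tuple(range(0, 361, 30))


@dataclass
class DemographicsSummary:
    """Characteristics table: counts and percents per agent and pooled."""

    counts: pd.DataFrame    # MultiIndex (block, category) x agent columns
    percents: pd.DataFrame  # same shape, percent of each agent's total
    totals: dict[str, int]

    def formatted(self) -> pd.DataFrame:
        """'count (pct)' strings, publication style."""
        out = self.counts.astype(object).copy()
        for col in out.columns:
            out[col] = [f"{int(c)}({p})" for c, p in
                        zip(self.counts[col], self.percents[col])]
        return out


def _blocks(case: CaseReport) -> list[tuple[str, str]]:
    entries = [("gender", case.sex if case.sex in ("M", "F") else "UNK"),
               ("age_stratum", case.stratum or "missing"),
               ("reporter", case.reporter_class)]
    for label, codes in OUTCOME_CATEGORIES:
        if case.outcomes & set(codes):
            entries.append(("outcome", label))
    if not case.outcomes:
        entries.append(("outcome", "Unknown"))
    if case.outcomes & SEVERE_CODES:
        entries.append(("severe", "Severe outcome"))
    return entries


def demographics_table(cases: Sequence[CaseReport],
                       agents: Sequence[str] = AGENTS,
                       decimals: int = 1) -> DemographicsSummary:
    """Tabulate sex, strata, reporter class and outcomes per agent + pooled.

    Outcome rows are non-exclusive: a case with outcomes {HO, LT} counts in
    both the Hospitalization and Life-Threatening rows.  Percents use the
    agent's case total as denominator, rounded half away from zero.
    """
    index = ([("gender", g) for g in ("M", "F", "UNK")]
             + [("age_stratum", s) for s in STRATA]
             + [("reporter", r) for r in REPORTER_ORDER]
             + [("outcome", lbl) for lbl, _ in OUTCOME_CATEGORIES]
             + [("outcome", "Unknown"), ("severe", "Severe outcome")])
    cols = [CLASS_LABEL, *agents]
    counts = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(index),
                          columns=cols)
    totals = {col: 0 for col in cols}
    for case in cases:
        case_cols = [CLASS_LABEL]
        if case.agent in agents:
            case_cols.append(case.agent)
        for col in case_cols:
            totals[col] += 1
        for key in _blocks(case):
            if key in counts.index:
                counts.loc[key, case_cols] += 1
    percents = counts.astype(float).copy()
    for col in cols:
        denom = totals[col]
        percents[col] = [proportion(int(c), denom, decimals) if denom else 0.0
                         for c in counts[col]]
    return DemographicsSummary(counts=counts, percents=percents, totals=totals)


def soc_aggregate(signals: Sequence[SignalResult],
                  pt_to_soc: Mapping[str, str]) -> pd.DataFrame:
    """Roll the signal table up to system organ classes.

    Per SOC: number of flagged (drug, PT) signal rows, number of distinct
    flagged PTs, and total reports (sum of n over flagged rows).  PTs absent
    from the mapping land in an "UNMAPPED" bucket.
    """
    rows: dict[str, dict] = {}
    for s in signals:
        if not s.is_signal:
            continue
        soc = pt_to_soc.get(s.pt, "UNMAPPED")
        agg = rows.setdefault(soc, {"soc": soc, "signal_rows": 0,
                                    "distinct_pts": set(), "reports": 0})
        agg["signal_rows"] += 1
        agg["distinct_pts"].add(s.pt)
        agg["reports"] += s.n
    out = [{"soc": soc, "signal_rows": agg["signal_rows"],
            "distinct_signal_pts": len(agg["distinct_pts"]),
            "reports": agg["reports"]}
           for soc, agg in sorted(rows.items())]
    return pd.DataFrame(out, columns=["soc", "signal_rows",
                                      "distinct_signal_pts", "reports"])


def stratum_compare(cases: Sequence[CaseReport],
                    signals: Sequence[SignalResult] = (),
                    top_n: int = 10,
                    decimals: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age-stratum SOC proportions and per-stratum top event ranking.

    Returns ``(soc_table, top_table)``.  SOC proportions use the stratum
    case total as denominator (cases may span several SOCs, so proportions
    need not sum to 100).  The ranking lists the ``top_n`` most frequent
    preferred terms per stratum (ties broken alphabetically); when
    ``signals`` is given, PTs are restricted to risk-prioritized
    (signal-flagged) terms.
    """
    flagged = {s.pt for s in signals if s.is_signal}
    per_stratum_total = {s: 0 for s in STRATA}
    soc_counts: dict[tuple[str, str], int] = {}
    pt_counts: dict[tuple[str, str], int] = {}
    for case in cases:
        st = case.stratum
        if st not in per_stratum_total:
            continue
        per_stratum_total[st] += 1
        for soc in set(case.socs):
            soc_counts[(st, soc)] = soc_counts.get((st, soc), 0) + 1
        for pt in set(case.pts):
            if flagged and pt not in flagged:
                continue
            pt_counts[(st, pt)] = pt_counts.get((st, pt), 0) + 1

    soc_rows = []
    for (st, soc), n in sorted(soc_counts.items()):
        total = per_stratum_total[st]
        soc_rows.append({"stratum": st, "soc": soc, "case_count": n,
                         "stratum_total": total,
                         "proportion_pct": proportion(n, total, decimals)})
    soc_table = pd.DataFrame(
        soc_rows, columns=["stratum", "soc", "case_count", "stratum_total",
                           "proportion_pct"])

    top_rows = []
    for st in STRATA:
        ranked = sorted(((pt, n) for (s, pt), n in pt_counts.items()
                         if s == st), key=lambda kv: (-kv[1], kv[0]))
        for rank, (pt, n) in enumerate(ranked[:top_n], start=1):
            top_rows.append({"stratum": st, "rank": rank, "pt": pt,
                             "case_count": n})
    top_table = pd.DataFrame(top_rows,
                             columns=["stratum", "rank", "pt", "case_count"])
    return soc_table, top_table


def onset_days(therapy_start: Optional[ParsedDate],
               event_dt: Optional[ParsedDate]) -> tuple[Optional[int], Optional[str]]:
    """Days from therapy start to event onset; both dates must be day-precise.

    Returns ``(days, exclusion_reason)`` — reasons are "missing_timeline"
    (absent or partial dates, no imputation) and "implausible" (event
    before therapy start).
    """
    if (therapy_start is None or event_dt is None
            or therapy_start.precision != "day"
            or event_dt.precision != "day"):
        return None, "missing_timeline"
    delta = (event_dt.to_date() - therapy_start.to_date()).days
    if delta < 0:
        return None, "implausible"
    return delta, None


@dataclass
class OnsetSummary:
    """Median/IQR and 30-day histogram of time-to-onset values."""

    label: str
    n_with_onset: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    bins: dict[str, int] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)


def _bin_label(lo: int, hi: Optional[int]) -> str:
    return f"({lo},{hi}]" if hi is not None else f"({lo},inf)"


def onset_summary(values: Iterable[float], label: str = "all",
                  excluded: Optional[dict[str, int]] = None) -> OnsetSummary:
    """Summarise onset days: quartiles (linear interpolation) + 30-day bins.

    Bins are left-open/right-closed: (0,30], (30,60], ..., (330,360],
    (360,inf); day-0 onsets fall into the first bin.
    """
    vals = np.asarray(sorted(values), dtype=float)
    bins: dict[str, int] = {}
    edges = ONSET_BIN_EDGES
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (vals > lo) & (vals <= hi)
        if lo == 0:
            mask |= vals == 0  # same-day onset counted in the first bin
        bins[_bin_label(lo, hi)] = int(mask.sum())
    bins[_bin_label(edges[-1], None)] = int((vals > edges[-1]).sum())
    if vals.size == 0:
        return OnsetSummary(label, 0, None, None, None, bins,
                            dict(excluded or {}))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return OnsetSummary(label, int(vals.size), float(med), float(q1),
                        float(q3), bins, dict(excluded or {}))


def onset_analysis(cases: Sequence[CaseReport],
                   agents: Sequence[str] = AGENTS) -> list[OnsetSummary]:
    """Per-agent and pooled onset summaries with exclusion accounting.

    For every curated case the earliest day-precision therapy start of the
    suspect drug and the event onset date yield a day count; cases with
    partial or absent dates are tallied as missing timelines, events before
    therapy start as implausible, so
    n_input = n_with_onset + missing + implausible.
    """
    per_agent: dict[str, list[float]] = {a: [] for a in agents}
    per_agent_excl: dict[str, dict[str, int]] = {
        a: {"missing_timeline": 0, "implausible": 0} for a in agents}
    pooled: list[float] = []
    pooled_excl = {"missing_timeline": 0, "implausible": 0}
    for case in cases:
        days, reason = onset_days(case.therapy_start, case.event_dt)
        target = per_agent.get(case.agent)
        if days is None:
            pooled_excl[reason] += 1
            if target is not None:
                per_agent_excl[case.agent][reason] += 1
            continue
        pooled.append(days)
        if target is not None:
            target.append(days)
    out = [onset_summary(pooled, label=CLASS_LABEL, excluded=pooled_excl)]
    for agent in agents:
        out.append(onset_summary(per_agent[agent], label=agent,
                                 excluded=per_agent_excl[agent]))
    return out
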