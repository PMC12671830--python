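"""Era-split sensitivity analysis.

Reporting patterns drift over two decades of spontaneous reports, so the
cohort is split into an early era (through 2013Q4 by default) and a recent
era (2014Q1 onward), RORs are recomputed per era for the most frequently
reported preferred terms, and the paired per-PT RORs are compared with a
two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curation import CaseReport
from .dispro import SignalCriteria, signal_table

__all__ = [
    "split_eras",
    "WilcoxonResult",
    "paired_wilcoxon",
    "EraComparison",
    "era_comparison",
]

DEFAULT_CUTOFF = "2014Q1"


def _cutoff_key(cutoff_quarter: str) -> tuple[int, int, int]:
    year = int(cutoff_quarter[:4])
    month = (int(cutoff_quarter[5]) - 1) * 3 + 1
    return (year, month, 1)


def split_eras(cases: Sequence[CaseReport],
               cutoff_quarter: str = DEFAULT_CUTOFF
               ) -> tuple[list[CaseReport], list[CaseReport]]:
    """Partition cases by FDA receipt date: before the cutoff quarter vs from it.

    Partial receipt dates are compared at available precision with missing
    components treated as lowest (so a bare "2014" falls in the recent era
    under the default cutoff).  Cases with no receipt date at all go to the
    early era; the partition is exhaustive and disjoint.
    """
    key = _cutoff_key(cutoff_quarter)
    early, recent = [], []
    for case in cases:
        case_key = case.fda_dt.sort_key() if case.fda_dt else (0, 0, 0)
        (early if case_key < key else recent).append(case)
    return early, recent


@dataclass
class WilcoxonResult:
    w: float            # min(T+, T-), the signed-rank statistic
    z: float            # normal approximation with tie + continuity correction
    p: float            # two-sided
    median_diff: float  # median of x - y over all pairs (zeros included)
    n: int              # pairs used after dropping zero differences
    method: str         # "exact" | "normal" | "degenerate"


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped before ranking; tied absolute differences
    get average ranks.  The p-value is exact (full sign enumeration, via
    scipy) when n <= 12 and there are no ties, otherwise a normal
    approximation with tie correction and a 0.5 continuity correction.  All
    differences zero returns W = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d_all = x - y
    median_diff = float(np.median(d_all)) if d_all.size else 0.0
    d = d_all[d_all != 0]
    n = int(d.size)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 1.0, median_diff, 0, "degenerate")

    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    w = min(t_plus, t_minus)

    # normal approximation pieces (reported as Z even in exact mode)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sigma = math.sqrt(sigma2) if sigma2 > 0 else 0.0
    dev = t_plus - mu
    if sigma == 0 or dev == 0:
        z = 0.0
    else:
        z = (dev - math.copysign(0.5, dev)) / sigma  # continuity correction

    has_ties = bool((tie_counts > 1).any())
    if n <= 12 and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        method = "normal"
        p = 2.0 * stats.norm.sf(abs(z)) if sigma > 0 else 1.0
    return WilcoxonResult(w, z, min(p, 1.0), median_diff, n, method)


@dataclass
class EraComparison:
    pt: str
    n_early: int
    ror_early: Optional[float]
    ci_early: tuple[Optional[float], Optional[float]]
    n_recent: int
    ror_recent: Optional[float]
    ci_recent: tuple[Optional[float], Optional[float]]

    @property
    def delta(self) -> Optional[float]:
        if self.ror_early is None or self.ror_recent is None:
            return None
        return self.ror_early - self.ror_recent

    @property
    def ci_overlap(self) -> Optional[bool]:
        lo_e, hi_e = self.ci_early
        lo_r, hi_r = self.ci_recent
        if None in (lo_e, hi_e, lo_r, hi_r):
            return None
        return lo_e <= hi_r and lo_r <= hi_e


def era_comparison(cases: Sequence[CaseReport],
                   cutoff_quarter: str = DEFAULT_CUTOFF,
                   n_top: int = 50,
                   criteria: SignalCriteria = SignalCriteria()
                   ) -> tuple[pd.DataFrame, WilcoxonResult]:
    """Compare class-pooled per-PT RORs between the two eras.

    The ``n_top`` most frequently reported PTs over the pooled cohort are
    treated as paired observations (ties broken alphabetically).  A PT's
    era ROR is the within-class ROR of its *lead agent* — the agent
    reporting that PT most often in the pooled cohort (ties alphabetical) —
    held fixed across eras so both members of a pair measure the same
    drug-event contrast.  Pairs with an undefined ROR in either era are
    excluded from the signed-rank test but still listed.
    """
    from .dispro import ContingencyTable, ror_ci

    pt_counts: dict[str, int] = {}
    lead_counts: dict[str, dict[str, int]] = {}
    for case in cases:
        for pt in set(case.pts):
            pt_counts[pt] = pt_counts.get(pt, 0) + 1
            lead_counts.setdefault(pt, {}).setdefault(case.agent, 0)
            lead_counts[pt][case.agent] += 1
    top = [pt for pt, _ in sorted(pt_counts.items(),
                                  key=lambda kv: (-kv[1], kv[0]))[:n_top]]
    lead_agent = {pt: min(lead_counts[pt],
                          key=lambda ag: (-lead_counts[pt][ag], ag))
                  for pt in top}

    early, recent = split_eras(cases, cutoff_quarter)

    def era_rows(sub: Sequence[CaseReport]) -> dict[str, tuple]:
        """pt -> (n, ror, lo, hi) for the PT's lead agent within this era."""
        totals: dict[str, int] = {}
        per_pt_agent: dict[str, dict[str, int]] = {}
        for case in sub:
            totals[case.agent] = totals.get(case.agent, 0) + 1
            for pt in set(case.pts):
                per_pt_agent.setdefault(pt, {}).setdefault(case.agent, 0)
                per_pt_agent[pt][case.agent] += 1
        grand = sum(totals.values())
        out: dict[str, tuple] = {}
        for pt in top:
            ag = lead_agent[pt]
            counts = per_pt_agent.get(pt, {})
            n_pt = sum(counts.values())
            a = counts.get(ag, 0)
            b = totals.get(ag, 0) - a
            c = n_pt - a
            d = (grand - totals.get(ag, 0)) - c
            if grand == 0 or grand == totals.get(ag, 0):
                out[pt] = (n_pt, None, None, None)
                continue
            ror, lo, hi, _ = ror_ci(ContingencyTable(a, b, c, d))
            out[pt] = (n_pt, ror, lo, hi)
        return out

    rows_e = era_rows(early) if early else {pt: (0, None, None, None) for pt in top}
    rows_r = era_rows(recent) if recent else {pt: (0, None, None, None) for pt in top}

    comparisons = []
    paired_e, paired_r = [], []
    for pt in top:
        n_e, ror_e, lo_e, hi_e = rows_e.get(pt, (0, None, None, None))
        n_r, ror_r, lo_r, hi_r = rows_r.get(pt, (0, None, None, None))
        comp = EraComparison(pt, n_e, ror_e, (lo_e, hi_e),
                             n_r, ror_r, (lo_r, hi_r))
        comparisons.append(comp)
        if ror_e is not None and ror_r is not None:
            paired_e.append(ror_e)
            paired_r.append(ror_r)

    if len(paired_e) >= 2:
        wres = paired_wilcoxon(paired_e, paired_r)
    else:
        wres = WilcoxonResult(0.0, 0.0, 1.0, 0.0, 0, "degenerate")

    frame = pd.DataFrame([{
        "pt": c.pt,
        "n_early": c.n_early,
        "ror_early": "/" if c.ror_early is None else round(c.ror_early, 4),
        "ci_low_early": "/" if c.ci_early[0] is None else round(c.ci_early[0], 4),
        "ci_high_early": "/" if c.ci_early[1] is None else round(c.ci_early[1], 4),
        "n_recent": c.n_recent,
        "ror_recent": "/" if c.ror_recent is None else round(c.ror_recent, 4),
        "ci_low_recent": "/" if c.ci_recent[0] is None else round(c.ci_recent[0], 4),
        "ci_high_recent": "/" if c.ci_recent[1] is None else round(c.ci_recent[1], 4),
        "delta": "/" if c.delta is None else round(c.delta, 4),
        "ci_overlap": "" if c.ci_overlap is None else c.ci_overlap,
    } for c in comparisons])
    return frame, wres
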