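"""Replicate experiments on the synthetic generator.

Self-contained simulation studies used to validate the estimator end to end:
confidence-interval coverage of a planted reporting odds ratio, and the
false-flag rate of the default signal criteria under the null configuration
(no planted associations).  Both consume the generator's case-level output
directly — the question under study is the estimator, not the file
round-trip, which has its own tests.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from .curation import CurationConfig, apply_pt_filters
from .dispro import ContingencyTable, SignalCriteria, ror_ci, signal_table
from .synthetic import SyntheticConfig, planted_truth, sample_cases

__all__ = ["CoverageResult", "ror_coverage_experiment",
           "NullCalibrationResult", "null_calibration_experiment",
           "recovery_config"]

_Lite = namedtuple("_Lite", "agent pts")


def recovery_config(theta: float = 10.0,
                    n_per_agent: int = 2000,
                    pair: tuple[str, str] = ("infliximab",
                                             "Clostridium difficile infection")
                    ) -> SyntheticConfig:
    """Parameter-recovery study conditions: one planted pair, clean reports.

    The report-composition overrides (off-label-only and product-issues-only
    forcing, indication co-reporting) are disabled so the planted odds
    multiplier is exactly the per-report odds ratio between arms.
    """
    agents = ("infliximab", "etanercept", "adalimumab", "golimumab",
              "certolizumab")
    return SyntheticConfig(
        n_cases={a: n_per_agent for a in agents},
        planted_associations={pair: theta},
        offlabel_only_fraction=0.0,
        product_issues_only_fraction=0.0,
        indication_pt_prob=0.0,
    )


@dataclass
class CoverageResult:
    true_ror: float
    n_replicates: int
    n_covered: int
    estimates: list[float]

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_replicates


def ror_coverage_experiment(config: SyntheticConfig,
                            pair: tuple[str, str],
                            n_replicates: int = 200,
                            seed: int = 0) -> CoverageResult:
    """How often does the 95% CI of the estimated ROR cover the truth?

    Each replicate regenerates the cohort, counts the fourfold table for the
    planted (agent, PT) pair at report level and checks whether the Woolf
    interval covers the closed-form expected ROR.
    """
    truth = planted_truth(config)
    row = truth[(truth.agent == pair[0]) & (truth.pt == pair[1])]
    if row.empty:
        raise ValueError(f"{pair} is not a planted association")
    true_ror = float(row.expected_ror.iloc[0])
    rng = np.random.default_rng(seed)
    covered = 0
    estimates: list[float] = []
    for _ in range(n_replicates):
        cases = sample_cases(config, rng=rng)
        target = (cases["agent"] == pair[0]).to_numpy()
        has_pt = cases["pts"].map(lambda ps: pair[1] in ps).to_numpy()
        a = int((target & has_pt).sum())
        b = int(target.sum()) - a
        c = int((~target & has_pt).sum())
        d = int((~target).sum()) - c
        ror, lo, hi, reason = ror_ci(ContingencyTable(a, b, c, d))
        if reason is None:
            estimates.append(ror)
            if lo <= true_ror <= hi:
                covered += 1
    return CoverageResult(true_ror=true_ror, n_replicates=n_replicates,
                          n_covered=covered, estimates=estimates)


@dataclass
class NullCalibrationResult:
    n_flagged: int
    n_pairs: int

    @property
    def flag_rate(self) -> float:
        return self.n_flagged / self.n_pairs if self.n_pairs else 0.0


def null_calibration_experiment(n_per_agent: int = 800,
                                n_replicates: int = 50,
                                criteria: SignalCriteria = SignalCriteria(),
                                seed: int = 0) -> NullCalibrationResult:
    """Per-pair signal-flag rate with no planted associations.

    Uses the generator's default configuration with theta = 1 everywhere,
    applies the curation PT filters (which remove the by-construction
    agent-specific indication terms), then counts flags over every observed
    (agent, PT) pair across replicates.
    """
    agents = ("infliximab", "etanercept", "adalimumab", "golimumab",
              "certolizumab")
    config = SyntheticConfig(n_cases={a: n_per_agent for a in agents})
    cur = CurationConfig()
    rng = np.random.default_rng(seed)
    flagged = pairs = 0
    for _ in range(n_replicates):
        cases = sample_cases(config, rng=rng)
        lites = []
        for agent, pts in zip(cases["agent"], cases["pts"]):
            kept, reason = apply_pt_filters(pts, agent, cur,
                                            config.pt_vocabulary)
            if reason is None:
                lites.append(_Lite(agent, kept))
        rows = signal_table(lites, pt_to_soc=config.pt_vocabulary,
                            criteria=criteria)
        flagged += sum(r.is_signal for r in rows)
        pairs += len(rows)
    return NullCalibrationResult(n_flagged=flagged, n_pairs=pairs)
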