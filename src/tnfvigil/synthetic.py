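"""Synthetic FAERS-format quarterly bundles with known ground truth.

Every pipeline stage is testable without the multi-gigabyte public archives:
this generator emits quarterly '$'-delimited tables in the exact dialect the
readers parse, with a controlled duplicate/deleted-report structure, ages in
mixed units, primary-suspect role codes with distractor co-medications,
therapy/event dates drawn from a configurable onset distribution, and
drug-event association strengths planted as odds multipliers whose implied
reporting odds ratios are available in closed form via :func:`planted_truth`.

The generative model is deliberately the simplest one consistent with
fourfold-table disproportionality: each preferred term is included on a
report independently with a per-PT baseline probability, shifted on the odds
scale by the planted multiplier for (agent, PT) pairs under study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import AGENTS
from .ingest import QuarterBundle, TABLE_COLUMNS, quarter_index

__all__ = [
    "SyntheticConfig",
    "DEFAULT_PT_SOC",
    "generate",
    "sample_cases",
    "planted_truth",
    "write_quarter_files",
    "write_pt_to_soc",
    "write_truth",
]

# ---------------------------------------------------------------------------
# toy MedDRA-like vocabulary: ~30 preferred terms across 10 system organ
# classes, including the headline terms of pediatric TNF-alpha inhibitor
# surveillance plus per-agent indication terms and product-issue terms.

_GEN = "General disorders and administration site conditions"
_INJ = "Injury, poisoning and procedural complications"
_GI = "Gastrointestinal disorders"
_INF = "Infections and infestations"
_MSK = "Musculoskeletal and connective tissue disorders"
_NRV = "Nervous system disorders"
_EYE = "Eye disorders"
_RES = "Respiratory, thoracic and mediastinal disorders"
_PRI = "Product issues"
_SKN = "Skin and subcutaneous tissue disorders"

#: reports with no sampled reaction get this filler term instead of a
#: resample, so every analysed PT keeps its exact per-report probability
FILLER_PT = "Drug ineffective"

DEFAULT_PT_SOC: dict[str, str] = {
    "Drug ineffective": _GEN,
    "Injection site pain": _GEN,
    "Injection site erythema": _GEN,
    "Injection site pruritus": _GEN,
    "Injection site warmth": _GEN,
    "Pyrexia": _GEN,
    "Fatigue": _GEN,
    "Malaise": _GEN,
    "Off-label use": _INJ,
    "Foetal exposure during pregnancy": _INJ,
    "Abdominal pain": _GI,
    "Haematochezia": _GI,
    "Diarrhoea": _GI,
    "Frequent bowel movements": _GI,
    "Vomiting": _GI,
    "Crohn's disease": _GI,
    "Ulcerative colitis": _GI,
    "Clostridium difficile infection": _INF,
    "Nasopharyngitis": _INF,
    "Influenza": _INF,
    "Sinusitis": _INF,
    "Pharyngitis streptococcal": _INF,
    "Arthralgia": _MSK,
    "Arthritis": _MSK,
    "Back pain": _MSK,
    "Juvenile idiopathic arthritis": _MSK,
    "Rheumatoid arthritis": _MSK,
    "Headache": _NRV,
    "Dizziness": _NRV,
    "Uveitis": _EYE,
    "Cough": _RES,
    "Dyspnoea": _RES,
    "Device leakage": _PRI,
    "Product quality issue": _PRI,
    "Psoriasis": _SKN,
    "Hidradenitis suppurativa": _SKN,
}

_INDICATION_PTS = frozenset({
    "Crohn's disease", "Ulcerative colitis", "Juvenile idiopathic arthritis",
    "Rheumatoid arthritis", "Psoriasis", "Hidradenitis suppurativa"})
_PRODUCT_ISSUE_PTS = ("Device leakage", "Product quality issue")

#: default per-PT baseline inclusion probabilities (indication and
#: product-issue PTs are driven by their own config fractions instead)
_DEFAULT_BASELINE = {
    "Injection site pain": 0.06, "Injection site erythema": 0.03,
    "Injection site pruritus": 0.02, "Injection site warmth": 0.01,
    "Pyrexia": 0.05, "Fatigue": 0.04, "Malaise": 0.03,
    "Off-label use": 0.08, "Foetal exposure during pregnancy": 0.005,
    "Abdominal pain": 0.05, "Haematochezia": 0.02, "Diarrhoea": 0.05,
    "Frequent bowel movements": 0.01, "Vomiting": 0.04,
    "Clostridium difficile infection": 0.01, "Nasopharyngitis": 0.04,
    "Influenza": 0.02, "Sinusitis": 0.02, "Pharyngitis streptococcal": 0.015,
    "Arthralgia": 0.04, "Arthritis": 0.02, "Back pain": 0.02,
    "Headache": 0.05, "Dizziness": 0.03, "Uveitis": 0.01,
    "Cough": 0.03, "Dyspnoea": 0.02,
}

DISTRACTOR_DRUGS = ("ASPIRIN", "METHOTREXATE", "PREDNISONE", "IBUPROFEN")

_AGENT_BRAND = {
    "infliximab": "REMICADE", "etanercept": "ENBREL",
    "adalimumab": "HUMIRA", "golimumab": "SIMPONI",
    "certolizumab": "CIMZIA",
}

_INDICATION_FOR_AGENT = {
    "infliximab": "Crohn's disease",
    "etanercept": "Juvenile idiopathic arthritis",
    "adalimumab": "Crohn's disease",
    "golimumab": "Ulcerative colitis",
    "certolizumab": "Juvenile idiopathic arthritis",
}


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults emulate the study conditions.

    Age mixture weights follow the pediatric stratum shares reported for
    this drug class (roughly 7% aged 0-3, 24% aged 4-11, 69% aged 12-17)
    plus an adult fraction so the <18 filter is exercised; the onset
    distribution is log-normal with a median near 235 days and quartiles
    near 46/832 days.  ``planted_associations`` maps (agent, PT) to an odds
    multiplier theta (>0); theta=1 everywhere is the null configuration.
    """

    n_cases: Mapping[str, int] = field(
        default_factory=lambda: {a: 2000 for a in AGENTS})
    pt_vocabulary: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PT_SOC))
    baseline_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE))
    planted_associations: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    duplicate_fraction: float = 0.10
    deleted_fraction: float = 0.02
    missing_age_fraction: float = 0.05
    adult_fraction: float = 0.15
    age_stratum_weights: tuple[float, float, float] = (0.07, 0.24, 0.69)
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.55, "M": 0.42, "UNK": 0.03})
    reporter_probs: Mapping[str, float] = field(default_factory=lambda: {
        "MD": 0.36, "PH": 0.03, "OT": 0.15, "RN": 0.05, "HP": 0.05,
        "CN": 0.34, "LW": 0.01, "": 0.01})
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: {
        "HO": 0.25, "LT": 0.014, "DE": 0.009, "DS": 0.005, "OT": 0.28})
    start_quarter: str = "2004Q1"
    end_quarter: str = "2024Q3"
    offlabel_only_fraction: float = 0.05
    product_issues_only_fraction: float = 0.01
    indication_pt_prob: float = 0.10
    distractor_prob: float = 0.30
    onset_log_mu: float = 5.46     # ln(235) -> median ~235 days
    onset_log_sigma: float = 1.87  # matches an IQR of roughly 46-832 days
    missing_event_dt_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for (agent, pt), theta in self.planted_associations.items():
            if theta <= 0:
                raise ValueError(f"odds multiplier for {(agent, pt)} must be >0")
            if agent not in self.n_cases:
                raise ValueError(f"planted agent {agent!r} not generated")
            if pt in _INDICATION_PTS:
                raise ValueError(
                    f"cannot plant on indication PT {pt!r}: the curation "
                    "stage removes it for its own agent")
        for p in (self.duplicate_fraction, self.deleted_fraction,
                  self.missing_age_fraction, self.adult_fraction,
                  self.offlabel_only_fraction,
                  self.product_issues_only_fraction,
                  self.indication_pt_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if _PRI not in set(self.pt_vocabulary.values()):
            raise ValueError("vocabulary must include a Product issues SOC")

    def event_prob(self, agent: str, pt: str) -> float:
        """Per-report inclusion probability of ``pt`` on ``agent`` reports."""
        p = self.baseline_prob.get(pt, 0.0)
        theta = self.planted_associations.get((agent, pt))
        if theta is None or p == 0.0:
            return p
        odds = p / (1.0 - p) * theta
        return odds / (1.0 + odds)


def _theta_probs(config: SyntheticConfig, agent: str,
                 pts: Sequence[str]) -> np.ndarray:
    return np.array([config.event_prob(agent, pt) for pt in pts])


def sample_cases(config: SyntheticConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the case-level truth table (one row per underlying case).

    Columns include the agent, demographics, dates, the sampled PT list and
    bookkeeping flags (duplicate/deleted).  :func:`generate` serialises this
    into FAERS quarterly tables; tests may also consume it directly when the
    question under study is the estimator, not the file round-trip.
    """
    rng = rng or np.random.default_rng(config.seed)
    sampled_pts = [pt for pt in config.pt_vocabulary
                   if pt not in _INDICATION_PTS
                   and pt not in _PRODUCT_ISSUE_PTS
                   and pt not in ("Off-label use", FILLER_PT)]
    q_lo = quarter_index(config.start_quarter)
    q_hi = quarter_index(config.end_quarter)

    sexes = list(config.sex_probs)
    sex_p = np.array([config.sex_probs[s] for s in sexes], dtype=float)
    sex_p /= sex_p.sum()
    reporters = list(config.reporter_probs)
    rep_p = np.array([config.reporter_probs[r] for r in reporters], dtype=float)
    rep_p /= rep_p.sum()

    rows: list[dict] = []
    caseid_counter = 10_000_000
    for agent in sorted(config.n_cases):
        n = int(config.n_cases[agent])
        if n == 0:
            continue
        probs = _theta_probs(config, agent, sampled_pts)
        pt_matrix = rng.random((n, len(sampled_pts))) < probs
        offlabel_extra = rng.random(n) < config.baseline_prob.get(
            "Off-label use", 0.0)
        indic_draw = rng.random(n) < config.indication_pt_prob
        mode_draw = rng.random(n)
        age_kind = rng.random(n)
        stratum_draw = rng.choice(3, size=n, p=np.asarray(
            config.age_stratum_weights) / sum(config.age_stratum_weights))
        sex_draw = rng.choice(len(sexes), size=n, p=sex_p)
        rep_draw = rng.choice(len(reporters), size=n, p=rep_p)
        unit_draw = rng.choice(4, size=n, p=[0.70, 0.15, 0.10, 0.05])
        onset = np.ceil(rng.lognormal(config.onset_log_mu,
                                      config.onset_log_sigma, size=n))
        lag = rng.integers(0, 180, size=n)
        start_q = rng.integers(q_lo, q_hi + 1, size=n)
        start_day_in_q = rng.integers(0, 90, size=n)
        dup_draw = rng.random(n) < config.duplicate_fraction
        del_draw = rng.random(n) < config.deleted_fraction
        missing_evt = rng.random(n) < config.missing_event_dt_fraction
        dup_back = rng.integers(30, 200, size=n)
        distract = rng.random(n) < config.distractor_prob
        distract_pick = rng.choice(len(DISTRACTOR_DRUGS), size=n)
        outcome_draws = {code: rng.random(n) < p
                         for code, p in config.outcome_probs.items()}
        pi_pick = rng.choice(len(_PRODUCT_ISSUE_PTS), size=n)

        for i in range(n):
            caseid_counter += 1
            caseid = str(caseid_counter)

            # --- adverse-event term list -------------------------------
            if mode_draw[i] < config.offlabel_only_fraction:
                pts = ["Off-label use"]
            elif mode_draw[i] < (config.offlabel_only_fraction
                                 + config.product_issues_only_fraction):
                pts = [_PRODUCT_ISSUE_PTS[pi_pick[i]]]
            else:
                pts = [pt for pt, hit in zip(sampled_pts, pt_matrix[i]) if hit]
                if offlabel_extra[i]:
                    pts.append("Off-label use")
                if indic_draw[i]:
                    pts.append(_INDICATION_FOR_AGENT[agent])
                if not pts:
                    # every report documents at least one reaction; a filler
                    # term keeps the sampled PTs' probabilities undistorted
                    pts = [FILLER_PT]

            # --- age in mixed units ------------------------------------
            if age_kind[i] < config.missing_age_fraction:
                age, age_cod, age_years = "", "", None
            else:
                if age_kind[i] < (config.missing_age_fraction
                                  + config.adult_fraction):
                    age_years = float(rng.uniform(18.0, 80.0))
                else:
                    lo, hi = ((0.0, 4.0), (4.0, 12.0), (12.0, 18.0))[
                        stratum_draw[i]]
                    age_years = float(rng.uniform(lo, hi))
                unit = ("YR", "MON", "WK", "DY")[unit_draw[i]]
                if unit == "YR":
                    age = f"{age_years:.2f}"
                elif unit == "MON":
                    age = f"{age_years * 12.0:.1f}"
                elif unit == "WK":
                    age = f"{age_years * 365.25 / 7.0:.1f}"
                else:
                    age = f"{age_years * 365.25:.1f}"

            # --- dates --------------------------------------------------
            q = int(start_q[i])
            year, qq = divmod(q, 4)
            start = (np.datetime64(f"{year:04d}-{qq * 3 + 1:02d}-01")
                     + np.timedelta64(int(start_day_in_q[i]), "D"))
            event = start + np.timedelta64(int(onset[i]), "D")
            fda = event + np.timedelta64(int(lag[i]), "D")
            end_dt = np.datetime64(f"{quarter_index(config.end_quarter) // 4:04d}-"
                                   f"{(quarter_index(config.end_quarter) % 4) * 3 + 3:02d}-28")
            if fda > end_dt:
                fda = end_dt

            rows.append({
                "caseid": caseid,
                "agent": agent,
                "pts": pts,
                "sex": sexes[sex_draw[i]],
                "occp_cod": reporters[rep_draw[i]],
                "age": age, "age_cod": age_cod if age == "" else
                    ("YR", "MON", "WK", "DY")[unit_draw[i]],
                "age_years": age_years,
                "outcomes": sorted(code for code in config.outcome_probs
                                   if outcome_draws[code][i]),
                "ther_start": str(start).replace("-", ""),
                "event_dt": ("" if missing_evt[i]
                             else str(event).replace("-", "")),
                "fda_dt": str(fda).replace("-", ""),
                "duplicate": bool(dup_draw[i]),
                "dup_back_days": int(dup_back[i]),
                "deleted": bool(del_draw[i]),
                "distractor": (DISTRACTOR_DRUGS[distract_pick[i]]
                               if distract[i] else None),
            })
    return pd.DataFrame(rows)


def planted_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Closed-form expected RORs for every planted (agent, PT) pair.

    The expectation is over the retained report universe: the fraction of
    reports forced to a single off-label or product-issue term never carries
    the planted PT, and product-issue-only reports are excluded at curation,
    so the retained-universe inclusion probability is
    ``p * (1 - f_ol - f_pi) / (1 - f_pi)`` in each arm.  With both forcing
    fractions at zero the expected ROR is exactly the planted odds
    multiplier times the baseline odds ratio (i.e. theta).
    """
    f_ol = config.offlabel_only_fraction
    f_pi = config.product_issues_only_fraction
    shrink = (1.0 - f_ol - f_pi) / (1.0 - f_pi) if f_pi < 1 else 0.0
    rows = []
    for (agent, pt), theta in sorted(config.planted_associations.items()):
        p_c = config.baseline_prob.get(pt, 0.0) * shrink
        p_t = config.event_prob(agent, pt) * shrink
        if 0 < p_c < 1 and 0 < p_t < 1:
            expected = (p_t / (1 - p_t)) / (p_c / (1 - p_c))
        else:
            expected = float("nan")
        rows.append({"agent": agent, "pt": pt, "theta": theta,
                     "p_target": p_t, "p_comparator": p_c,
                     "expected_ror": expected})
    return pd.DataFrame(rows, columns=["agent", "pt", "theta", "p_target",
                                       "p_comparator", "expected_ror"])


# ---------------------------------------------------------------------------
# FAERS serialisation

def _quarter_of(date8: str) -> str:
    return f"{date8[:4]}Q{(int(date8[4:6]) - 1) // 3 + 1}"


def _version_rows(case: Mapping, version: int, primaryid: str,
                  fda_dt: str) -> dict[str, list[list[str]]]:
    """All seven-table rows for one report version of one case."""
    cid = case["caseid"]
    out: dict[str, list[list[str]]] = {t: [] for t in TABLE_COLUMNS}
    out["demo"].append([primaryid, cid, fda_dt, case["event_dt"],
                        case["age"], case["age_cod"], case["sex"],
                        case["occp_cod"], "US"])
    drugname = _AGENT_BRAND[case["agent"]]
    out["drug"].append([primaryid, cid, "1", "PS", drugname, case["agent"].upper()])
    if case["distractor"]:
        out["drug"].append([primaryid, cid, "2", "C", case["distractor"], ""])
    for pt in case["pts"]:
        out["reac"].append([primaryid, cid, pt])
    for code in case["outcomes"]:
        out["outc"].append([primaryid, cid, code])
    out["ther"].append([primaryid, cid, "1", case["ther_start"], ""])
    out["indi"].append([primaryid, cid, "1", _INDICATION_FOR_AGENT[case["agent"]]])
    out["rpsr"].append([primaryid, cid, "FGN"])
    return out


def _shift_date8(date8: str, back_days: int) -> str:
    d = np.datetime64(f"{date8[:4]}-{date8[4:6]}-{date8[6:8]}")
    return str(d - np.timedelta64(back_days, "D")).replace("-", "")


def generate(config: SyntheticConfig,
             outdir: str | Path | None = None,
             rng: np.random.Generator | None = None
             ) -> tuple[list[QuarterBundle], pd.DataFrame]:
    """Generate quarterly bundles (and optionally write them to disk).

    Returns ``(bundles, cases)`` where ``cases`` is the ground-truth case
    table from :func:`sample_cases`.  Each case is serialised as one report
    version; a ``duplicate_fraction`` of cases additionally emit an earlier
    version (same CASEID, earlier FDA_DT, lower PRIMARYID) so exactly the
    latest version per case survives deduplication.  A ``deleted_fraction``
    of caseids is listed in the deleted-report file of their quarter.
    Fully deterministic for a given config + seed.
    """
    cases = sample_cases(config, rng=rng)
    per_quarter: dict[str, dict[str, list[list[str]]]] = {}
    deleted_per_quarter: dict[str, set[str]] = {}

    def add_rows(qid: str, rows: dict[str, list[list[str]]]) -> None:
        bucket = per_quarter.setdefault(
            qid, {t: [] for t in TABLE_COLUMNS})
        for table, rs in rows.items():
            bucket[table].extend(rs)

    for case in cases.to_dict("records"):
        cid = case["caseid"]
        fda_final = case["fda_dt"]
        qid_final = _quarter_of(fda_final)
        add_rows(qid_final, _version_rows(case, 2, cid + "2", fda_final))
        if case["duplicate"]:
            fda_v1 = _shift_date8(fda_final, case["dup_back_days"])
            qid_v1 = _quarter_of(fda_v1)
            add_rows(qid_v1, _version_rows(case, 1, cid + "1", fda_v1))
        if case["deleted"]:
            deleted_per_quarter.setdefault(qid_final, set()).add(cid)

    bundles: list[QuarterBundle] = []
    for qid in sorted(per_quarter):
        tables = {}
        for tname, rows in per_quarter[qid].items():
            df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS[tname]),
                              dtype=str)
            if tname != "demo":
                df["orphan"] = False
            tables[tname] = df
        bundles.append(QuarterBundle(
            quarter_id=qid, tables=tables,
            deleted_caseids=set(deleted_per_quarter.get(qid, set()))))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for bundle in bundles:
            write_quarter_files(bundle, outdir)
    return bundles, cases


def write_quarter_files(bundle: QuarterBundle, outdir: str | Path) -> list[Path]:
    """Serialise one bundle in the FAERS ASCII dialect (DEMOyyQq.txt etc.)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qid = bundle.quarter_id
    tag = f"{qid[2:4]}Q{qid[5]}"
    written = []
    for tname in TABLE_COLUMNS:
        df = bundle.tables.get(tname)
        if df is None:
            continue
        cols = list(TABLE_COLUMNS[tname])
        path = outdir / f"{tname.upper()}{tag}.txt"
        lines = ["$".join(c.upper() for c in cols)]
        for row in df[cols].itertuples(index=False):
            lines.append("$".join(str(v) for v in row))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    dpath = outdir / f"DELETED{tag}.txt"
    dpath.write_text("".join(f"{cid}\n" for cid in
                             sorted(bundle.deleted_caseids)),
                     encoding="utf-8")
    written.append(dpath)
    return written


def write_pt_to_soc(vocabulary: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    lines = ["pt\tsoc"] + [f"{pt}\t{soc}" for pt, soc in
                           sorted(vocabulary.items())]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_truth(config: SyntheticConfig, path: str | Path) -> Path:
    path = Path(path)
    planted_truth(config).to_csv(path, index=False)
    return path


def expected_survivors(cases: pd.DataFrame) -> set[str]:
    """Primaryids that must survive deduplication (latest version, not deleted)."""
    return {row.caseid + "2" for row in cases.itertuples()
            if not row.deleted}
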