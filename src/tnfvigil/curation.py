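"""Cohort curation: deduplication, drug mapping, pediatric selection, PT filters.

Turns raw quarterly bundles into the analysis cohort of one
:class:`CaseReport` per surviving safety report.  The attrition chain is
fully tallied so raw count = retained + sum of exclusion reasons.

Deduplication follows the spontaneous-reporting convention: among report
versions sharing a CASEID keep the one with the most recent FDA receipt
date, breaking ties by the highest PRIMARYID; cases on the quarterly
deleted-report lists are then removed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .ingest import (AGE_CODES, ParsedDate, QuarterBundle, parse_date,
                     quarter_index)

__all__ = [
    "AGENTS",
    "CaseReport",
    "DrugDictionary",
    "CurationConfig",
    "CurationResult",
    "deduplicate",
    "to_years",
    "select_pediatric",
    "assign_stratum",
    "map_drug",
    "apply_pt_filters",
    "reporter_class",
    "curate",
    "load_pt_to_soc",
]

AGENTS = ("infliximab", "etanercept", "adalimumab", "golimumab", "certolizumab")

STRATA = ("0-3", "4-11", "12-17")

#: raw FAERS occupation codes collapsed to reporting-table categories
REPORTER_CLASSES = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health professional",
    "RN": "Other health professional",
    "HP": "Other health professional",
    "CN": "Consumer",
}

_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

OFF_LABEL_PT = "Off-label use"


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class AgentEntry:
    generic: str
    brands: tuple[str, ...]
    approval_quarter: str  # 'YYYYQn'


@dataclass
class DrugDictionary:
    """Per-agent synonym sets (generic + brands) and approval quarters.

    Matching is token based: a synonym matches when its token sequence
    appears contiguously in the normalised verbatim drug name, so
    "REMICADE 100MG" maps to infliximab but "ASPIRIN" maps to nothing.
    """

    agents: dict[str, AgentEntry]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, ...], str] = {}
        for agent, entry in self.agents.items():
            for syn in (entry.generic, *entry.brands):
                toks = _tokens(syn)
                if toks in seen and seen[toks] != agent:
                    raise ValueError(
                        f"synonym {syn!r} ambiguous between "
                        f"{seen[toks]} and {agent}")
                seen[toks] = agent
        self._synonyms = seen

    @classmethod
    def default(cls) -> "DrugDictionary":
        return cls(agents={
            "infliximab": AgentEntry("infliximab", ("Remicade",), "1998Q3"),
            "etanercept": AgentEntry("etanercept", ("Enbrel", "Erelzi"), "1998Q4"),
            "adalimumab": AgentEntry(
                "adalimumab", ("Humira", "Amjevita", "Mjevita", "Cyltezo"),
                "2002Q4"),
            "golimumab": AgentEntry("golimumab", ("Simponi",), "2009Q2"),
            "certolizumab": AgentEntry(
                "certolizumab", ("Cimzia", "Certolizumab pegol"), "2008Q2"),
        })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugDictionary":
        raw = yaml.safe_load(Path(path).read_text())
        agents = {
            name: AgentEntry(spec.get("generic", name),
                             tuple(spec.get("brands", ())),
                             spec["approval_quarter"])
            for name, spec in raw.items()
        }
        return cls(agents=agents)

    @property
    def synonyms(self) -> Mapping[tuple[str, ...], str]:
        return self._synonyms


#: indication preferred terms excluded per agent to curb indication bias
#: (the treated disease's own manifestations misread as drug reactions).
#: Shipped as editable data — extend via CurationConfig or YAML.
DEFAULT_INDICATION_EXCLUSIONS: dict[str, frozenset[str]] = {
    "infliximab": frozenset({"Crohn's disease", "Ulcerative colitis",
                             "Inflammatory bowel disease"}),
    "etanercept": frozenset({"Juvenile idiopathic arthritis",
                             "Rheumatoid arthritis", "Psoriasis"}),
    "adalimumab": frozenset({"Crohn's disease", "Ulcerative colitis",
                             "Juvenile idiopathic arthritis", "Psoriasis",
                             "Hidradenitis suppurativa"}),
    "golimumab": frozenset({"Ulcerative colitis", "Rheumatoid arthritis"}),
    "certolizumab": frozenset({"Crohn's disease", "Rheumatoid arthritis",
                               "Juvenile idiopathic arthritis"}),
}


@dataclass
class CurationConfig:
    indication_exclusion: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_INDICATION_EXCLUSIONS))
    offlabel_retention: bool = True
    product_issues_soc_label: str = "Product issues"
    age_max_plausible: float = 120.0
    pediatric_age_max: float = 18.0  # strict upper bound (exclusive)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "indication_exclusion" in raw:
            kwargs["indication_exclusion"] = {
                agent: frozenset(pts)
                for agent, pts in raw["indication_exclusion"].items()}
        for key in ("offlabel_retention", "product_issues_soc_label",
                    "age_max_plausible", "pediatric_age_max"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# case container

@dataclass
class CaseReport:
    """One deduplicated, curated safety report."""

    primaryid: str
    caseid: str
    fda_dt: Optional[ParsedDate]
    event_dt: Optional[ParsedDate]
    age_years: Optional[float]
    stratum: Optional[str]
    sex: str
    reporter_class: str
    agent: str
    pts: list[str]
    socs: list[str]
    outcomes: set[str]
    therapy_start: Optional[ParsedDate]
    indications: list[str] = field(default_factory=list)
    quarter_id: Optional[str] = None


# ---------------------------------------------------------------------------
# elementary operations

def _id_key(s: str) -> tuple[int, object]:
    # numeric ids compare numerically; non-numeric fall back to lexicographic
    return (0, int(s)) if s.isdigit() else (1, s)


def deduplicate(demo: pd.DataFrame, deleted: Iterable[str] = ()) -> set[str]:
    """Collapse report versions to one primaryid per case.

    Keeps, per CASEID, the row with the latest FDA_DT (partial dates compared
    at available precision, missing components lowest), ties broken by the
    highest PRIMARYID (numeric when possible).  CASEIDs in ``deleted`` are
    dropped entirely.  Idempotent and input-order invariant.
    """
    deleted = set(deleted)
    best: dict[str, tuple[tuple, str]] = {}
    for pid, cid, fdt in zip(demo["primaryid"], demo["caseid"],
                             demo.get("fda_dt", [""] * len(demo))):
        if not pid:
            continue
        cid = cid or pid  # caseid absent -> treat report as its own case
        d = parse_date(fdt)
        key = (d.sort_key() if d else (0, 0, 0), _id_key(pid))
        cur = best.get(cid)
        if cur is None or key > cur[0]:
            best[cid] = (key, pid)
    return {pid for cid, (_, pid) in best.items() if cid not in deleted}


def to_years(age_value, age_code: str) -> Optional[float]:
    """Convert a FAERS age to years (e.g. 6 months -> 0.5).

    Returns None for negative, non-numeric or unknown-unit input; such
    records are excluded from age-stratified analyses.
    """
    if age_code not in _AGE_FACTORS:
        return None
    try:
        value = float(age_value)
    except (TypeError, ValueError):
        return None
    if value < 0 or value != value:  # negative or NaN
        return None
    return value * _AGE_FACTORS[age_code]


def select_pediatric(ages: Iterable[Optional[float]],
                     age_max: float = 18.0,
                     age_max_plausible: float = 120.0
                     ) -> tuple[list[bool], dict[str, int]]:
    """Flag ages in [0, age_max); tally missing / implausible / adult."""
    keep: list[bool] = []
    tally = {"missing": 0, "implausible": 0, "adult": 0, "retained": 0}
    for a in ages:
        if a is None:
            tally["missing"] += 1
            keep.append(False)
        elif a < 0 or a > age_max_plausible:
            tally["implausible"] += 1
            keep.append(False)
        elif a >= age_max:
            tally["adult"] += 1
            keep.append(False)
        else:
            tally["retained"] += 1
            keep.append(True)
    return keep, tally


def assign_stratum(age_years: float) -> str:
    """Half-open pediatric strata: [0,4) -> 0-3, [4,12) -> 4-11, [12,18) -> 12-17."""
    if not 0 <= age_years < 18:
        raise ValueError(f"age {age_years} outside pediatric range [0, 18)")
    if age_years < 4:
        return "0-3"
    if age_years < 12:
        return "4-11"
    return "12-17"


_PUNCT = str.maketrans({c: " " for c in r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~"""})


def _tokens(name: str) -> tuple[str, ...]:
    return tuple(name.upper().translate(_PUNCT).split())


def map_drug(drugname: str, dictionary: DrugDictionary) -> Optional[str]:
    """Map a verbatim drug name to an agent, or None.

    Normalises to uppercase tokens and matches any dictionary synonym as a
    contiguous token subsequence; a name matching two different agents is
    ambiguous and maps to None.
    """
    toks = _tokens(drugname or "")
    if not toks:
        return None
    hits: set[str] = set()
    for syn, agent in dictionary.synonyms.items():
        k = len(syn)
        if k > len(toks):
            continue
        for i in range(len(toks) - k + 1):
            if tuple(toks[i:i + k]) == syn:
                hits.add(agent)
                break
    if len(hits) == 1:
        return hits.pop()
    return None


def reporter_class(occp_cod: str) -> str:
    return REPORTER_CLASSES.get((occp_cod or "").strip().upper(),
                                "Unknown/other")


def apply_pt_filters(pts: Sequence[str], agent: str, config: CurationConfig,
                     pt_to_soc: Mapping[str, str]
                     ) -> tuple[list[str], Optional[str]]:
    """Apply report-level PT filters; return (kept PTs, exclusion reason).

    1. PTs matching the agent's approved indications are dropped (indication
       bias); 2. a report left with no PTs is excluded ("indication_only");
    3. a report whose only PT is "Off-label use" is retained (golimumab has
       no pediatric approval, so pediatric exposure is inherently off-label;
       the rule is applied to all agents for comparability); 4. a report
       whose remaining PTs all map to the Product-Issues SOC is excluded
       ("product_issues_only") — those reflect device or administration
       errors, not medicinal adverse events.
    """
    excl = {p.casefold() for p in config.indication_exclusion.get(agent, ())}
    kept = [p for p in pts if p.casefold() not in excl]
    if not kept:
        return [], "indication_only"
    if config.offlabel_retention and all(
            p.casefold() == OFF_LABEL_PT.casefold() for p in kept):
        return kept, None
    pi = config.product_issues_soc_label.casefold()
    if all(pt_to_soc.get(p, "").casefold() == pi for p in kept):
        return [], "product_issues_only"
    return kept, None


def load_pt_to_soc(path: str | Path) -> dict[str, str]:
    """Read a two-column (PT <tab> SOC) mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "pt" not in cols or "soc" not in cols:
        raise ValueError(f"{path}: expected columns PT and SOC, got {cols}")
    return dict(zip(df["pt"], df["soc"]))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class CurationResult:
    cases: list[CaseReport]
    attrition: dict[str, int]
    log: list[dict] = field(default_factory=list)

    def conserved(self) -> bool:
        """Raw report count equals retained + every exclusion tally."""
        a = self.attrition
        total = a["retained"] + sum(v for k, v in a.items()
                                    if k not in ("raw_reports", "retained"))
        return total == a["raw_reports"]


def _group_rows(df: pd.DataFrame) -> dict[str, list[dict]]:
    if df.empty:
        return {}
    out: dict[str, list[dict]] = {}
    for row in df.to_dict("records"):
        out.setdefault(row["primaryid"], []).append(row)
    return out


def curate(bundles: Sequence[QuarterBundle],
           pt_to_soc: Mapping[str, str],
           config: CurationConfig | None = None,
           dictionary: DrugDictionary | None = None) -> CurationResult:
    """Run the full attrition chain over parsed quarters.

    Order of operations: deduplicate across all quarters (deleted lists
    pooled) -> restrict to reports whose Primary Suspect drug maps to one of
    the five agents (post-approval quarters only) -> pediatric age filter
    (< 18 years, mixed units normalised) -> PT-level filters (indication
    exclusion, Product-Issues-only exclusion, off-label-only retention).
    """
    config = config or CurationConfig()
    dictionary = dictionary or DrugDictionary.default()
    log: list[dict] = []

    demo_frames = []
    for b in bundles:
        d = b.demo.copy()
        d["quarter_id"] = b.quarter_id
        demo_frames.append(d)
    demo = (pd.concat(demo_frames, ignore_index=True)
            if demo_frames else pd.DataFrame(
                columns=["primaryid", "caseid", "fda_dt", "quarter_id"]))
    deleted: set[str] = set()
    for b in bundles:
        deleted |= b.deleted_caseids

    attrition = {
        "raw_reports": int(len(demo)),
        "duplicate_versions": 0, "deleted_cases": 0,
        "no_ps_target_agent": 0, "pre_approval": 0,
        "age_missing": 0, "age_implausible": 0, "age_adult": 0,
        "indication_only": 0, "product_issues_only": 0,
        "retained": 0,
    }

    survivors_all = deduplicate(demo, deleted=())
    survivors = deduplicate(demo, deleted=deleted)
    attrition["duplicate_versions"] = len(demo) - len(survivors_all)
    attrition["deleted_cases"] = len(survivors_all) - len(survivors)

    drug_by_pid: dict[str, list[dict]] = {}
    reac_by_pid: dict[str, list[dict]] = {}
    outc_by_pid: dict[str, list[dict]] = {}
    ther_by_pid: dict[str, list[dict]] = {}
    indi_by_pid: dict[str, list[dict]] = {}
    for b in bundles:
        for target, df in ((drug_by_pid, b.drug), (reac_by_pid, b.reac),
                           (outc_by_pid, b.outc), (ther_by_pid, b.ther),
                           (indi_by_pid, b.indi)):
            for pid, rows in _group_rows(df).items():
                target.setdefault(pid, []).extend(rows)

    approval_idx = {agent: quarter_index(e.approval_quarter)
                    for agent, e in dictionary.agents.items()}

    demo_by_pid = {}
    for row in demo.to_dict("records"):
        demo_by_pid.setdefault(row["primaryid"], row)

    cases: list[CaseReport] = []
    for pid in sorted(survivors, key=_id_key):
        drow = demo_by_pid[pid]
        # --- primary-suspect restriction -------------------------------
        ps_rows = [r for r in drug_by_pid.get(pid, ())
                   if r.get("role_cod") == "PS"]
        agents_hit = {}
        for r in ps_rows:
            agent = (map_drug(r.get("drugname", ""), dictionary)
                     or map_drug(r.get("prod_ai", ""), dictionary))
            if agent:
                agents_hit.setdefault(agent, r)
        if len(agents_hit) != 1:
            attrition["no_ps_target_agent"] += 1
            if len(agents_hit) > 1:
                log.append({"kind": "ambiguous_ps", "primaryid": pid,
                            "agents": sorted(agents_hit)})
            continue
        agent, ps_row = next(iter(agents_hit.items()))

        quarter_id = drow.get("quarter_id")
        if quarter_id and quarter_index(quarter_id) < approval_idx[agent]:
            attrition["pre_approval"] += 1
            continue

        # --- pediatric age filter --------------------------------------
        age_years = to_years(drow.get("age"), drow.get("age_cod", ""))
        if age_years is None:
            attrition["age_missing"] += 1
            continue
        if age_years > config.age_max_plausible:
            attrition["age_implausible"] += 1
            continue
        if age_years >= config.pediatric_age_max:
            attrition["age_adult"] += 1
            continue

        # --- PT filters -------------------------------------------------
        pts_raw: list[str] = []
        for r in reac_by_pid.get(pid, ()):
            pt = r.get("pt", "").strip()
            if pt and pt not in pts_raw:  # report-level: count each PT once
                pts_raw.append(pt)
        kept, reason = apply_pt_filters(pts_raw, agent, config, pt_to_soc)
        if reason is not None:
            attrition[reason] += 1
            continue

        socs = sorted({pt_to_soc.get(p, "UNMAPPED") for p in kept})
        outcomes = {r.get("outc_cod") for r in outc_by_pid.get(pid, ())
                    if r.get("outc_cod")}

        ps_seq = ps_row.get("drug_seq", "")
        starts = []
        for r in ther_by_pid.get(pid, ()):
            if ps_seq and r.get("dsg_drug_seq") != ps_seq:
                continue
            d = parse_date(r.get("start_dt", ""))
            if d is not None:
                starts.append(d)
        therapy_start = min(starts, key=lambda d: d.sort_key()) if starts else None

        indications = [r.get("indi_pt", "").strip()
                       for r in indi_by_pid.get(pid, ())
                       if r.get("indi_pt", "").strip()]

        sex = drow.get("sex", "").upper()
        if sex not in ("M", "F"):
            sex = "UNK"

        cases.append(CaseReport(
            primaryid=pid,
            caseid=drow.get("caseid") or pid,
            fda_dt=parse_date(drow.get("fda_dt", "")),
            event_dt=parse_date(drow.get("event_dt", "")),
            age_years=age_years,
            stratum=assign_stratum(age_years),
            sex=sex,
            reporter_class=reporter_class(drow.get("occp_cod", "")),
            agent=agent,
            pts=kept,
            socs=socs,
            outcomes=outcomes,
            therapy_start=therapy_start,
            indications=indications,
            quarter_id=quarter_id,
        ))
    attrition["retained"] = len(cases)
    return CurationResult(cases=cases, attrition=attrition, log=log)
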