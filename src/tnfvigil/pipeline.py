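"""End-to-end orchestration with an auditable run manifest.

``run_pipeline`` wires the stages together — simulate (optional), ingest,
curate, signals, strata, onset, sensitivity — writing each stage's outputs
as CSV plus a JSON manifest recording the config hash, per-stage attrition
counts and content hashes of every output, so a flow-diagram of record
attrition can be reconstructed from the manifest alone.  Re-running with
the same inputs and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import curation, dispro, ingest, sensitivity, strata, synthetic
from .reporting import proportion

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "SUBCOMMANDS"]

SUBCOMMANDS = ("simulate", "ingest", "curate", "signals", "strata",
               "onset", "sensitivity", "all")


@dataclass
class PipelineConfig:
    """Run configuration; everything has a workable default."""

    quarters_dir: Optional[str] = None      # defaults to <outdir>/quarters
    pt_to_soc: Optional[str] = None         # defaults to <outdir>/pt_to_soc.tsv
    drug_dictionary: Optional[str] = None   # YAML; default built-in
    seed: int = 0
    comparator: str = "within_class"
    cutoff_quarter: str = sensitivity.DEFAULT_CUTOFF
    criteria: dispro.SignalCriteria = field(default_factory=dispro.SignalCriteria)
    curation: curation.CurationConfig = field(
        default_factory=curation.CurationConfig)
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("quarters_dir", "pt_to_soc", "drug_dictionary", "seed",
                    "comparator", "cutoff_quarter"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "criteria" in raw:
            cfg.criteria = dispro.SignalCriteria(**raw["criteria"])
        if "curation" in raw:
            cur = dict(raw["curation"])
            if "indication_exclusion" in cur:
                cur["indication_exclusion"] = {
                    k: frozenset(v)
                    for k, v in cur["indication_exclusion"].items()}
            cfg.curation = curation.CurationConfig(**cur)
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if "planted_associations" in syn:
                syn["planted_associations"] = {
                    (d["agent"], d["pt"]): d["theta"]
                    for d in syn["planted_associations"]}
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        return cfg

    def config_hash(self) -> str:
        def canon(o):
            if dataclasses.is_dataclass(o):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return {str(k): canon(v) for k, v in
                        sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [canon(x) for x in o]
            if isinstance(o, (set, frozenset)):
                return sorted(str(x) for x in o)
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)
        blob = json.dumps(canon(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run (Fig-1-style attrition bookkeeping)."""

    config_hash: str
    seed: int
    quarters: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    attrition: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256

    def attrition_chain(self) -> list[tuple[str, int]]:
        order = ("raw", "deduplicated", "ps_restricted", "pediatric",
                 "post_filter")
        return [(k, self.stage_counts[k]) for k in order
                if k in self.stage_counts]

    def is_monotone(self) -> bool:
        chain = [n for _, n in self.attrition_chain()]
        return all(x >= y for x, y in zip(chain, chain[1:]))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
            + "\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    manifest.outputs[path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig | str | Path,
                 subcommand: str = "all",
                 outdir: str | Path = "tnfvigil_out") -> RunManifest:
    """Execute one stage (with its prerequisites) and write outputs + manifest.

    ``subcommand`` is one of ``simulate, ingest, curate, signals, strata,
    onset, sensitivity, all``.  ``simulate`` writes synthetic FAERS quarters
    plus the PT->SOC mapping and the planted-truth sidecar under
    ``<outdir>/quarters``; the analysis stages read whatever
    ``quarters_dir`` points at (by default, that simulated directory).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}; "
                         f"expected one of {SUBCOMMANDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)

    quarters_dir = Path(config.quarters_dir or outdir / "quarters")
    pt_to_soc_path = Path(config.pt_to_soc or outdir / "pt_to_soc.tsv")

    if subcommand in ("simulate", "all"):
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        synthetic.generate(syn, outdir=quarters_dir)
        synthetic.write_pt_to_soc(syn.pt_vocabulary, pt_to_soc_path)
        truth_path = outdir / "planted_truth.csv"
        synthetic.write_truth(syn, truth_path)
        manifest.outputs[truth_path.name] = _sha256(truth_path)
        if subcommand == "simulate":
            manifest.write(outdir / "manifest.json")
            return manifest

    if not pt_to_soc_path.exists():
        raise FileNotFoundError(
            f"PT->SOC mapping table not found at {pt_to_soc_path}; supply "
            "one as a two-column TSV (pt, soc) or run the simulate stage "
            "first")
    pt_to_soc = curation.load_pt_to_soc(pt_to_soc_path)

    bundles = ingest.read_quarters(quarters_dir)
    manifest.quarters = [b.quarter_id for b in bundles]
    raw = sum(len(b.demo) for b in bundles)
    manifest.stage_counts["raw"] = raw
    if subcommand == "ingest":
        counts = pd.DataFrame([{"quarter": b.quarter_id, **b.counts,
                                "deleted": len(b.deleted_caseids)}
                               for b in bundles])
        _write_csv(counts, outdir / "ingest_counts.csv", manifest)
        manifest.write(outdir / "manifest.json")
        return manifest

    dictionary = (curation.DrugDictionary.from_yaml(config.drug_dictionary)
                  if config.drug_dictionary else
                  curation.DrugDictionary.default())
    result = curation.curate(bundles, pt_to_soc, config=config.curation,
                             dictionary=dictionary)
    att = result.attrition
    manifest.attrition = dict(att)
    manifest.stage_counts["deduplicated"] = (
        raw - att["duplicate_versions"] - att["deleted_cases"])
    manifest.stage_counts["ps_restricted"] = (
        manifest.stage_counts["deduplicated"]
        - att["no_ps_target_agent"] - att["pre_approval"])
    manifest.stage_counts["pediatric"] = (
        manifest.stage_counts["ps_restricted"]
        - att["age_missing"] - att["age_implausible"] - att["age_adult"])
    manifest.stage_counts["post_filter"] = att["retained"]

    cases = result.cases
    attr_df = pd.DataFrame(sorted(att.items()), columns=["reason", "count"])
    _write_csv(attr_df, outdir / "attrition.csv", manifest)
    cases_df = pd.DataFrame([{
        "primaryid": c.primaryid, "caseid": c.caseid, "agent": c.agent,
        "age_years": round(c.age_years, 4) if c.age_years is not None else "",
        "stratum": c.stratum, "sex": c.sex,
        "reporter_class": c.reporter_class,
        "fda_dt": str(c.fda_dt) if c.fda_dt else "",
        "event_dt": str(c.event_dt) if c.event_dt else "",
        "therapy_start": str(c.therapy_start) if c.therapy_start else "",
        "outcomes": ";".join(sorted(c.outcomes)),
        "pts": ";".join(c.pts),
        "socs": ";".join(c.socs),
    } for c in cases])
    _write_csv(cases_df, outdir / "curated_cases.csv", manifest)
    if subcommand == "curate":
        manifest.write(outdir / "manifest.json")
        return manifest

    signals = dispro.signal_table(cases, pt_to_soc,
                                  criteria=config.criteria,
                                  comparator_mode=config.comparator)
    ranked = dispro.prioritize(signals)
    if subcommand in ("signals", "all"):
        _write_csv(dispro.signals_frame(ranked),
                   outdir / "signals.csv", manifest)
        rsr_rows = []
        flagged_total = pt_total = 0
        for drug in sorted({s.drug for s in signals}):
            rows = [s for s in signals if s.drug == drug]
            n_sig = sum(s.is_signal for s in rows)
            flagged_total += n_sig
            pt_total += len(rows)
            rsr_rows.append({"drug": drug, "signal_pts": n_sig,
                             "observed_pts": len(rows),
                             "rsr_pct": proportion(n_sig, len(rows), 2)})
        if pt_total:
            rsr_rows.append({"drug": dispro.CLASS_LABEL,
                             "signal_pts": flagged_total,
                             "observed_pts": pt_total,
                             "rsr_pct": proportion(flagged_total, pt_total, 2)})
        _write_csv(pd.DataFrame(rsr_rows), outdir / "rsr.csv", manifest)
        if subcommand == "signals":
            manifest.write(outdir / "manifest.json")
            return manifest

    if subcommand in ("strata", "all"):
        demo = strata.demographics_table(cases)
        demo_df = demo.formatted().reset_index(names=["block", "category"])
        _write_csv(demo_df, outdir / "demographics.csv", manifest)
        _write_csv(strata.soc_aggregate(signals, pt_to_soc),
                   outdir / "soc_signal_counts.csv", manifest)
        soc_table, top_table = strata.stratum_compare(cases, signals)
        _write_csv(soc_table, outdir / "stratum_soc.csv", manifest)
        _write_csv(top_table, outdir / "stratum_top10.csv", manifest)
        if subcommand == "strata":
            manifest.write(outdir / "manifest.json")
            return manifest

    if subcommand in ("onset", "all"):
        summaries = strata.onset_analysis(cases)
        summary_df = pd.DataFrame([{
            "group": s.label, "n_with_onset": s.n_with_onset,
            "median_days": s.median if s.median is not None else "",
            "q1_days": s.q1 if s.q1 is not None else "",
            "q3_days": s.q3 if s.q3 is not None else "",
            "missing_timeline": s.excluded.get("missing_timeline", 0),
            "implausible": s.excluded.get("implausible", 0),
        } for s in summaries])
        _write_csv(summary_df, outdir / "onset_summary.csv", manifest)
        bins_df = pd.DataFrame([
            {"group": s.label, "bin": b, "count": n}
            for s in summaries for b, n in s.bins.items()])
        _write_csv(bins_df, outdir / "onset_bins.csv", manifest)
        if subcommand == "onset":
            manifest.write(outdir / "manifest.json")
            return manifest

    if subcommand in ("sensitivity", "all"):
        era_df, wres = sensitivity.era_comparison(
            cases, cutoff_quarter=config.cutoff_quarter,
            criteria=config.criteria)
        _write_csv(era_df, outdir / "era_comparison.csv", manifest)
        wil_df = pd.DataFrame([{
            "w": wres.w, "z": round(wres.z, 4), "p": wres.p,
            "median_diff": round(wres.median_diff, 4),
            "n_pairs": wres.n, "method": wres.method}])
        _write_csv(wil_df, outdir / "wilcoxon.csv", manifest)

    manifest.write(outdir / "manifest.json")
    return manifest
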