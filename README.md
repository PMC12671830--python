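# tnfvigil

Pediatric pharmacovigilance of TNF-α inhibitors (infliximab, etanercept,
adalimumab, golimumab, certolizumab) from FAERS-style quarterly
spontaneous-report tables.

Spontaneous-reporting databases such as the FDA Adverse Event Reporting
System (FAERS) are the main source of post-marketing safety evidence for
drugs used in children, where trial data are thin. They are also messy:
reports arrive in quarterly `$`-delimited table dumps, the same case shows
up as multiple report versions, ages come in years, months, weeks or days,
and the treated disease's own manifestations are frequently coded as if
they were drug reactions. `tnfvigil` packages the whole analysis path for
the five TNF-α inhibitors in pediatric patients — ingestion, deduplication,
cohort curation, disproportionality signal detection, age-stratified and
time-to-onset summaries, and an era-split sensitivity analysis — together
with a synthetic FAERS generator with known ground truth, so every stage is
testable without downloading the real archives.

## The statistics

Signal detection uses the reporting odds ratio on the fourfold table of
report counts

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | b            |
| comparators  | c            | d            |

with

- ROR = (a·d)/(b·c)
- 95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )
- Pearson χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))

A drug–event pair is flagged as a signal when n = a ≥ 3, the lower CI bound
exceeds 1 and χ² > 4 (all configurable; an optional ROR threshold is off by
default). Counting is report-level — a report listing a preferred term (PT)
twice counts once — and the default comparator universe is the curated
reports of the other four agents (within-class comparison); external
background counts can be supplied instead. Tables with a zero cell are
reported as undefined rather than silently corrected. The risk-signal
detection ratio (RSR) of a drug is the share of its observed PTs that are
flagged, in percent. No multiple-testing adjustment is applied: flags are
screening hypotheses, not confirmed associations.

Curation implements the standard spontaneous-report hygiene: keep, per
case, only the report version with the latest FDA receipt date (ties broken
by the highest report-version id), drop cases on the quarterly deleted
lists, restrict to reports whose Primary Suspect drug maps to one of the
five agents (post-approval quarters only), keep ages `< 18` years after
converting mixed units (6 months → 0.5 years), drop indication PTs per
agent, exclude reports coded solely to the Product Issues SOC, and retain
reports whose only PT is "Off-label use".

## Worked example

Simulate a five-agent pediatric cohort with two planted associations
(a true ROR of 10 for Clostridium difficile infection on infliximab and 8
for injection site pain on etanercept) and run the full analysis:

```python
from tnfvigil import PipelineConfig, run_pipeline, SyntheticConfig
from tnfvigil.curation import AGENTS

cfg = PipelineConfig(seed=7, synthetic=SyntheticConfig(
    n_cases={a: 1000 for a in AGENTS},
    planted_associations={
        ("infliximab", "Clostridium difficile infection"): 10.0,
        ("etanercept", "Injection site pain"): 8.0}))
manifest = run_pipeline(cfg, "all", outdir="demo")
print(manifest.attrition_chain())
```

```
[('raw', 5507), ('deduplicated', 4893), ('ps_restricted', 4587),
 ('pediatric', 3699), ('post_filter', 3505)]
```

5,507 raw report versions collapse to 4,893 deduplicated reports; 4,587
survive the Primary-Suspect restriction, 3,699 the pediatric age filter and
3,505 the PT-level filters. The ranked signal table (`demo/signals.csv`)
recovers both planted pairs at the top:

```
      drug   pt                               n    ror    ci_low  ci_high  chi2      is_signal
etanercept   Injection site pain              257  7.4858  6.0272   9.2973  406.3157  True
infliximab   Clostridium difficile infection   54  9.5580  5.8250  15.6834  116.0555  True
```

The estimates (7.49 and 9.56) sit inside their confidence intervals around
the planted truths (8 and 10); nothing else clears the default criteria
except one borderline pair, consistent with the measured ~3% per-pair
false-flag rate of the criteria under the null. `demo/onset_summary.csv`
reports the pooled median time-to-onset (256 days, IQR 68–921 here) with
the missing-timeline exclusions tallied, and `demo/wilcoxon.csv` holds the
era-split signed-rank comparison (p ≈ 0.99: no era effect was simulated).

The same pipeline runs from a shell:

```sh
tnfvigil simulate --seed 7 --outdir demo
tnfvigil all --seed 7 --outdir demo --min-cases 3 --chi2 4
```

Pointing `--quarters` (or `quarters_dir` in the YAML config) at a directory
of real FAERS quarterly ASCII files, plus a licensed PT→SOC mapping TSV,
runs the identical analysis on real data.

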