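# Methods

## Scope and data model

The package analyses spontaneous adverse-event reports for the five TNF-α
inhibitors in pediatric patients (< 18 years). Input is the FAERS quarterly
ASCII layout: seven `$`-delimited tables per quarter (DEMO, DRUG, REAC,
OUTC, THER, INDI, RPSR), one header row each, plus a deleted-case list (one
case id per line). Column names are matched case-insensitively and
LAERS-era variants (`ISR`→`primaryid`, `CASE`→`caseid`, `GNDR_COD`→`sex`)
are mapped through a user-extensible alias table, since the schema drifted
over the 2004–2024 study window. Unknown extra columns are preserved.
Files are decoded as UTF-8 with a logged Latin-1 fallback. Malformed rows
(wrong field count, role/outcome/age-unit codes outside their enumerated
domains, empty required ids) are excluded and logged with their line
numbers rather than silently dropped. Rows referencing a report version
absent from DEMO are kept but flagged as orphans and fall out at curation,
so the attrition accounting stays complete.

Dates are digit strings of length 8, 6 or 4 and are parsed into a
date-with-precision (day / month / year). No component is ever imputed;
each consumer states how it treats partial dates.

## Cohort curation

Stages, in order, each with an exclusion tally so that
`raw = retained + Σ reasons`:

1. **Deduplication.** Per CASEID keep the version with the latest FDA
   receipt date; ties go to the highest PRIMARYID (numeric comparison when
   both ids are digit strings, lexicographic otherwise). Partial receipt
   dates are compared at available precision with missing components
   treated as lowest, which yields a deterministic total order. Cases on
   the pooled deleted lists are then removed. The operation is idempotent
   and invariant to input order and row duplication.
2. **Primary-Suspect restriction.** A report is kept iff its PS-role drug
   maps to exactly one of the five agents. Mapping normalises the verbatim
   name to uppercase tokens and requires a dictionary synonym (generic or
   brand, e.g. HUMIRA → adalimumab) as a contiguous token subsequence;
   names matching two agents are ambiguous and excluded with a log entry.
   Reports from quarters before the agent's approval quarter are dropped
   (relevant to golimumab, approved 2009Q2, and certolizumab, 2008Q2; the
   other three predate the 2004Q1 study start).
3. **Pediatric age filter.** Ages are converted to years (DEC×10, YR×1,
   MON÷12, WK×7/365.25, DY÷365.25, HR÷8766); negative or non-numeric
   values are treated as absent. Ages above 120 years are implausible.
   Retention requires 0 ≤ age < 18 (strict); the three analysis strata are
   the half-open intervals [0,4), [4,12), [12,18), read off the integer
   labels 0–3 / 4–11 / 12–17 with full coverage of the pediatric range.
4. **PT filters.** Indication PTs for the report's own agent are dropped
   per-PT (indication-bias control); the shipped per-agent lists are
   editable data, not code. Reports left with no PTs are excluded. A
   report whose only PT is "Off-label use" is retained — golimumab has no
   pediatric approval, so pediatric exposure is inherently off-label, and
   the rule is applied to all five agents for comparability. Reports whose
   remaining PTs all map to the Product Issues SOC are excluded: they
   describe device or administration faults, not medicinal reactions.

Reporter occupation codes collapse to five classes (MD→Physician,
PH→Pharmacist, OT/RN/HP→Other health professional, CN→Consumer, anything
else→Unknown/other). Lawyers (LW) fall under Unknown/other since they are
not health professionals.

## Disproportionality

ROR, its Woolf (log-normal) 95% CI and the Pearson χ² are computed exactly
as printed in the README. Defaults and the reasoning behind them:

- **Comparator**: within-class (the other four agents' curated reports).
  The curated dataset contains only this drug class, so class-level pooled
  questions require externally supplied background counts; both modes are
  exposed and neither is asserted as uniquely correct.
- **Zero cells** yield an "undefined" result (serialised `/`), matching
  how sparse rows are conventionally published; the Haldane–Anscombe 0.5
  correction exists behind a flag but is off by default.
- **χ²** is Pearson without continuity correction by default; a Yates flag
  is provided. Both variants are cross-checked against
  `scipy.stats.chi2_contingency` in the tests.
- **Signal criteria**: n ≥ 3 AND lower CI > 1 AND χ² > 4. An ROR > 2
  screen is available but off by default. Tightening any criterion can
  only remove flags (tested property).
- **Prioritisation** sorts by report volume, then by how many agents flag
  the same PT (pan-class recurrence), then alphabetically — deterministic.
- **No multiple-testing adjustment** is applied anywhere. With ~140
  drug–PT pairs at the default criteria the measured per-pair false-flag
  rate under the null generator is about 3%, so a handful of chance flags
  per full screen is expected; flags are screening output.

## Descriptive summaries

The demographics table tabulates sex, age strata, reporter class and
outcome categories per agent and pooled. FAERS outcome codes are
multi-valued, so outcome rows are non-exclusive category counts (a case
with {HO, LT} appears in both rows); a severe-outcome row counts cases
with any of death, life-threatening, disability or hospitalization.
Percentages are recomputed from counts and rounded half away from zero
(one decimal in tables, two for quoted shares) — Python's banker's
rounding is deliberately not used.

Time-to-onset is the day difference between the earliest day-precision
therapy start of the suspect drug and the day-precision event onset date.
Partial dates are never imputed: such cases are tallied as missing
timelines, events before therapy start as implausible, and
`n_input = n_with_onset + missing + implausible` always holds. Summaries
report the median and quartiles (linear interpolation between order
statistics) and 30-day histogram bins (0,30], …, (330,360], (360,∞), with
same-day onsets in the first bin.

Age-stratum comparisons report per-SOC case proportions against the
stratum case total (cases span SOCs, so proportions need not sum to 100)
and a top-10 PT ranking per stratum, count-descending with alphabetical
ties.

## Era-split sensitivity analysis

The cohort is partitioned by FDA receipt date at a configurable cutoff
(default 2014Q1) into early and recent eras. The 50 most frequently
reported PTs over the pooled cohort form paired observations. Because a
per-PT "class-level" ROR is not well defined inside a single-class cohort
(pooling the five per-agent fourfold tables by cell-wise summation
provably collapses to ROR = 1), each PT's era ROR is the within-class ROR
of its *lead agent* — the agent reporting that PT most often in the pooled
cohort — held fixed across both eras so each pair measures one stable
drug–event contrast.

The paired RORs are compared with a two-sided Wilcoxon signed-rank test:
zero differences dropped before ranking, average ranks for tied absolute
differences, exact p by full sign enumeration (via scipy) when n ≤ 12
without ties, otherwise a normal approximation with tie correction and a
0.5 continuity correction. The Z statistic is always reported from the
normal approximation. Pairs with an undefined ROR in either era are listed
but excluded from the test.

## Synthetic generator

The generator emits FAERS-dialect quarters with a fully known ground
truth. Per case: an agent (case counts per agent configurable, default
2,000 each), a PS drug row under the agent's brand name plus occasional
concomitant distractor drugs, independent Bernoulli inclusion of each
vocabulary PT at its baseline probability — shifted on the odds scale by
the planted multiplier θ for pairs under study — sex/reporter/outcome
draws, ages from the three-stratum pediatric mixture (7/24/69%, matching
the reported stratum shares for this drug class) plus a 15% adult fraction
and 5% missing ages, emitted in mixed units (YR/MON/WK/DY) to exercise the
unit conversion; therapy start, a log-normal onset delay (median ≈ 235
days, quartiles ≈ 46/832 days, matching the reported class-level onset
distribution) and a uniform 0–180-day reporting lag determine the event
and receipt dates, hence the quarter. A configurable fraction of cases
emits an earlier duplicate version (same CASEID, earlier receipt date,
lower PRIMARYID) and another fraction lands on the deleted list, so the
exact post-deduplication survivor set is known by construction. Reports
with no sampled reaction receive a filler term ("Drug ineffective") rather
than a resample, which keeps every analysed PT's per-report probability
exact. Small fractions of reports are forced to be off-label-only (5%) or
product-issue-only (1%) to exercise the retention/exclusion rules, and
each agent co-reports its own indication PT on 10% of reports to exercise
indication filtering. Everything derives from one seeded generator;
identical config + seed gives byte-identical files.

`planted_truth` returns the expected ROR per planted pair from the
generative probabilities: with the forcing fractions f_ol and f_pi, the
retained-universe inclusion probability in each arm is
p·(1−f_ol−f_pi)/(1−f_pi) and the expected ROR is the odds ratio of the two
adjusted probabilities. A second-order correction from indication-only
exclusions (reports whose only term was an indication PT) is ignored;
with indication co-reporting at its default 10% this perturbs the
expectation by well under 1% relative. The parameter-recovery experiments
(`tnfvigil.experiments`) use a calibration configuration with all three
composition knobs at zero, where the planted θ is exactly the per-report
odds ratio.

PT sampling is independent across PTs — the simplest generative model
consistent with fourfold-table analysis. Real spontaneous reports violate
this (reaction terms co-occur in syndromes), and the generator makes no
attempt to match real FAERS marginal frequencies, reporting-volume trends,
or label-change dynamics. Passing tests therefore demonstrate correctness
of the estimator and plumbing under the stated model, not calibration
against real reporting behaviour.

## Validation and problem sizes

The replicate studies run at sizes chosen to make the checks sharp while
keeping the whole suite quick on a single CPU: CI coverage of a planted
ROR = 10 uses 2,000 cases per agent × 200 replicates (measured coverage
≈ 93–96% against the nominal 95%); null calibration uses 800 cases per
agent × 50 replicates (≈ 7,000 drug–PT pairs, flag rate ≈ 2.5–3%);
determinism and deduplication checks use 200–250 cases per agent. The
formula oracle re-evaluates the printed formulas directly on 1,000 random
tables with cells in [1, 50] and agrees to ~1e-15 relative error.

## Known limitations

- The ROR measures reporting disproportionality, not incidence or causal
  risk; there is no exposure denominator.
- Indication-PT exclusion is per-PT, not per-report; a report that listed
  both an indication term and a reaction keeps the reaction.
- The lead-agent convention for era comparisons is one defensible choice
  among several; the per-agent signal tables per era are available for any
  alternative pairing.
- The drug dictionary is token-exact over a short synonym list; real
  FAERS verbatim names (misspellings, compound strings) would need a
  richer dictionary, which can be supplied as YAML.
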