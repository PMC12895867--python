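# pvsignal

Pharmacovigilance signal detection for spontaneous adverse-event report
databases, built around the analysis design used for thromboembolic events
(TEEs) under the intravenous antiangiogenic monoclonal antibodies
bevacizumab, ramucirumab and aflibercept: ingestion and deduplication of
FAERS-dialect quarterly ASCII archives, MedDRA-Preferred-Term event
classification, cohort construction with route/reporter/role filters,
disproportionality statistics with signal thresholds, time-to-onset
analysis, and a multivariable logistic model of fatal outcome.  A bundled
synthetic-archive generator with closed-form ground truth makes every stage
testable without downloading the real database.

It is aimed at pharmacoepidemiologists and drug-safety analysts who want a
scripted, reproducible version of the standard FAERS workflow instead of a
chain of SQL and spreadsheet steps.

## The statistics

Each drug–event combination is reduced to a 2×2 table over the deduplicated
report universe (a = target drug & target event, b = drug & other events,
c = other drugs & event, d = neither).  Two disproportionality measures are
computed:

* **Reporting odds ratio** — ROR = (a·d)/(b·c), with the Woolf 95% CI
  `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`; the Haldane–Anscombe
  correction (+0.5 to every cell) is applied only when a cell is zero.
* **Information component** — IC = log₂((a + 0.5)/(E + 0.5)) with
  E = (a+b)(a+c)/N, the shrinkage form used in BCPNN screening, with a
  closed-form 95% credibility interval (a gamma-posterior quantile interval
  is available as an option).

A combination with at least three reports is flagged as a **signal of
disproportionate reporting** when the ROR CI lower bound exceeds 1 *and*
the IC interval lower bound exceeds 0.  No multiple-testing adjustment is
applied — these are screening signals, not confirmatory tests.

Time to onset is EVENT_DT − START_DT in whole days (day-complete dates
only, negative intervals excluded as input errors), compared across groups
with Mann-Whitney U / Kruskal-Wallis tests.  Fatal outcome (outcome code
DE) is modelled as `logit P(fatal) = β₀ + β·TEE + sex + age group + drug`,
reported as adjusted odds ratios with Wald intervals.

## Worked example

Simulate a four-quarter archive of 6 000 reports with an 8-fold odds
multiplier planted on pulmonary-embolism reporting under bevacizumab, then
run the full pipeline:

```yaml
# run.yaml
simulate:
  n_reports: 6000
  planted_signals:
    - {drug: BEVACIZUMAB, target: PULMONARY EMBOLISM, odds_multiplier: 8.0}
seed: 11
```

```
$ pvsignal all --config run.yaml --out out/
```

`out/signals.tsv` then contains (excerpt):

```
drug         event  n   expected  ror       ror_lower  ror_upper  ic        ic_lower  ic_upper  evaluated  signal
BEVACIZUMAB  PE     21  5.01537   6.91286   3.8783     12.3218    1.96281   1.23105   2.47539   True       True
BEVACIZUMAB  MI     3   4.59742   0.624878  0.192799   2.02529    -0.542413 -2.61178  0.66408   True       False
```

The planted pulmonary-embolism effect is recovered (21 reports observed
against 5.0 expected, ROR 6.9 with CI above 1, IC025 = 1.23 > 0 → signal),
while myocardial infarction, where nothing was planted, stays below both
thresholds.  The other tables are `cohort_summary.tsv` (descriptive
percentages of the TEE cohort), `pt_scan.tsv` (per-PT IC lower bounds),
`head_to_head.tsv` (drug-vs-drug comparisons), `onset_tests.tsv` and
`cumulative_incidence.tsv` (time-to-onset), and `mortality_forest.tsv`
(TEE-vs-non-TEE fatal-outcome odds ratios per stratum).  `manifest.json`
records input hashes, the config echo and the seed; a rerun with the same
config is byte-identical.

The same stages are available as a library (`pvsignal.faers_io`,
`pvsignal.event_dictionary`, `pvsignal.cohort`, `pvsignal.signal_stats`,
`pvsignal.onset_analysis`, `pvsignal.outcome_model`,
`pvsignal.synthetic_faers`, `pvsignal.pipeline`).

MedDRA is licensed, so real-data runs require a user-supplied PT-list
dictionary (`dictionary: path/to/lists.yaml`); the bundled dictionary is a
small synthetic fixture for tests and examples.

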