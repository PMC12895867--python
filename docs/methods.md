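# Methods

This note documents the statistical procedures, parameter defaults and
numerical conventions implemented in pvsignal, and what the bundled
synthetic data can and cannot establish.

## Report ingestion and deduplication

FAERS quarters are `$`-delimited ASCII tables without quoting or escaping,
so lines are split on the literal delimiter; a data line whose field count
differs from the header goes to a structured rejects log and is skipped.
Nothing is ever silently dropped — report-count figures must be auditable
against the rejects file.  Both the modern (PRIMARYID/CASEID) and legacy
(ISR/CASE, pre-2012Q3) dialects parse into one internal schema, with the
legacy ISR mapped into `primaryid`, because analysis windows that start in
2004 span the dialect change.

Dates are kept as *partial dates* (day, month, year or no precision);
impossible calendar content degrades to no precision rather than raising.
Ages are converted to years with DEC×10, YR×1, MON÷12, WK÷52.14, DY÷365.25
and HR÷8766 — the week and hour divisors follow the 365.25-day-year
convention and live in one constant table.  A blank age unit is read as
years, the dominant FAERS convention.

Deduplication keeps, per case identifier, the version with the latest FDA
receipt date, ties broken by numerically largest primaryid — the
latest-version rule the FDA recommends for its quarterly extracts.  The
stricter multi-field clinical-duplicate heuristics used by some groups are
deliberately out of scope: the simple rule is exactly testable and matches
the cited guidance.  Reports with an empty caseid cannot be grouped and are
kept as flagged singletons.  The operation is idempotent and
order-independent (output sorted by caseid).

## Event classification

Reactions are MedDRA Preferred Terms.  The thromboembolic universe is split
into three disjoint top-level categories — venous (VTE), arterial (ATE) and
vessel-unspecified/mixed — with subtype lists PE ⊆ VTE and MI,
cerebral ATE ⊆ ATE; overall TEE is always the derived union, never stored.
Containment and disjointness are enforced at load time.  Matching is exact
string equality on upper-cased, trimmed PTs; REAC rows are already
PT-coded, so fuzzy matching would only add false positives.  A report
counts at most once per label however many matching PTs it lists; a report
with both VTE and ATE terms counts in both categories but once in overall
TEE.  MedDRA is licensed, so the shipped dictionary is a small synthetic
fixture and real analyses must supply their own lists.

## Cohorts

A report enters a drug cohort iff (i) a drug entry matches the drug of
interest (case-insensitive containment of a configured synonym — ingredient
or brand — in the verbatim name or active-ingredient field) with role
primary suspect, (ii) that entry's route class passes the route filter,
(iii) the reporter qualification passes, (iv) a dated event falls inside
the window.  Route classes: anything starting with INTRAVENOUS is
intravenous; INTRAVITREAL/OPHTHALMIC/INTRAOCULAR are intraocular; blank is
unspecified and excluded by default — this is what removes intraocular use
of agents that are also injected into the eye.  The default reporter filter
is physicians, pharmacists and other health professionals; RN-coded
reporters in some quarters are not mapped into the accepted set by default
but the filter is configuration.  The filters are pure predicates, so their
application order cannot change the cohort.

Therapy class: `plus_chemotherapy` if any co-reported drug is in the
configured chemotherapy list, else `other_combined` if in the configured
non-chemotherapy antineoplastic list, else `monotherapy`.  Indication
groups come from a substring-match table over INDI terms (colorectal,
NSCLC, gastroesophageal, ovarian, glioblastoma, other, unknown).

Descriptive percentages are computed over the full cohort for sex, age
group, outcome, country, indication and therapy class, and over the subset
with a computable onset for the onset bins (that subset size is reported as
the block's denominator).  Percentages round half-up to one decimal, the
convention of the published tables this mirrors.

## Disproportionality

The 2×2 cells are counts of *distinct deduplicated reports*.  The
comparison universe defaults to the same reporter provenance as the cohorts
(health professionals); this is a config switch because public analyses are
often ambiguous on the point.

ROR = (a·d)/(b·c) with the Woolf interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).  The Haldane–Anscombe +0.5
correction is applied to all four cells only when some cell is zero, and
only for the ROR, so point estimates on non-degenerate tables are
untouched; a policy switch instead marks zero-cell tables non-evaluable.

IC = log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N.  The default 95% interval is
the closed-form shrinkage approximation
IC₀₂₅ = IC − 3.3(a+0.5)^−½ − 2(a+0.5)^−³ᐟ²,
IC₉₇₅ = IC + 2.4(a+0.5)^−½ − 0.5(a+0.5)^−³ᐟ²;
a Gamma(a+0.5, rate E+0.5) posterior-quantile interval is available behind
the same function.  The shared +0.5 offset makes IC > 0 ⟺ a > E exactly.

A combination is evaluated only at a ≥ 3 reports; the signal flag requires
both ROR CI lower bound > 1 and IC interval lower bound > 0.  No
multiple-testing adjustment is applied across PTs or categories — the
outputs are screening signals.  Head-to-head comparisons restrict the
universe to the two cohorts (which must be disjoint by report id; a report
primary-suspect for both drugs is excluded upstream and logged) and use the
same estimators and thresholds.

## Time to onset

Onset = event date − therapy start of the primary-suspect drug, in whole
days, only when both dates are day-complete and the interval is
non-negative; everything else is excluded with an explicit reason (missing,
partial precision, negative interval).  Partial dates are excluded rather
than imputed by default — spontaneous-report dates are unreliable and the
upstream convention is to treat them as input errors — though a
first-of-month imputation mode exists for sensitivity analyses.  With
multiple therapy episodes the earliest dated start is used.

Bins are the closed integer ranges [0,30], [31,60], [61,90], [91,180],
[181,365], [366,∞).  Quartiles default to linear interpolation of order
statistics (the numpy default); Tukey inclusive hinges are a switch, since
printed tables rarely state their convention.  The Mann-Whitney U test uses
exact enumeration for samples of at most 8 per group without ties and
otherwise the normal approximation with midranks, tie-corrected variance
and continuity correction; Kruskal-Wallis uses midranks, the standard tie
correction and the χ² tail with k−1 degrees of freedom.  Degenerate input
with every pooled value identical returns p = 1 rather than NaN.
Cumulative incidence curves are empirical CDFs of observed onsets per
group — no censoring model, because spontaneous reports carry no follow-up.

## Fatal-outcome model

Among reports with a study drug as primary suspect, fatal outcome (code DE;
all-cause, not cause-attributed) is regressed on TEE status with sex, age
group and drug as categorical covariates.  Reference levels: non-TEE, male,
18–64 years, bevacizumab.  Unknown sex and age are retained as explicit
levels because dropping them would shrink the cohort materially (about a
quarter of reports lack age); a complete-case switch exists.  Declared
levels with no rows are dropped with a log entry.  Estimation is maximum
likelihood (IRLS via a binomial GLM); intervals are Wald, exp(β ± 1.96·se),
matching the symmetric-on-log-scale intervals conventionally reported.
Perfect separation (a fitted probability within 1e-8 of 0/1 with a runaway
coefficient) is reported as a diagnostic with no odds ratios emitted.
Subgroup fits (per indication, within one drug) adjust for sex and age
only.  Strata without outcome variation in an exposure arm are emitted with
a not-estimable flag rather than dropped.

## Synthetic archives and ground truth

The generator samples, per case: a primary-suspect drug from a catalog with
configured prevalences; a route and reporter; demographics; TEE PTs as
independent Bernoulli draws at configured background probabilities, with
planted effects applied as multipliers on the *odds* of the target PT (or
of every PT in a target category) given the drug; a fatal flag with
exposure-dependent odds; a log-normal onset per drug.  Duplication (an
extra earlier version with an advanced-receipt-date final version), date
truncation and missingness are applied after truth is recorded, so the
truth reconstructs every sampling decision.  Identical (config, seed) pairs
produce byte-identical archives.

Because planted effects are odds multipliers, the implied population ROR is
available in closed form from the configuration (expected cells over the
catalog), and recovery tests compare the estimate to that value — not to
the raw multiplier, which only approximates the ROR for rare events.

Defaults mirror the study conditions this package operationalizes: onset
medians 60.5 / 26.5 / 31.5 days for bevacizumab / ramucirumab / aflibercept
with log-scale σ = 1.25 (the upper-quartile-to-median ratios of the
published onset distributions are near e^{0.674·1.25}), fatality base 0.25
with a TEE odds multiplier of 1.2, TEE PT backgrounds of 0.08–0.6% per
term, 10% duplicate cases, 5% month-truncated dates.

What the generator does **not** emulate: real MedDRA term frequencies or
co-reporting structure, correlated multi-drug regimens, reporting-rate
drift over quarters, country- or indication-dependent outcome rates, or
clinically coherent PT co-occurrence.  Passing recovery tests therefore
demonstrates that the estimators and plumbing are correct under the stated
sampling model — not that real-data signals are unbiased, which no
simulation can establish for spontaneous reports.

## Pre-specified simulation studies

The calibration and recovery studies in `pvsignal.studies` fix their
designs up front:

* null calibration: 2000 multinomial 2×2 tables at N = 1e5 under
  independence (drug margin 10%, event margin 5%, so the drug–event cell
  expects 500 reports);
* signal recovery: one archive of 1e5 reports, ×3 odds multiplier on the
  pulmonary-embolism terms of bevacizumab;
* mortality recovery: one archive of 1e5 reports with the fatal-odds
  multiplier 1.2 and a raised TEE background (≈20% of cohort rows exposed);
* onset separation: 500 onsets per group from medians 60.5 vs 26.5 days.

The study drugs carry elevated catalog prevalence (0.40 combined) in the
recovery designs, and the mortality design raises the TEE background, for
one reason: at these sizes the relevant cells hold hundreds to thousands of
reports, so sampling error is a small fraction of the recovery bands.
These are power choices made from the CI formulas when the designs were
written; they are not estimates of real reporting shares.

## Known limitations

* Drug matching is substring-based over a synonym table; unusual verbatim
  spellings need explicit synonyms.
* The dedup rule is identifier-based only; true clinical duplicates filed
  under different case ids survive it, as they do in the FDA rule.
* The PT dictionary fixture is illustrative; category membership on real
  data is entirely determined by the user's MedDRA-derived lists.
* Fatal outcome is report-level all-cause death, with all the reporting
  biases of spontaneous data; the model adjusts only for sex, age, and
  drug.
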