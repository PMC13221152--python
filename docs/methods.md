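# Methods

This note documents the models, rules and design choices implemented in
`hcepi`, the parameters that matter, what the synthetic cohort generator
does and does not emulate, and the package's known limitations.

## Exposure-episode model

Prescription purchase invoices are converted to exposure under a
consistent-use assumption: each purchase covers a deterministic number
of days given by the formulation catalog (28 days per package unit for
short-acting methods, 35 for the levonorgestrel-only pill G03AC03,
1,095 days for the implant, and 1,095/1,835/2,190 days for the
13.5/19.5/52 mg levonorgestrel IUD). Dosage is a package multiplier;
day counts round half away from zero to whole days.

Periods are closed intervals on a daily grid. Same-formulation
purchases merge while consecutive purchase dates are **strictly less
than 90 days** apart (90 splits); drug-free days inside a chain belong
to the period, reflecting that fecundity returns only two–three months
after discontinuation. Numerical conventions that the data do not pin
down, chosen once and fixed:

* **Coverage clock.** Each refill resets the coverage clock (period end
  = last purchase date + its covered days − 1); unused days from the
  previous purchase do not accumulate. Same-day purchases of the same
  formulation sum their covered days, because multi-package buys are
  often split across invoices. The additive carry-over alternative is
  implemented behind `coverage_mode="carry"`; clock reset is the
  default since refill gaps — not coverage ends — drive the merging
  rule.
* **Switches.** A purchase of a different formulation always opens a
  new period. If the previous period is still covered it is truncated
  to the day before (minimum one-day period) so periods never overlap.
  A switch purchased on the same day as the previous formulation's last
  purchase is resolved the same way; that degenerate case leaves the
  stranded purchase date outside the truncated period and does not
  occur in generated data.
* **Pregnancy censoring.** ICD-10 O00–O99, excluding the puerperium
  block O85–O92, ends a period on the earliest qualifying date inside
  it. No backdating is applied, because gestational timing of pregnancy
  codes varies too widely; a code on the start date collapses the
  period to one day rather than deleting it.
* **Administrative censoring.** Periods truncate at the study end
  (2022-12-31) and at the last day of the calendar year in which the
  participant turns 55 — ages are computed as year differences
  throughout (purchase year − birth year), so the age limit is also a
  year-end boundary.

A brute-force day-grid simulator (independent integer-day
implementation in the test suite) reproduces `build_periods` exactly on
1,000 randomised ≤ 5-purchase fixtures including pregnancy censoring.

## Filtering cascade

Raw invoices pass five ordered filters: HC selection (ATC G02B/G03A
prefixes plus G03HB01, dropping emergency contraceptives G03AD), exact
prescribed = purchased ATC match, short-acting dosage within [0.3, 6]
(bounds inclusive; long-acting exempt), age at purchase within [15, 55]
(inclusive), and an individual-level BMI filter: the BMI record closest
to the first retained purchase date must lie within [14.0, 43.0].
Decisions the source rules leave open: a missing ATC code counts as a
mismatch (the match cannot be affirmed); missing dosages are dropped
under the dosage filter and counted separately; equidistant BMI ties
resolve to the earlier record; individuals with *no* BMI record are
retained — only out-of-range values exclude. The report object proves
conservation (removals sum to input − output) and the cascade is
idempotent.

## Switching phenotypes

Labels follow the period definitions in the README. Two deliberately
resolved ambiguities: the rapid-switch criterion (gap ≤ 90 days,
pre-switch period < 90 days) applies to **any** consecutive
different-formulation pair, not only the first, and a user may
contribute several rapid-switch events; and rapid-discontinuer
verification accepts **any** later ICD-10 record as residency evidence,
since its purpose is ruling out emigration, not clinical relevance.
Formulation identity is the catalog key (ATC level 5, with the
transdermal gestodene/ethinylestradiol product "G03AA10(p)"
distinguished from the oral pill that shares its ATC code).

## Diagnosis windows

All windows are closed day intervals and translation-invariant:
90 days before the first period start for initiation reasons; the
period plus 90 days after its end for candidate side effects —
restricted to first-time-ever codes over the participant's whole
history to exclude pre-existing conditions; the interval between the
two first-purchase dates of a rapid switch (both endpoints inclusive)
for gap diagnoses; original (pre-censoring) coverage for
abortion-overlap queries. Code sets live in a registry: 3-character
entries match all subcodes, 4-character entries match exactly, and
ranges are inclusive over the category ordering with exclusion
sub-ranges (the pregnancy definition requires inclusive endpoints).
Because the full curated code lists are not published, the shipped
defaults cover the codes that are — Z30, N92, O04, N94, L70, E28.2 for
initiation reasons; N92, G43, R51, L70, N94, F32, F41, N64.4 for the
side-effect panel; I80, I80.2, I80.3, I26.9, I82.8 for
venous/arterial thromboembolism — and every set is overridable from a
YAML file for real-data parity.

## Risk factors and statistics

The 15-factor roster pairs seven fixed factors (age > 35 by year
arithmetic; obesity as closest BMI ≥ 30; migraine; H02/N05A/N06A
medication purchase; FVL/PTM carriage with imputed dosages thresholded
at ≥ 0.5 copies; personal thromboembolism history over the whole record
before the index date; family history in first-degree relatives before
the index date) with eight registry-named condition sets defaulting to
standard ICD-10 chapters (hypertension I10–I15, hyperlipidaemia E78,
diabetes E10–E14, pneumonia J12–J18, cardiovascular disease I20–I25,
cancer C00–C97, smoking-related F17, other thrombosis-risk D68 + I83).
The condition/medication lookback is the closed 730-day window ending
on the index date. Missing genotypes leave the carrier factor missing
and drop out of that factor's denominators.

The 2×2 layer is self-contained: Katz log-intervals for prevalence
ratios and Woolf intervals for odds ratios (the conventional defaults;
published intervals computed by other CI methods can differ in the
second decimal while point estimates agree), a 0.5 continuity
correction applied only when a cell is zero, Fisher's exact test under
the probability-mass two-sided definition with exact integer
hypergeometric weights (no floating-point tie ambiguity), Wald
proportion intervals truncated to [0, 1] (degenerate and flagged at
p̂ ∈ {0, 1}), and Bonferroni adjustment `min(1, m·p)` with m = 15 by
default.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the *structure*
the pipeline assumes, not Estonian demography. Defaults are the study
conditions: archetype mix 23.9% non-switchers / 46.5% broad /
17.7% rapid / 7.3% rapid discontinuers / 4.6% other; Hardy–Weinberg
genotypes at MAF 0.02 (FVL) and 0.01 (PTM); a carrier–thrombosis odds
ratio of 1.6 over a 4.2% non-carrier baseline; a 3.2% pregnancy
interruption rate; a 23.1% side-effect-diagnosis rate inside
rapid-switch gaps; 60% of participants linked to a first-degree
relative; and corruption rates matching the observed exclusion
fractions (1.8% ATC mismatch, 0.04% dosage, 0.1% age, 1.1% of
individuals BMI). First-purchase ages draw from N(28, 9.2²) clipped to
[16, 50] and BMI values from N(24.3, 4.6²).

Design choices: one integer seed drives five named substreams
(demographics, purchases, genetics, diagnoses, corruption) so adding
draws to one stream never perturbs another, and identical
configurations are byte-identical. Archetype streams are constructed so
the pipeline provably recovers the label — e.g. pregnancy interruptions
are placed where censoring cannot cross a defining threshold (after day
181 of a non-switcher period, in the post-switch period of a rapid
switcher), and every stream is placed far enough from the study end
that administrative truncation cannot flip a label. Corruption is
planted as *extra* labelled rows (and extra out-of-range BMI records
dated on the first purchase), recorded only in a side table, so the
clean streams are untouched and the filters must rediscover exactly the
planted rows.

What the generator does **not** emulate: market-availability calendars,
seasonality and the 2020 purchasing shock, realistic age–archetype
dependence, correlated diagnoses, IUD removals, or family-structure
beyond disjoint pairs. Passing tests therefore demonstrate correctness
of the episode/classification/statistics machinery under the stated
assumptions, not fidelity of any particular cohort-level estimate to a
real population.

## Problem sizes

The test suite and acceptance script choose sizes that make their
statistical checks sharp but cheap: 1,000 randomised fixtures for the
day-grid oracle, every 2×2 table with total ≤ 40 (135,751 tables) for
the Fisher cross-check, 20,000 participants for Hardy–Weinberg and
allele-frequency checks, ten replicates of 50,000 participants for
odds-ratio recovery, 1,000 participants per archetype for label
recovery, and 3,000 participants for planted-corruption recovery. The
full suite runs in about two minutes and the acceptance script in about
two minutes on one CPU.

## Known limitations

Covered days assume guideline-consistent use; actual adherence is
unobservable in claims data, so episode lengths are upper bounds.
Long-acting method removals cannot be detected, only pregnancy-censored.
Same-formulation brand/regimen differences are ignored by construction.
The default diagnosis code sets are a documented subset of the
unpublished curated lists and should be replaced for real-data use.
Confidence-interval methods for PR/OR are fixed to Katz/Woolf; exact or
mid-p intervals are not implemented.
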