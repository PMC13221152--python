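# hcepi — hormonal-contraceptive exposure epidemiology

`hcepi` is a Python library for pharmacoepidemiologists working with
prescription-claims data on hormonal contraceptives (HCs). Pharmacy
purchase invoices record *when a package was bought*, not *when the drug
was used*; the library turns purchase streams into contiguous exposure
episodes ("usage periods"), classifies each woman's
formulation-switching behaviour, links ICD-10 diagnosis windows to the
episodes, and quantifies clinical and genetic thromboembolism risk
factors with 2×2 contingency statistics. A synthetic cohort generator
with the same linkage structure (participants ↔ purchases ↔ diagnoses ↔
genotypes ↔ first-degree relatives) makes the whole pipeline testable
without access-restricted biobank data.

## The method

**Exposure episodes.** Each purchase of formulation *f* on day *t*
covers `round(dosage × d_f)` days, where `d_f` = 28 days per package
unit for pills, patches and rings (35 for the levonorgestrel-only pill
G03AC03), 1,095 days for the etonogestrel implant, and 1,095/1,835/2,190
days for the 13.5/19.5/52 mg levonorgestrel IUD. Purchases of the same
formulation with inter-purchase gaps < 90 days chain into one closed
period `[t_first, t_last + cover(t_last) − 1]`; drug-free days inside a
chain count as exposure. A purchase of a different ATC level-5 code
always opens a new period (truncating a still-covered one to the day
before), and periods are censored at pregnancy codes (O00–O99 excl.
O85–O92) inside original coverage, at the study end, and at age 55.

**Switching phenotypes.** From ordered periods: *broad switchers* used
≥ 2 formulations; *rapid switchers* (⊂ broad) had an inter-period gap
≤ 90 days after a pre-switch period < 90 days; *non-switchers* used one
formulation with a period > 180 days; *rapid discontinuers* had a single
period < 90 days, verified by a later diagnosis record (residency
evidence) and a first purchase > 90 days before study end; everyone else
is unclassified.

**Risk factors.** Users with an index-year purchase split into combined
(CHC) vs progestin-only (POC) groups by their first purchase of the
year. Fifteen risk factors — age > 35, obesity (closest BMI ≥ 30),
migraine, risk-increasing medications (ATC H02/N05A/N06A), Factor V
Leiden (rs6025) or prothrombin G20210A (rs1799963) carriage, personal
and family thromboembolism history, and eight configurable condition
sets — are assessed over a closed 730-day lookback ending on the index
date. Group contrasts use the prevalence ratio `PR =
p̂_CHC / p̂_POC` with a Katz log-interval, odds ratios `OR = ad/bc` with
Woolf intervals, exact two-sided Fisher tests (integer hypergeometric
enumeration), Wald proportion intervals, and Bonferroni correction
across the 15 factors.

## Worked example

Three purchases of a drospirenone/ethinylestradiol pill (G03AA12, three
packages each), a medical-abortion code during coverage, then a switch
to a desogestrel progestin-only pill (G03AC09):

```python
>>> from hcepi import build_periods, censor_by_pregnancy
>>> periods = censor_by_pregnancy(build_periods(purchases), diagnoses)
```

```
formulation_key start_date   end_date  length_days  n_purchases censor_reason
        G03AA12 2010-01-01 2010-07-10          191            3     pregnancy
        G03AC09 2011-02-01 2011-04-25           84            1          none
```

The pill purchases merge into one 191-day episode ending on the
pregnancy diagnosis date; the later progestin-only purchase opens a
fresh 84-day episode. Running the contingency layer on the published
family-history × carrier counts (76/1,022 vs 327/7,375):

```
family history vs carrier: OR = 1.73 [1.34, 2.24], p = 8.4e-05
sensitivity of family history for carrier status: 18.9% [15.0, 22.7]
specificity: 88.2% [87.5, 88.9]
```

i.e. women with an affected first-degree relative have 1.7-fold higher
odds of carrying a high-risk variant, yet family history identifies
fewer than one in five carriers. The `examples/` directory holds four
short scripts (period construction, switching classification, cohort
trends on a simulated cohort, risk-factor statistics) that print these
numbers and explain them; a thin CLI (`hcepi simulate / prepare /
periods / classify / validate / run-all`) wraps the same functions for
shell use.

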