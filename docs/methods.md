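# Methods

## Scope and structure

The package implements a two-stage decision model for amyloid
test-and-treat strategies in mild cognitive impairment (MCI): a
diagnostic decision tree over three biomarkers (plasma p-tau 217 "BBM",
CSF Aβ42/40, amyloid PET as reference standard) and a lifetime Markov
cohort model of dementia progression under anti-amyloid treatment
(AAT).  Four strategies are compared: standard of care (no amyloid
test, no AAT), CSF-and-treat, BBM-and-treat, and BBM screening with CSF
confirmation.  Outputs are lifetime discounted costs split by payer
sector, QALYs, person-years by state, and the usual decision metrics
(ICER, NMB, NHB, incremental NHB, value-based price thresholds).

## Diagnostic stage

BBM accuracy is known against CSF, and CSF against PET.  The joint
distribution of the eight (BBM±, CSF±, PET±) outcomes is built by
chaining the conditional probabilities under the assumption
BBM ⊥ PET | CSF:

P(b, c, p) = P(b | c) · P(c | p) · P(p),  P(PET+) = 0.4902.

Classification is always against PET.  Under standard of care nobody is
tested, so the amyloid-positive fraction is counted as (untreated)
false negatives and the rest as true negatives; this bookkeeping only
assigns progression tracks — no misdiagnosis disutility can apply where
no test was administered.

**Accuracy values.**  The bundled base case uses
P(CSF+|PET+) = 0.962749, P(CSF−|PET−) = 0.931424,
P(BBM+|CSF+) = 0.72108743 and P(BBM−|CSF−) = 0.85314888.  These are the
values consistent with the published per-100,000 decision-tree counts
(derived from 47,194/49,020, 47,484/50,980, 34,031/47,194 and the
BBM-only false-positive count 9,494); with them every printed count
(47,194 / 3,496 / 34,031 / 2,521 / 34,299 / 9,494 / 41,486 / 14,721)
reproduces exactly.  The rounded text-quoted accuracies (93.1/96.3 and
72.1/85.3, with sens/spec in the text's roles) ship as
`methods_text_accuracy.yaml`; they reproduce the same counts only to
≈0.05%.  Scenario variants quoted as predictive values (APS2,
p-tau217-ratio) are converted to sens/spec by Bayes inversion at the
prevalence of the BBM's reference condition, the CSF-positivity rate
P(CSF+) = 0.50690.

## Markov stage

States MCI → mild → moderate → severe → dead; two progression tracks
(amyloid-positive "AD", non-AD); annual cycles; no backward
transitions.  Event order within a cycle is death first, then
progression conditional on survival:

- death: q(age, state) = 1 − (1 − q_gen(age))^HR(state), with HR(MCI)=1;
- progression: one severity step per year with track-specific annual
  probability; for treated, non-discontinued amyloid-positive arms in
  the effect states the probability is multiplied by (1 − e_t).

Treatment effect e_t = e·(1 − w)^(t−1) from treatment year 2 onward
(full effect in year 1), capped at 1; negative waning w grows the
effect.  Year-1 discontinuation moves that fraction of each treated arm
into an identical off-treatment arm at the end of cycle 1 (drug,
administration, monitoring and effect all cease).  Treatment states are
a severity prefix ({MCI, mild}, optionally + moderate), so leaving the
prefix permanently ends treatment costs and effect without extra arm
splitting; time-on-treatment equals the cycle index for every arm, so
no tunnel states are needed.  Transition probabilities are
age-invariant; only mortality is age-specific.  An ordered-logit
(cumulative link) parameterization of the annual progression step is
supported as an alternative input form.

## Economics

Per cycle, each living state contributes occupancy × annual state cost
per payer sector (municipal institutional, municipal home care,
hospital, open care, drugs other than AAT, informal care) and occupancy
× utility.  On-treatment arms occupying treatment states add the AAT
schedule: drug price + administration (26 infusions × unit cost; zero
for subcutaneous dosing) + monitoring (year 1: 4 physician visits +
4 MRI; later years: 1 + 1).  The optional misdiagnosis disutility
(default 0; scenario −0.05/yr) applies to alive FP and FN persons in
tested strategies for a configurable duration (default lifetime — the
underlying calibration is an open question, so it is a config knob).
The optional productivity cost applies to alive person-years below
age 65 and is therefore inert at the base-case start age of 70.

Lifetime totals use trapezoidal half-cycle weights (½ at cycle 0 and
the final cycle, 1 elsewhere) combined with discount factors
(1 + r)^(−t), r = 3%, identically for costs and QALYs; person-years are
reported undiscounted with the same weights, so years alive + years
dead always equal the horizon (30 years, to age 100).  The diagnostic
work-up is a one-time entry cost booked at time 0 at full weight —
exempting it from the ½ weight is what makes a €714/person work-up
appear as €71.4m per 100,000, matching the published sector table.
"Years dead" is reported as horizon − years alive.  Per-person results
are cohort-normalized; cohort totals multiply by the cohort size.

Decision metrics are computed from full-precision increments (the
published tables round first, which shifts NMB by tens of euros but NHB
by < 0.001).  ΔQALY = 0 yields an "undefined" ICER label rather than an
exception; the four quadrants are labelled dominant / dominated / ICER
/ ICER (savings per QALY lost).  The price-threshold solver uses the
affinity of ΔCost in the annual drug price (QALYs do not depend on
price): two evaluations identify slope and intercept, the solution is
verified by a re-run, and a bisection oracle cross-checks it in the
tests.  WTP = 0 gives the cost-saving price; a negative solution means
even a free drug is not cost-effective at that WTP (reported as n/a).

## Parameter provenance and the synthetic stand-ins

Published, used as printed: diagnostic accuracies (above), prevalence
0.4902, work-up costs €714/€1,364/€997/€1,550, drug price €5,000/yr,
effect 30%, discount 3%, WTP €94,800, start age 70, horizon 30 years,
cohort 100,000, monitoring schedule, and all scenario definitions
(including lecanemab: age 71, MCI 61.5%/mild 38.5%, effects 28%/27%,
discontinuation 6.9%; donanemab: age 73, 17%/83%, 30%/33%, 13.1%).

Registry-derived magnitudes are not public at input level, so the
bundled base case carries synthetic stand-ins, chosen once and frozen:

- **Life table**: Gompertz q(a) = 1 − exp(−2·10⁻⁵·e^{0.1a}), ages
  40–100 (q(70) ≈ 0.0217, remaining life expectancy at 70 ≈ 11–12 y).
- **Transitions** (annual, conditional on survival): AD
  0.18 / 0.28 / 0.10 and non-AD 0.10 / 0.15 / 0.06 for
  MCI→mild / mild→moderate / moderate→severe.  The non-AD MCI value is
  the reported ≈10%/yr conversion for non-AD memory-clinic MCI; the
  rest were calibrated in one pass so the untreated cohort reproduces
  the published lifetime person-year profile (≈5.3 y non-dementia,
  3.1 mild, 2.5 moderate, 0.5 severe, 11.3 alive) and then frozen.
- **Mortality hazard ratios** 1 / 1.25 / 2.8 / 6.0 (MCI carries
  general-population risk).
- **State costs by sector**: solved so that the untreated cohort's
  lifetime discounted sector totals match the published payer-sector
  table (institutional €128,550/person, home care €49,550, hospital
  €4,220, open care €16,780, drugs €5,930, informal €29,360), with
  severity gradients fixed a priori (institutional care concentrated in
  moderate/severe, informal care rising with severity, medical costs
  nearly flat).
- **Utilities** 0.76 / 0.64 / 0.50 / 0.34 (dead 0), in the range of
  published Swedish dementia utility sets.
- **Unit costs**: physician visit €300, MRI €300, infusion
  administration €285 × 26/yr — the administration cost is backed out
  of the published affine slope of incremental cost in drug price
  (≈3.615 discounted treated person-years).

Consequences: decision-tree counts, per-case diagnostic costs, all
structural properties and every closed-form check are exact
reproductions; absolute ICERs are stand-in-dependent (the bundled base
case gives ≈€93k/QALY for CSF-and-treat vs SoC, in the neighbourhood of
— but not equal to — the published ≈€110k).  With the original registry
inputs supplied as a config file, the pipeline reproduces the published
analysis unchanged; nothing in the code assumes the stand-in values.

## Synthetic data and the microsimulation oracle

`synthetic.synth_params` draws random invariant-satisfying bundles
(ordered utilities, severity-monotone costs, valid probabilities,
Gompertz life tables with a ∈ [10⁻⁵, 5·10⁻⁵], b ∈ [0.08, 0.12]) for
property-based testing.  `synthetic.microsim` is the independent check
on the cohort engine's *trace evolution and accounting*: it pushes n
individuals through the same per-cycle matrices by categorical sampling
and accumulates the same ledger per individual, so it deliberately
reuses `build_cycle_matrix` (which is itself tested against closed
forms) while exercising completely different aggregation code.
Validation asserts agreement within 3 Monte-Carlo standard errors of
the mean at n = 200,000 for lifetime cost, QALYs, deaths and per-state
person-years, over 20 random bundles; where a sampled outcome is
constant (plug-in SE exactly 0, e.g. all individuals dead when the true
survivor fraction is ~10⁻⁶) the comparison uses the estimator's
resolution 1/n as the absolute floor.  All generators take a single
seed and are bit-reproducible.

These synthetic inputs emulate parameter *structure*, not any
particular population: passing tests demonstrate that the engine
computes the model correctly for any valid input, not that the bundled
stand-ins describe Scandinavian reality.

## Numerical choices

- Classification fractions are kept at full precision; integer person
  counts are produced only at report time, rounding half away from
  zero.
- Trace invariants enforced after every run: occupancy sums to 1 per
  cycle (1e−10), entries ≥ 0, dead non-decreasing; cycle matrices
  row-stochastic to 1e−12.
- Discount base: factor 1 at cycle 0, (1+r)^(−t) at cycle t.
- The effect cap at 1.0 (binding only for sustained negative waning)
  keeps transition probabilities in [0, 1].
- Scenario overrides are applied to a deep copy and re-validated
  through the full model schema; a failing scenario is logged and
  reported, and the sensitivity run continues.
- Problem sizes: the cohort engine runs a 31×6×5 occupancy array
  (milliseconds); oracle validation uses 200,000 individuals per bundle
  (~0.6 s each), and the analysis drivers use 5–20 bundles.

## Known limitations

- No ARIA side-effect treatment costs (monitoring costs only), no
  probabilistic sensitivity analysis, no amyloid-clearance pausing rule
  for donanemab, no test-retest variability or alternative assay
  cut-offs, no currency conversion or inflation machinery (EUR at the
  2019 level; SEK/NOK/USD rates are documentation-only metadata).
- Transitions advance at most one severity state per year and are
  age-invariant; institutionalization is implicit in state costs rather
  than modelled as a care-setting state, so the productivity cost
  cannot distinguish institutional from home-dwelling person-years.
- The half-cycle treatment of a one-time entry cost and the exact
  TreeAge half-cycle convention may differ in the last decimal of
  reproduced totals.
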