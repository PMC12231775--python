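# adcea — test-and-treat cost-effectiveness of early Alzheimer's disease

`adcea` is a health-economic model of diagnosing and treating early
Alzheimer's disease (AD) with anti-amyloid treatment (AAT) in a
memory-clinic setting.  It answers questions of the form: *is it
cost-effective to screen for amyloid pathology with a blood-based
biomarker (plasma p-tau 217), with CSF Aβ42/40, or with blood screening
plus CSF confirmation — and treat the test-positives with an
anti-amyloid drug — compared with standard of care?*  It is written for
health economists and HTA analysts who want a transparent, scriptable
alternative to spreadsheet/TreeAge implementations of this model class.

## Model

Two stages:

1. **Diagnostic decision tree.**  BBM accuracy is measured against CSF,
   and CSF against amyloid PET.  Assuming conditional independence
   (BBM ⊥ PET | CSF) the joint distribution of the eight
   (BBM±, CSF±, PET±) outcomes is P(b,c,p) = P(b|c)·P(c|p)·P(p) at
   amyloid prevalence P(PET+) = 0.4902.  Each strategy's positivity rule
   (CSF+; BBM+; BBM+ ∧ CSF+; never, for standard of care) splits the
   cohort into TP/TN/FP/FN against PET.  Test-positives start treatment;
   so false positives are treated without benefit and false negatives
   miss treatment.

2. **Markov cohort model.**  States MCI → mild → moderate → severe
   dementia → death on two tracks (amyloid-positive "AD", and non-AD),
   annual cycles from age 70 to 100, no backward transitions.  Death
   comes first each cycle — the general-population life-table
   probability under a severity-specific hazard ratio,
   q = 1 − (1 − q_gen)^HR — and progression is conditional on survival.
   Treatment multiplies the MCI→mild and mild→moderate conversions of
   treated amyloid-positive people by (1 − e), base case e = 0.30, with
   optional waning e_t = e·(1 − w)^(t−1) and year-1 discontinuation.
   Costs (drug €5,000/yr + 26 infusions + monitoring MRI/visits,
   state costs by payer sector: municipal institutional/home care,
   medical sector, informal care) and utilities accrue per cycle and are
   discounted at 3% with a trapezoidal half-cycle correction (weight ½
   at cycles 0 and 30).

Decision metrics: ICER = ΔC/ΔQ; NMB = Q·λ − C; NHB = Q − C/λ;
iNHB = ΔQ − ΔC/λ at willingness-to-pay λ = €94,800/QALY, plus a
value-based price solver exploiting that ΔC is affine in the drug price.

The diagnostic accuracies and the economic settings above are published
values; the registry-derived magnitudes (transition probabilities,
hazard ratios, state costs, utilities, unit costs, life table) are
**synthetic stand-ins** bundled in `src/adcea/data/base_case.yaml` — see
`docs/methods.md` for how each block was chosen and what that implies
for interpreting absolute results.

## Worked example

```python
from adcea import load_base_case, run_strategy, compare, price_threshold

params = load_base_case()
soc = run_strategy(params, "SoC")
csf = run_strategy(params, "CSF")
cmp = compare(csf, soc, params.econ.wtp)
print(f"SoC:  cost €{soc.cost_total:,.0f}  QALYs {soc.qalys:.3f}")
print(f"CSF:  cost €{csf.cost_total:,.0f}  QALYs {csf.qalys:.3f}")
print(f"ΔCost €{cmp.d_cost:,.0f}  ΔQALY {cmp.d_qaly:.3f}  "
      f"ICER €{cmp.icer:,.0f}/QALY  iNHB {cmp.inhb:.3f}")
print(f"value-based price: €{price_threshold(params, 'CSF', 'SoC', 94_800):,.0f}/yr")
```

prints

```
SoC:  cost €235,104  QALYs 6.186
CSF:  cost €264,012  QALYs 6.495
ΔCost €28,907  ΔQALY 0.309  ICER €93,474/QALY  iNHB 0.004
value-based price: €5,108/yr
```

Read: testing everyone with CSF and treating the positives costs an
extra €28,907 per person over their lifetime and gains 0.309 QALYs — an
ICER of €93,474 per QALY, right at the €94,800 threshold under these
stand-in inputs; the drug price at which the ICER exactly meets the
threshold is €5,108/year.  (ICER magnitudes depend on the synthetic
stand-in blocks; the diagnostic-tree counts below do not.)

The same numbers come from the command line:

```bash
adcea compare --out results/base    # CEA, person-years, sector costs
adcea sensitivity --out results/s   # all one-way scenarios
adcea threshold --out results/t     # price thresholds per WTP level
adcea validate                      # microsimulation oracle check
```

and the numbered drivers `analysis/01_decision_tree.py` …
`05_validation.py` run the full analysis sequence, writing tables under
`results/`.

## Layout

- `src/adcea/` — library: `params` (types + YAML config I/O),
  `diagnostics` (decision tree), `progression` (Markov engine),
  `economics` (accrual + discounting), `cea` (decision metrics),
  `scenarios` (one-way sensitivity catalogue), `synthetic` (generators +
  microsimulation oracle), `cli`/`report` (command line and tables)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite including end-to-end acceptance checks
- `docs/methods.md` — model documentation and design choices
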