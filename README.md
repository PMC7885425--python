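# smokecea

A Markov cohort cost-utility model for smoking-cessation programmes in
primary care, comparing **health advice alone** with **health advice
reinforced by motivational text messages** sent to smokers' phones.

The question it answers is the standard one in health economics: over the
remaining lifetime of a cohort of smokers, does the extra cost of the
messaging programme buy enough quality-adjusted life years (QALYs) to be
worth paying for — and from whose point of view (the health system's, or
society's including lost productivity)?

## The model

A deterministic cohort moves through three mutually exclusive states —
*smoker*, *former smoker*, *dead* — in 6-month cycles from a start age
(default 45) to age 100 or extinction. The former-smoker state carries a
one-cycle **tunnel substate** so relapse can depend on time since
quitting: quitting smokers face a high arm-specific relapse probability in
their first post-quit cycle (0.333 combined, 0.5264 advice-only) and a
common 0.05/cycle afterwards. First-cycle quit probabilities come from a
randomized trial of the two programmes (0.24375 vs 0.11875); later
attempts succeed at 0.02/cycle. Death is applied first each cycle from an
age- and status-specific mortality schedule; behavioural transitions split
the survivors, so occupancy is conserved exactly.

Outcomes are valued per cycle:

- **QALYs** — alive persons × ½ year × utility (0.75 smoker / 0.78 former
  smoker, lowered by the worst decrement among prevalent smoking-related
  diseases — lung cancer, myocardial infarction, stroke, COPD, heart
  disease — whose status-specific rates are background rates × relative
  risk);
- **healthcare costs** — programme cost once at cycle 0 (€187.90 vs
  €166.95 per patient, plus spread training costs for the combined arm)
  and annual disease treatment costs halved per cycle;
- **productivity losses** (societal perspective only) — sick-leave days by
  smoking status (11 vs 7 days/year) × employment fraction × daily wage,
  the human-capital approach.

Both streams are discounted at 3 %/year and compared as an incremental
cost-utility ratio, ICUR = ΔC/ΔQ, against a €22,000/QALY willingness-to-pay
threshold, with dominance classified when one arm wins on both axes.
Status-specific mortality is calibrated to an all-cause reference life
table by a single corrective factor found by root-finding on life
expectancy. Age-specific schedules that are not published (mortality by
smoking status, disease incidence/prevalence, utility decrements by age)
ship as clearly labelled synthetic defaults and can be replaced from a
config file.

## Worked example

```python
import smokecea as sc

params = sc.baseline_parameters("combined", "male")

st = sc.short_term_summary(params, 1000)
print(f"incremental 6-month cost : EUR {st.incremental_cost:,.0f}")
print(f"quitters (combined/advice): {st.quitters_intervention} / {st.quitters_comparator}")
print(f"cost per additional quitter: EUR {st.cost_per_additional_quitter}")

res = sc.run_cea(params, "societal")
print(f"lifetime societal: dCost={res.delta_cost:,.0f} dQALY={res.delta_qaly:.1f} -> {res.dominance}")
```

prints

```
incremental 6-month cost : EUR 22,850
quitters (combined/advice): 244 / 119
cost per additional quitter: EUR 183
lifetime societal: dCost=-2,166,699 dQALY=169.6 -> dominant
```

At the end of the 6-month programme the messaging arm has cost €22,850
more for a 1000-smoker cohort and produced 244 quitters against 119 —
€183 per additional quitter. Over the lifetime horizon (here on the
packaged synthetic disease and mortality schedules) the combined programme
is *dominant* from the societal perspective: it saves money and gains
QALYs, because former smokers develop fewer smoking-related diseases and
take less sick leave.

There is also a command line:

```bash
smokecea run --sex both --outdir out          # base-case tables + traces
smokecea sensitivity --mode multivariate      # quit-probability grids
smokecea fixtures --outdir fx                 # synthetic life table + config
smokecea validate --reference fx/life_table.csv
```

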