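# Methods

## State structure and cycle conventions

The model is a deterministic (expected-value) Markov cohort over four
substates: `smoker`, `former_tunnel_1` (quit in the previous cycle),
`former_established` (quit ≥ 2 cycles ago), and `dead`. The tunnel depth
is one because relapse probabilities are only distinguished between the
first post-quit cycle and all later cycles; a deeper tunnel would add
states without changing any input's meaning. Relapsed persons re-enter
`smoker` and may quit again at the later-cycle rate (0.02/cycle, i.e. one
opportunity per 6-month cycle, consistent with up to two quit attempts a
year).

Within a cycle, death is applied first from the status-specific schedule
and the behavioural probabilities split the survivors. This competing-risk
ordering keeps every row of the transition matrix normalized, and
separates mortality (a property of smoking status and age) from programme
effectiveness (a property of the arm).

**Accrual convention.** Trace row *t* is the state at the start of cycle
*t* (= end of cycle *t − 1*). Life-years, QALYs, disease costs and
productivity losses accrue on rows *t ≥ 1* — survivors of a cycle earn ½
year — and the programme cost is charged on row 0. No half-cycle
correction is applied (none is standard for this family of cessation
models); a constant per-cycle death probability *q* therefore gives the
closed-form life expectancy ½(1 − q)/q, which the tests assert. Discount
factors are (1 + r)^(−t/2) at row *t*, default r = 3 %/year for both costs
and effects, independently settable.

## Probability conversions

Behavioural annual rates use the *halving* convention (10 %/year relapse ↔
0.05/cycle), because that is the relationship the printed per-cycle inputs
embody; the exact constant-hazard conversion 1 − (1 − p)^½ is available as
an option. Mortality, by contrast, is converted annual → per-cycle with
the exact form, the usual life-table practice.

## Mortality calibration

Status-specific reference mortality (smoker / former smoker) is calibrated
to an all-cause target by one positive scalar *f* applied identically to
both statuses' per-cycle probabilities (clamped at 1). The objective is
life expectancy at the cohort start age of the prevalence-weighted mixture
(default weight 0.34 daily-smoking prevalence, configurable): *f* is found
by Brent root-finding on the bracket [0.1, 10] and the result must match
the target within 0.1 years, else a `CalibrationError` with diagnostics is
raised. Life expectancy was chosen as the objective because it is the
quantity the model's validation tables compare; it is also monotone in
*f*, giving a unique root. Calibration is exactly idempotent and recovers
known synthetic scaling factors to three significant figures (tested).

## Disease layer

Diseases are not explicit states; they enter as weights on the occupancy.
For each of the five smoking-related diseases, status-specific rates are
background schedules × relative risk, and per-cycle expected incident
cases / prevalent persons come from the two-term status mixing equations.
Bookkeeping: incident cases (annual rate, halved per cycle) are charged
the incident cost per case-year; prevalent persons are charged half the
annual prevalent cost per cycle. Comorbidity fractions assume independence
across diseases, and a person's utility is the healthy status utility
minus the **largest** decrement among their prevalent diseases (the
lowest-utility rule), computed by exact enumeration over the 2⁵ disease
subsets; utilities are clamped at 0 with a warning.

## Costing

Per-patient programme totals (€187.90 combined, €166.95 advice) are
authoritative; the itemized components are shipped for reference but do
not sum to the totals and are never used in computation. The one-off
training cost of the combined arm (€1,900) is spread over the reference
group size (1000) and charged as a per-patient rate, so all costs scale
linearly in cohort size and the ICUR is exactly scale-invariant — for the
default 1000-person cohort this is numerically identical to charging it
once.

Productivity losses use the human-capital approach: daily wage = hourly
wage × (monthly agreed hours × 12 / 365); alternatives (divide by 30, or
by ~21.7 working days) are a single configurable divisor. Sick-leave days
attach to smoking status (11 smoker / 7 former smoker per year), not to
disease, following the stated source of those figures; a config switch
(`labour.restrict_to_diseased`) restricts losses to the SRD-prevalent
fraction instead. The employment fraction of the open-ended ≥ 55 band
applies at all older ages with no separate retirement cut-off — the band's
low employment share already reflects retirement, and any overstatement at
very old ages is symmetric across arms.

## CEA and sensitivity analysis

Dominance is classified by sign quadrant (ΔC < 0 ∧ ΔQ > 0 dominant;
ΔC > 0 ∧ ΔQ < 0 dominated; otherwise trade-off, with the ratio undefined
at ΔQ = 0). The signed ratio is retained alongside a dominant
classification because cost-utility tables conventionally print it; the
`icur` property itself is only non-None for trade-offs. Reported ratios
round to the nearest euro, or one decimal below €100/QALY in magnitude.
The threshold verdict marks trade-offs cost-effective at ICUR ≤ threshold
(€22,000/QALY default); in the rare south-west quadrant (cheaper, fewer
QALYs) this rule is conservative.

Deterministic sensitivity grids cover the trial 95 % confidence intervals
of the first-cycle quit probabilities (combined 0.1772 / 0.24375 / 0.3103;
advice 0.0686 / 0.11875 / 0.1688), a start age of 50, a multivariate cross
of both quit grids with and without first-cycle relapse equalized at
0.5264, and a 6 % discount rerun — each cell is a full model run per sex
and perspective. No probabilistic sensitivity analysis is implemented.

## Synthetic defaults and what tests do (and do not) show

Age-specific schedules that the source inputs cite but do not print ship
as labelled synthetic defaults from `smokecea.fixtures`:

- **Mortality** — Gompertz annual hazard h(a) = α·e^(β·a) (α = 5×10⁻⁵ male
  / 2.5×10⁻⁵ female, β ≈ 0.085–0.088), former smokers at baseline and
  smokers at a 1.8 hazard ratio: a smooth, age-increasing schedule in the
  range of modern southern-European life tables.
- **Disease incidence/prevalence** — exponential growth with age from
  anchors at 40 (e.g. lung-cancer incidence 4×10⁻⁴/year, COPD prevalence
  0.04), piecewise-constant over 5-year bands, female rates 0.7× male,
  prevalence capped at 0.60.
- **Utility decrements** — placeholders per disease (lung cancer 0.25,
  stroke 0.15, MI 0.12, COPD 0.10, heart disease 0.08).

Every generator is a pure function of its spec (seeded; default noise 0).
These defaults emulate the *structure* real inputs have — monotone
hazards, smoker excess risk, ordered RRs — but not any country's levels.
Consequently the short-term quantities and all structural guarantees
(conservation, oracle equivalence, additivity, scale invariance,
monotonicity) are exact and tested, while lifetime cost/QALY *totals* on
the packaged defaults are illustrative: reproducing published lifetime
tables requires the user to supply the national life table and
epidemiology via the config hooks (`mortality.csv`, per-disease
`incidence`/`prevalence` schedules).

## Numerical choices

- Extinction threshold 10⁻⁶ persons; age cap 100 years in analysis runs
  (110 for life-expectancy ladders, so truncation error is far below the
  0.1-year calibration tolerance).
- Conservation holds to < 10⁻⁹ persons per cycle by construction (row
  normalization); verified over 10,000 randomized parameter sets.
- The comorbidity subset enumeration is exact (no sampling); with five
  diseases it costs 32 terms per status per cycle.
- Ages index mortality by floor(age); disease schedules are
  piecewise-constant over their bands with no interpolation.
- All pipelines are pure and deterministic: reruns are bit-identical.

## Known limitations

- Disease dynamics are prevalence-weighted, not state-based: no disease
  duration, progression, or excess mortality beyond what the calibrated
  status-specific schedules embody.
- Disease independence for comorbidity mixing is an assumption, not a fit.
- Never-smoker life expectancy is only available if the user supplies a
  never-smoker mortality schedule; it is otherwise omitted from reports.
- Costs are 2018 euros throughout; no inflation machinery.
- The women/societal cost-effectiveness boundary quit probabilities
  reported around 0.17 depend on unpublished age-specific inputs and are
  treated qualitatively, not as reproduction targets.
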