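# Methods

## Model

`strokeburden` estimates the lifetime health and economic burden of stroke by
age of onset with a three-state Markov cohort model run in yearly cycles:

* **post primary stroke event** — occupied only during cycle 1, the year of
  the first-ever stroke;
* **alive post stroke** — all survivors of the first year;
* **dead** — absorbing.

Ten cohorts are modelled (male/female x onset at 45, 55, 65, 75, 85), each
followed until age 99 or death. In cycle 1 the only transitions are survive
or die, governed by the 12-month survival fraction of the onset band, applied
directly as a probability (it is already a one-year proportion). From cycle 2
onward the living face four exits each year: non-fatal recurrent stroke,
fatal recurrent stroke, death from non-stroke causes, and staying alive
without recurrence (the complement of the other three). Non-fatal events
return to the living state; the model therefore tracks no recurrence history,
and the same recurrence hazard applies however long ago the first stroke was.

## Transition probabilities

The national epidemiology report tabulates, per gender and 10-year band, the
prevalence of prior stroke `p`, the first-ever incidence `R_n` (per 100,000
person-years among people without prior stroke) and the attack rate `R_t`
(all acute strokes per 100,000 in the whole population). Since the attack
rate is a prevalence-weighted mixture of the two sub-populations,

```
R_t = p·R_s + (1−p)·R_n      ⇒      R_s = (R_t − (1−p)·R_n) / p
```

gives the recurrent-stroke rate `R_s` among people with prior stroke. This
inversion reproduces the report's printed recurrent-risk column within 1.5%
for every row (the residual comes from the prevalence being printed to two
decimals). `R_s` is split into non-fatal and fatal components with the
band's 12-month survival proportion `P_nfs` (split first, convert second).
Non-stroke mortality after stroke is the general-population non-stroke rate
scaled by a standardised mortality ratio, `D_s = D_t·SMR`, with SMR 1.914
(men) and 2.295 (women). Each rate `r` (divided by 100,000 to a per-person
scale) becomes a per-cycle probability via `1 − exp(−r·t)` with `t` = 1 year.
As the cohort ages, the band parameters switch at attained ages 55, 65, 75
and 85 (step function, no interpolation; the 85+ band is open-ended).

The stay-alive probability is the complement of all three exits. Should the
three converted exits ever exceed one (impossible with the bundled inputs,
possible in principle for extreme user inputs) they are renormalised
proportionally and the stay probability floored at zero; conservation of the
four probabilities to 1 within 1e−12 is a tested invariant.

## Life expectancy and years of life lost

Decedents are credited zero life-years in their cycle of death, so
post-stroke life expectancy is the sum over cycles of the end-of-cycle alive
fraction; no half-cycle correction is applied. Anyone alive after the cycle
ending at age 99 dies the following year and accrues nothing further. Years
of life lost are the gender/age-matched general-population remaining life
expectancy minus the model value, and the percent reduction divides that by
the general-population value.

## Costs

All money is thousand KRW at 2008 values. Future costs are neither inflated
nor discounted: the model treats the two adjustments as offsetting, so
streams are summed at face value. Per cycle, expected cost is the event
fraction times the cost attached to the event:

* cycle 1 — first-year cost for survivors; fatal-stroke cost plus the
  premature-death productivity cost of the onset band for decedents;
* later cycles — subsequent-year cost for those staying recurrence-free;
  first-year cost again for non-fatal recurrences (subsequent-year costs
  resume afterwards); fatal-stroke cost plus the premature-death cost of the
  *attained-age* band for fatal recurrences; nothing for non-stroke deaths.

The input table states premature-death costs per onset band; charging fatal
recurrences by the band of the attained age at death is the consistent
generalisation and automatically zeroes the component at 65+ (retirement).
Survivors of the final cycle at 99 do accrue that year's subsequent-year
cost (the alternative changes totals by <0.5%). Lifetime cost is the sum of
all cycle costs; it is exactly linear in every unit-cost field, and the
total always equals the premature component plus the rest (tested
invariants).

## Cost assembly

The `cost_assembly` module implements the micro-costing rules that build
per-person annual costs from utilisation and wage inputs, used to validate
or regenerate schedules of the shape the engine consumes:

* uninsured medical cost — the published uninsured proportions (29.5%
  inpatient, 15.2% outpatient) are shares of the *total* medical cost, so
  the uninsured amount is `insured × f/(1−f)` per setting;
* informal caregiver — hospital days at the average daily wage (56.809
  thousand KRW), outpatient visits at a third of a day each; patients over
  65 add one companion round trip per admission/visit;
* transport — 0.891 (outpatient) and 2.896 (admission) thousand KRW per
  round trip;
* out-of-pocket beyond year one — first-year out-of-pocket times a ratio in
  the published 0.13–0.38 range;
* human-capital premature death — annual wages summed from the age of death
  to retirement (65) or the end of the potential years of life lost if
  sooner, fractional final year pro rata; the printed PYLL itself is the
  full remaining life expectancy, truncation applies to costing only;
* absenteeism — daily/hourly wages over hospital days and visit hours, zero
  from retirement (hourly wage defaults to daily/8);
* friction cost — half a year of the decedent's wage (friction period 0.5 y)
  plus employer training for the replacement: 362 USD (2000) inflated by the
  consumer price index (129.3/100) and converted at 1,200 KRW/USD ≈ 561.7
  thousand KRW.

The gender/age wage schedule behind the published premature-death costs is
not public; a synthetic schedule (`wages_synthetic.csv`) supports testing,
and the published cost table is used as-is for the base case.

## Burden projection and sensitivity

National burden multiplies each band's incident case count (2004) by a
per-person lifetime cost for that band and reports totals and age-group
shares; the cost schedule is an explicit input, so either the model's own
lifetime costs or an external schedule can be projected. One-way sensitivity
reruns the whole pipeline with both SMRs scaled ±20%, with all unit costs
scaled ±20% (by default premature-death costs are left unscaled; the variant
scaling them too is always reported alongside, since the choice is genuinely
ambiguous), and with the friction-cost valuation replacing human capital.

## Synthetic data and the microsimulation oracle

`generate_scenario(seed)` draws internally consistent parameter tables:
prevalence, incidence and mortality increase with age, survival decreases,
the attack rate is *composed* from a known recurrent rate (so the mixture
inversion can be checked against ground truth), life expectancy decreases
with age at realistic decrements, and costs/wages sit in plausible spans.
It emulates the structure of the national tables, not their correlations
with any real population; a green test shows the pipeline's arithmetic and
bookkeeping are right under those conditions, not that the inputs describe
any particular country. Synthetic claim records (codes I60–I64, inpatient/
outpatient, optional death date) exercise the incident-case rule: first
stroke claim of the index year with a one-year claim-free washout, fatal if
death follows within 365 days (years are fixed at 365 days).

`microsim_oracle` simulates n independent life histories with the same
transition sets as the cohort engine but accumulates life-years and costs
per individual, so it checks the engine's expectation bookkeeping without
sharing it. The equivalence tests use n = 200,000 and a 3-standard-error
band; the parameter-recovery test tabulates an attack rate from two million
simulated person-years and inverts the mixture.

## Reproduction accuracy and limitations

With the conventions above, the model reproduces the published post-stroke
life expectancies closely for onsets 45–65 (within ~10%) but overshoots at
75 and 85 for men (up to +23% at 85, on a base of 0.70 years), while the
published female-85 value is *higher* than the male one despite lower
12-month survival and a higher SMR — a pattern no single timing or
conversion convention reproduces, pointing at band-averaged inputs for the
open-ended 85+ band rather than at the cycle arithmetic. Years of life lost
are within ±7% for all ten cohorts. Lifetime costs inherit the survival
overshoot: onset-45/55 cohorts reproduce within ±13%, the 65/75 cohorts run
14–19% high. The test suite asserts the published-table comparisons at
fixed tolerances and these are left failing where the deviation exceeds
them, rather than widening the bands.

Other limitations: no stroke-severity strata (fatal/non-fatal only), no
time-since-event dependence of recurrence, recurrent strokes assumed to cost
the same as first strokes, no valuation of housewife or family-caregiver
productivity, and no discounting toggle.
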