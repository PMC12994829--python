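# Methods

## Decision problem and model structure

The model compares two strategies for adults (entry age 45) with a
cryptogenic stroke and a confirmed patent foramen ovale: percutaneous
closure plus antiplatelet therapy, versus medical therapy alone. It is a
cohort-level Markov model — state proportions, not individual patients —
with four mutually exclusive states: stable, post-recurrent minor stroke
(mRS ≤ 2), post-recurrent moderate-to-severe stroke (mRS 3–5), and death.
Cycles are 3 months (fixed), the default horizon 30 years (120 cycles),
and both costs and QALYs are discounted at 5%/year, evaluated at cycle
midpoints.

Structural assumptions:

* No recovery transitions out of the post-stroke states. Survivors retain
  the state's utility and cost profile for life.
* The recurrent-stroke hazard is strategy-specific (1.07 vs 0.58 per 100
  person-years) and continues unchanged in the post-stroke states. A new
  minor event in the post-minor state does not change state but is counted
  as an event; a new moderate-to-severe event moves the occupant onward
  (a configuration toggle disallows this transition for structure
  sensitivity); the fatal share (14.2%) of any event moves straight to
  death.
* Competing risks within a cycle are resolved multiplicatively with the
  stroke event first: background mortality applies to the event-free
  remainder. Orderings differ at O(q·m), far below reporting precision; a
  regression test pins the chosen order.
* Procedure-related mortality (0.1%) is applied once, before any
  transitions, in the closure arm's first cycle.

## Background mortality (synthetic life table)

Chinese yearbook life-table rates are not redistributable, so the default
table is synthetic: a Gompertz–Makeham hazard μ(x) = a + b·e^{cx} evaluated
at integer ages 30–110. The shape constants are fixed on demographic
grounds — a = 2×10⁻⁴/year (a low extrinsic/background floor typical of
modern low-accident populations) and c = 0.10/year (adult mortality
doubling time ≈ 7 years) — and the scale b is calibrated by log-scale
bisection so that remaining life expectancy at age 45 equals 35 years, the
population anchor the analysis is built on (calibrated table: LE(45) =
35.04 y). Life expectancy is computed as the upper Riemann sum of the
yearly survival curve (Σ_{k≥0} S(k), S(0)=1), truncated at the table end.

What the synthetic table reproduces: a plausible adult age-gradient and
the stated life expectancy. What it does not: period/cohort effects, sex
differences, and the exact yearbook age profile. Consequently,
person-years at risk inside the 30-year window (≈26.5 of 30) — and with
them absolute event counts, costs, and QALY totals — differ from results
computed against the true national table. Cumulative strokes per patient
come out at 0.283 (medical) and 0.155 (closure), below the published
0.32/0.17, which correspond to rate×30 years with almost no mortality
attrition; the incremental comparison (dominance, ICER sign) is
insensitive to this. Passing tests therefore demonstrate internal
correctness and robustness of the decision, not agreement with the
unpublished mortality data; any real table can be supplied as a CSV.

## Accrual rules

Half-cycle correction is trapezoidal: recurring payoffs value the mean of
start- and end-of-cycle occupancy (equivalent to half-weighting the first
and last cycles for constant payoffs). The published phrase "half of the
cycle-specific transition probabilities at the beginning and end" is
non-standard; the trapezoid is the conventional reading and is what the
tests pin down. Flow-level valuation: a person moving i→j in a cycle
contributes (u_i+u_j)/2; occupants experiencing a recurrent stroke are
instead valued at the event utility 0.20 for that cycle (the published
table labels 0.20 both a "temporary decrement" and an event utility; the
absolute reading is the default, a toggle `event_utility_is_decrement`
implements the other).

Costs per cycle: stable/medical pays the annual medical-therapy cost /4,
the antithrombotic regimen (aspirin by default; clopidogrel or warfarin
selectable — the source prices all three without stating a mix), and the
high-distress psychological cost at 40% prevalence; stable/closure pays
aspirin for the first year only (routine post-closure antiplatelet
practice — an assumption); post-stroke states pay their quarterly care
cost plus the depression/anxiety cost at 40% prevalence in both arms (the
medical arm also continues its regimen). Acute event costs are charged in
the event cycle; a fatal event is charged once at the moderate-to-severe
acute cost (assumption). The closure package ($6,635) and the 0.02
procedure disutility (applied for the procedure cycle) enter undiscounted
at time zero. Psychological prevalences (40% for both depression among
post-stroke survivors, consistent with the 30–50% range reported for
post-stroke depression, and high distress among stable medical-therapy
patients) are configuration values; `--no-psych-costs` removes them.

Age-related utility decline (2%/year multiplicative) exists as a
scenario flag and is off in the base case, since the base analysis does
not state it as active.

Stroke-free survival is cumulative first-event incidence: the probability
that no recurrent stroke has occurred by year y, with deaths from other
causes remaining stroke-free. Without background mortality this reduces to
(1−q)^{4y}, the check used in the tests.

## Sensitivity analysis

One-way ranges are the printed 95% intervals where a source interval
exists, otherwise ±25% of base. PSA families follow parameter class:
probabilities and utilities beta, costs gamma, relative risks log-normal;
method-of-moments fits treat each range as a 95% CI (sd = range/3.92); the
log-normal takes (μ, σ) directly from the interval endpoints. Parameters
are sampled independently — no correlation structure is published — except
that the closure-arm rate is derived per draw as
rate_medical × (1 − RRR) with RRR ~ log-normal(0.35–0.70), keeping the
arms coherent. Background mortality is held fixed across draws. The
severity split is held fixed in PSA (compositional; no printed interval),
and `device_efficacy` is a one-way-only blending multiplier
(e·rate_closure + (1−e)·rate_medical); the base case uses the trial rates
unmodified because intention-to-treat estimates already include failed
closures. The CEAC grid is $0–80,000 in $1,000 steps plus the named
thresholds ($18,827, $37,654). EVPI uses the two-strategy form
E[max(NMB,0)] − max(E[NMB],0).

With independent utility draws the closure and medical stable-state
utilities occasionally cross, producing a ΔQALY<0 tail (~7% of draws);
this drives an EVPI of roughly $1,000–1,500 per patient, well above the
published $127, which evidently reflects tighter (unpublished) joint
distributions. The probability of cost-effectiveness at the $37,654
threshold lands near 93%, consistent with the published 94.2%.

## Budget impact

A stacked-cohort projection: each year's treated cohort (4,200 eligible ×
uptake, default ramp 50%→80% by year 5) follows the cohort model's own
undiscounted incremental cost trajectory — net cost ≈ +$6,000 in the
treatment year, then ≈ −$400 to −$600/year savings — plus $2M/year
implementation costs in years 1–3. Under these printed inputs the upfront
spending dominates the 10-year window and no break-even occurs within it;
the published year-3/4 break-even depends on unpublished per-patient
savings assumptions and is treated as qualitative only.

## Numerical choices

* Dollar outputs (ICER, NMB) truncate toward zero, matching the published
  −2,868 = trunc(−4,045/1.41).
* ICER with ΔE = 0 is flagged undefined rather than computed; negative
  ICERs always carry the dominance flag.
* Matrix rows are validated to sum to 1 within 1e−9 every cycle; cohort
  conservation and monotone death occupancy are asserted during the run.
* Rate↔probability conversions round-trip to 1e−12; the engine matches an
  independent scalar re-implementation to 1e−9 on a 5-cycle fixture.
* Life-table calibration stops when |LE − target| ≤ 0.05 y (requirement
  0.1 y); the bisection bracket is b ∈ [10⁻¹², 10⁻¹].
* PSA uses a single seeded `numpy` Generator; reruns with the same seed
  are byte-identical.

## Known limitations

* Cohort proportions only; no microsimulation, no patient-level
  heterogeneity (RoPE score, shunt anatomy).
* The synthetic life table is unisex and period-free (see above).
* Psychological-cost prevalences and the closure-arm antiplatelet duration
  are assumptions, exposed as configuration.
* Only two strategies; no efficiency frontier for >2 comparators.
* No currency-year conversion; all costs are 2021 USD.
* A +75% procedure-price scenario ($11,611) makes closure cost-incurring
  (ΔC ≈ +$2,000) though still far below the willingness-to-pay threshold
  (ICER ≈ $1,500/QALY); with base-case savings below $4,976 per patient no
  parameterization of this model can keep that scenario strictly
  cost-saving.
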