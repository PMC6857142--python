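# Methods

## Model

`eldercea` implements a deterministic Markov cohort model for the long-term
cost-effectiveness of brief health-promoting interventions (group senior
meetings; a single preventive home visit) offered to community-dwelling
older people at risk of functional decline, compared with no intervention.

The state space has five levels ordered by dependency in activities of
daily living: **mild**, **moderate**, **severe** and **total** dependency,
plus absorbing **death**. The cycle length is one year; an annual
row-stochastic transition matrix moves cohort proportions between states.
Recovery is possible between adjacent levels except from total dependency
back to mild, which is structurally zero, and death admits no exit. The
whole cohort starts in mild dependency, matching the "risk zone" trial
population from which effects are estimated.

Each state carries an HRQoL utility weight (mild 0.77, moderate 0.60,
severe 0.47, total 0.41, death 0) and an annual societal cost in euros
(2 600 / 7 801 / 20 708 / 62 407 / 0), covering health care, home help,
informal care and special accommodation. QALYs are utility-weighted
person-time; both QALYs and costs are discounted at 3 %/year.

### Outcome timing and discounting

Occupancy is measured at the **end** of each cycle and cycle-*t* outcomes
are discounted by (1.03)^(−t), t = 1..4, with no half-cycle correction.
This convention reproduces the published no-intervention outcomes (QALYs
2.355, costs 24 291 €) to within 0.5 % and the published per-100 count
table exactly after rounding; adding a half-cycle correction worsens
agreement. Intervention delivery costs are charged at the **start** of
their cycle: the upfront per-participant cost is undiscounted (factor
(1.03)^0) and a booster in cycle *t* carries factor (1.03)^(−(t−1)).

### Intervention effects

Effects are estimated from one-year trial transition counts: control
87/19/6/0/2 of n=114, senior meetings 149/11/3/3/5 of n=171, preventive
home visit 150/19/1/0/4 of n=174 (destinations mild/moderate/severe/total/
dead, all starting mild). The risk of a destination is its count divided by
n; relative risks (RR) are treated/control risk ratios on unrounded
fractions. An *as-printed* mode reproduces two-decimal worked arithmetic
(0.06/0.17 = 0.35, 0.11/0.17 = 0.65) for cross-checking quoted figures
only.

Counts can be mapped onto a modified mild-dependency matrix row in more
than one defensible way, and the published narrative (per-destination RRs)
and count tables pull in different directions. All four conventions are
first-class and selectable:

- `overall_rr_nondeath` (default): the pooled progression RR — all
  non-mild destinations, deaths included in the counts (SM 0.5432, PV
  0.5824) — multiplies the mild→moderate/severe/total probabilities;
  mild→dead stays at baseline and the saved mass returns to mild→mild.
  This is the only convention we found that reproduces the published
  year-1 occupancies (SM mild 87, SM moderate 7, PV moderate 8).
- `per_destination_rr`: each destination scaled by its own RR; a 0/0 RR is
  unidentifiable and leaves its destination unmodified (no information is
  not protection).
- `direct_proportions`: the mild row is replaced by the treated arm's
  observed proportions.
- `moderate_only_rr`: only mild→moderate is scaled.

The effect is one-time (year 1 only) in the main analysis. An
`effect_scale` in [0, 1] attenuates any convention linearly toward RR = 1:
the effective RR is 1 − scale·(1 − RR), so 0.8 is a "20 % reduced effect"
and 0 restores the baseline matrix bit-exactly.

The published PV year-1 mild cell prints 86 while the default convention
yields 86.52, which rounds half-up to 87; every other year-1 cell
reproduces exactly. The discrepancy is a rounding-boundary artifact of the
two-decimal printed matrix and is left as is.

### Costing

Intervention cost sheets hold the printed item amounts (education,
salaries, travel, rooms, materials) as authoritative pre-computed values;
the underlying time-and-salary micro-accounting is not re-derived because
it is not fully reconstructible from the stated unit figures. Totals are
compensated sums (order-independent); per-participant costs are
total/participants, rounded half-up to whole euros for scenario input
(27 293 €/171 → 160 €; 12 337 €/174 → 71 €), with an unrounded mode
available. Booster unit costs are 19 € (one extra senior meeting) and 71 €
(one extra home visit) per participant, taken as given.

### Scenarios, boosters and sensitivity

A scenario couples the baseline matrix, an optional effect with schedule,
upfront and booster per-participant costs, the 4-year horizon, the discount
rate and the all-mild start. Incremental analysis differences a scenario
against no intervention and classifies dominance (ΔQALY > 0 and Δcost < 0
⇒ dominant); an ICER is reported only in trade-off quadrants, where the
ratio's sign is meaningful.

The booster schedule applies the effect-modified matrix in every cycle.
Because the effect touches only the mild row, this is mathematically
identical to treating exactly the mild-state occupants — the booster target
group (asserted by a unit test); the booster cost for cycle t ∈ {2,3,4} is
the unit cost times mild occupancy at the end of cycle t−1.

One-way sensitivity analysis runs two independent variants: all
intervention costs ×1.2 (raising the SM 4-year per-person cost by exactly
0.2×160 = 32 € and PV by 14 €, since the upfront charge is undiscounted),
and effect_scale 0.8.

## Numerical choices

- Row-stochasticity and share-sum tolerance 1e-9; structural zeros must be
  exact.
- Person-count tables round half-up (`floor(x+0.5)`), display-only; the
  propagation always uses unrounded shares.
- Aggregate person counts (e.g. "severe + total + dead at year 4") are sums
  of the *rounded* per-state report cells, matching how such totals are
  read off a published count table. For the control cohort the rounded
  cells 7+5+16 give 28 per 100 while the unrounded share sum is 27.38; the
  two intervention arms give 25 either way.
- Golden comparisons to the published accumulated outcomes use 1 % relative
  tolerance: the two-decimal printed transition matrix appears to be
  rounded from an unrounded working matrix, producing a consistent
  ~0.4–0.5 % offset that cannot be removed without guessing unprinted
  digits. The published incremental deltas (0.054/−2283 SM, 0.048/−2091
  PV, booster 0.123/−6145) are additionally sensitive to the undocumented
  spreadsheet conventions, so they are checked as property bands (SM ΔQALY
  ∈ [0.045, 0.065], Δcost ∈ [−2600, −1900] €, booster/main ratios ∈
  [2.0, 2.6] for QALYs and [2.0, 2.8] for costs, dominance in all
  analyses) rather than as point goldens. Under the default convention
  this package computes 0.054/−2304 (SM), 0.050/−2182 (PV) and booster
  0.125/−6069.

## Synthetic trial generator

`synthetic_trials` emulates the statistical structure of the effect trial:
an arm is a single multinomial draw of one-year destination counts from a
true transition row, at a chosen arm size, from one seeded
`numpy.random.Generator` (bit-reproducible). `scaled_row` constructs a
treated-arm row whose pooled progression RR versus a base row is exact, for
parameter-recovery tests; `generate_random_matrix` samples flat-Dirichlet
rows honouring the structural zeros and absorbing death for property
sweeps.

The generator does not emulate dropout/attrition, covariate structure,
multi-year individual paths or overdispersion relative to the multinomial.
Passing recovery tests therefore show that the estimator is consistent for
the generating process, not that the original trial was free of such
features.

Default study conditions mirror the trial: arms start all-mild, sizes of
order 100–200 for realism checks, n = 10 000 with 200 replicates for
recovery (mean bias < 2 %), and 1 000 random matrices over 10-year horizons
for invariant sweeps — sizes at which every suite runs in seconds.

## Limitations

- The 4-year horizon and one-time (or yearly-boosted) effect are fixed
  design choices of the evaluated problem; no lifetime extrapolation.
- Deterministic only: no probabilistic sensitivity analysis or CEACs; RRs
  carry no confidence intervals.
- Transition probabilities, utilities and state costs are taken as printed;
  they are not re-estimated from their source cohorts.
- Currency conversion/inflation adjustment is out of scope (inputs already
  in 2018 euros).
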