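# eldercea

Markov cohort cost-effectiveness analysis of health promotion for
community-dwelling older people.

Brief health-promoting interventions — a series of group *senior meetings*
or a single *preventive home visit* — can delay the loss of independence in
older adults, but a one-year trial cannot show whether they pay off over
the long run. `eldercea` answers that question with a deterministic
five-state Markov cohort model: annual transitions between **mild**,
**moderate**, **severe** and **total** dependency and **death**, each state
valued with an HRQoL utility weight and an annual societal cost. A cohort
starting in mild dependency is propagated over a 4-year horizon; each
intervention enters as a relative risk (RR) of progression out of mild
dependency estimated from one-year trial counts, plus a per-participant
cost. Accumulated, discounted (3 %/year) QALYs and costs are compared
incrementally against no intervention:

- QALYs = Σ_t (1+r)^(−t) Σ_s π_t(s)·u(s), costs analogous with per-state
  annual costs plus intervention charges,
- ΔQALY > 0 with Δcost < 0 ⇒ the intervention *dominates* (no ICER
  needed); otherwise the ICER Δcost/ΔQALY is reported.

Deterministic sensitivity analyses (+20 % intervention cost, −20 % effect)
and a yearly *booster session* variant (effect and cost repeated for people
still in mild dependency) are built in. Full model details are in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
from eldercea import fixtures, run_bundle, qaly_to_days

payoffs = fixtures.payoff_table()
results = run_bundle(fixtures.main_scenarios(), payoffs).set_index("scenario")
print(results[["qalys", "costs", "incr_qalys", "incr_costs", "dominance"]].round(3))

sm = results.loc["senior_meetings"]
print(f"{qaly_to_days(sm.incr_qalys)} days of full health gained")
```

prints

```
                       qalys      costs  incr_qalys  incr_costs dominance
scenario
no_intervention        2.356  24291.798         NaN         NaN      None
senior_meetings        2.410  21987.518       0.054   -2304.279  dominant
preventive_home_visit  2.405  22109.808       0.050   -2181.990  dominant
20 days of full health gained
```

Reading: without intervention a person accumulates 2.356 discounted QALYs
and 24 292 € of societal costs over 4 years. Senior meetings (160 € per
participant) add 0.054 QALYs — about 20 days of full health — while
*saving* 2 304 €, so the intervention dominates no intervention; the
preventive home visit (71 €) behaves the same with slightly smaller gains.

The same analysis runs from the shell, including the sensitivity and
booster variants and the per-100-persons occupancy table:

```sh
eldercea reproduce-published --out-dir reports
eldercea run --config my_bundle.yaml --cost-multiplier 1.2
eldercea generate --n 114 --seed 9 --row baseline-mild
```

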