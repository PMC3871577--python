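# cwprisk

Cohort analysis of coal workers' pneumoconiosis (CWP) for occupational
epidemiologists: reconstruction of cumulative dust exposure from job
spells, actuarial life-table cumulative incidence with Peto log-rank curve
comparisons, projection of the future CWP case load within life expectancy,
and neural-network risk stratification of workers without CWP into
surveillance classes.

The package follows the analysis design of a large Chinese colliery cohort
(Kailuan Colliery Group, followed 1970–2011: 17,023 underground workers,
838 CWP cases) and ships that study's published summary tables — work-area
dust concentrations by decade, characteristic counts, subgroup incidence
rates, projection totals — as default inputs. Because the individual
records were never deposited, a synthetic-cohort generator with known
ground truth reproduces the cohort's statistical structure so that every
stage is testable end to end.

## The model in brief

* **Exposure.** For worker *i* with job spells *s* of duration *t_s* years
  in work area *a(s)*, cumulative dust exposure is
  `CDE_i = Σ_s Σ_y f_{s,y} · c(a(s), y)` (mg/m³·years), where `f_{s,y}` is
  the fraction of calendar year *y* covered by the spell and `c(a, y)` the
  area's geometric-mean concentration. Occupational category
  (tunneling / mining / combining / helping) follows a fixed rule cascade on
  the area durations.
* **Incidence.** Actuarial life table on 1-year intervals since first
  exposure: `q_k = d_k / (n_k − w_k/2)`, `CI(t) = 1 − Π_{k<t}(1 − q_k)`;
  annual average incidence `= CI(T)/T`. Curves are compared with a
  survival-weighted (Peto-type) log-rank statistic; stratified counts with
  Pearson χ².
* **Projection.** A non-case of age *a* in subgroup with rate *r*
  contributes `r · max(0, LE − a)` expected future cases, allocated
  linearly over future decade windows and tabulated by current-age band.
* **Risk.** A three-layer MLP (category, entry era, exposure duration,
  CDE → probability of CWP) trained on a random 7:3 split; cutoffs
  (c_low, c_high) calibrated so the high-risk pool covers the projected
  case load expanded by 50 % and the low-risk pool matches the designated
  low-risk population; classes low (p < c_low) / middle / high (p ≥ c_high).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Run the whole pipeline on a 2,000-worker synthetic cohort:

```sh
cwprisk all --seed 7 --out-dir run
cat run/run_summary.txt
```

```
workers: 2000
cases: 97 (4.8%)
CI(40y) tunneling: 29.0%
CI(40y) mining: 27.2%
CI(40y) combining: 29.2%
CI(40y) helping: 1.2%
projected new cases within life expectancy: 50.2
model accuracy at 0.2: 90.5% (1809 of 2000)
risk classes (low/middle/high): 1155/665/83 at cutoffs (0.01, 0.28), high-risk target 75
```

Reading the numbers: 4.8 % of the simulated workforce developed CWP during
follow-up, close to the generator's configured subgroup rates; the 40-year
cumulative incidences separate the dust-generating categories (≈ 27–29 %)
from helping workers (1.2 %); 50.2 new cases are expected among the 1,903
current non-cases before they reach the default 74-year life expectancy;
and threshold calibration flags 83 workers as high-risk against a protected
pool target of 75 (= 50.2 × 1.5). The run directory also contains the
per-category life tables and incidence curves, pairwise curve comparisons,
the stratified characteristics table with χ² tests, both projection tables,
the risk model, per-variable importances, and the per-worker risk report —
all as delimited text. Estimated subgroup rates
(`run/subgroup_rates.csv`) recover the configured generator rates, e.g.
8.06 ‰/y for 1970- tunneling entrants (configured: 8.1 ‰).

The same analyses are available as library functions
(`cwprisk.build_life_table`, `cwprisk.project_cases`,
`cwprisk.train_model`, …) on cohorts read with `cwprisk.read_cohort` from
a worker CSV plus a job-spell sidecar CSV.

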