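# Methods

`cwprisk` re-implements, as a reusable and tested pipeline, the analysis
chain used in retrospective colliery cohorts of coal workers' pneumoconiosis
(CWP): reconstruction of each worker's dust exposure from dated job spells,
actuarial life-table estimation of cumulative incidence, projection of the
future case load within life expectancy, and stratification of workers
without CWP into surveillance classes by a neural-network risk probability.
The package ships the published summary tables of a large Chinese colliery
cohort (Kailuan Colliery Group, follow-up 1970–2011; 17,023 workers, 838
CWP cases) as default inputs; the individual records of that cohort were
never deposited, so per-worker analyses run on user-supplied files or on the
synthetic cohorts described below.

## Exposure model

A career is an ordered list of half-open job spells `[start, end)`, each in
one of four underground work areas (tunneling, mining, combining, helping).
Durations are `days / 365.25`. Overlapping spells are rejected: recorded
durations are sums of disjoint job spells. Workers with less than 1 year of
total exposure are excluded, mirroring the cohort inclusion rule.

**Occupational category** follows a fixed cascade: a single consistent area
wins outright; tunneling wins if its share exceeds half the total; mining
wins if tunneling is under 2 years and mining exceeds half; a tunneling
spell of at least 2 years (but at most half) makes the worker "combining";
everyone else is "helping". Two boundary readings the rule text leaves open
are resolved as: exactly half is *not* "more than half", and exactly 2 years
of tunneling *is* combining-eligible (an inclusive boundary avoids a dead
zone in which no rule could fire before the fallback).

**Cumulative dust exposure (CDE, mg/m³·years; printed "mg-years")** is the
sum over spells of year-fraction × the work area's geometric-mean dust
concentration in that calendar year. The default concentration table
resolves each calendar year to its decade block (1970-, 1980-, 1990-,
2000-), the only resolution the source monitoring summary provides; a
per-year table may override any cell, and exact-year entries take precedence
over blocks. Geometric standard deviations are back-solved from the
published (+1 SD, −1 SD) columns as `sqrt(plusSD / minusSD)`.

**Observation window**: first exposure to diagnosis (cases — this equals
the latency period) or to censoring (non-cases; default study end
2011-12-31).

## Life-table statistics

Cumulative incidence uses the classical actuarial estimator on 1-year
intervals of time since first exposure (interval width configurable):
effective denominator `n_k − w_k/2`, conditional incidence
`q_k = d_k / n'_k`, `CI(t) = 1 − Π_{k<t}(1 − q_k)`. Events and withdrawals
are assigned to the interval containing the observed years; events are
counted before withdrawals within an interval. The **annual average
incidence** is `CI(T)/T`, the constant-rate summary used for projection,
reported in ‰/year.

Curve comparisons use a two-sample weighted log-rank statistic
`(Σ w_j (O_j − E_j))² / Σ w_j² V_j` on 1 df. The default weights are the
pooled actuarial survival product taken through each event time inclusively,
without the `n+1` modification — the simplest defensible reading of a
Peto-type test; `weighting="logrank"` gives unit weights, cross-checked in
the tests against both a frozen 6-subject hand calculation and
`lifelines.statistics.logrank_test`. Multi-group comparisons are pairwise
with no multiplicity adjustment. Contingency tables use the Pearson
chi-square without continuity correction (`scipy.stats.chi2_contingency`),
and p-values are displayed to 3 decimals with a `<0.001` floor.

## Projection

Each worker without CWP, with subgroup rate `r` and `m = max(0, LE − age)`
remaining years, contributes `r × m` expected cases, allocated linearly to
future-time windows (<10, 10–19, 20–29, 30– years) by the years of `m`
falling in each, and to the worker's current-age band (<20, 20–29, …, 60–).
Linear (non-compounding) accumulation is the default because equal
consecutive decade totals in published projections of this design are only
consistent with non-compounding allocation; `compounding=True` switches to
`1 − (1 − r)^m` with window contributions `(1−r)^a − (1−r)^b`. Subgroups
with no published or estimable rate (1990- entrants) receive the most recent
available era's rates (1980-), a configurable mapping. Life expectancy
defaults to a scalar 74 y (the cohort's local value is unpublished) and may
be an age-indexed function. Current age is computed as calendar year of
study end minus birth year; expected counts are kept unrounded internally
and printed to one decimal.

## Risk model

A three-layer perceptron (scikit-learn `MLPClassifier`): 9 encoded inputs
(4-level occupational category and 3-level entry era, both one-hot;
standardized exposure duration; standardized log1p-CDE), one tanh hidden
layer, logistic output. The published description of the network's size ("74
synapses") is ambiguous between units and weighted connections; the default
hidden layer is 9 units, a close integer reading in connections, and is a
config knob. Training uses Adam with a fixed seed (reproducible weights);
class imbalance is left unweighted, matching the specificity ≫ sensitivity
pattern of the published model. Data are split 7:3 into training and
validation at random; metrics are reported on the validation set and on all
records.

**Variable importance** is permutation-based (the encoding columns of a
categorical variable are permuted jointly; importance = mean increase in
log-loss, floored at 0, normalized to sum 1). Whether the original
analysis's importance was permutation- or derivative-based is unknown;
permutation is chosen and labelled as such.

**Risk classes.** `p < c_low` → low, `p ≥ c_high` → high, else middle; a
boundary probability always goes to the upper class (the published text and
table disagree at the boundaries; `≥` is the documented convention here).
Calibration chooses `c_high` on a grid so the high-risk pool best matches
the projected case load expanded by 50 % (e.g. 844 → 1266), and `c_low` so
the low-risk pool best matches a designated low-risk population (in the
pipeline: non-case helping workers first exposed after 1980); grid ties
break toward the lower cutoff (more protection).

## Synthetic cohorts

`simulate.CohortSpec` defaults are the study conditions: n = 17,023; era mix
36.2/35.8/28.0 % (1970-/1980-/1990-); category mix 7.0/15.8/12.5/64.7 %
(tunneling/mining/combining/helping); age at first exposure N(21.4, 4.0²)
truncated to [16, 40]; career length N(28, 8²) years truncated to
[1.1, 45], cut at study end; 30 % of careers are multi-area, constructed so
the sampled category genuinely satisfies its classification rule (including
branches 3 and 4 of the cascade). Subgroup annual rates default to
8.1/8.0/6.5/0.6 ‰ (1970- era) and 1.7/2.1/1.4/0.3 ‰ (1980- and 1990-).

Onset uses constant *absolute* annual risk by default: a worker converts
with probability `min(1, rate × observed_years)`. This is the exact
generative counterpart of the annual-average-incidence summary `CI(T)/T`,
so subgroup rate recovery is unbiased; an exponential constant-hazard
variant (`1 − e^{−rate·T}`) is provided but at 8.1 ‰ over 40 years it
yields `CI(40)/40 ≈ 6.9 ‰`, i.e. the linear summary under-reads a true
exponential hazard by ~14 %. A `dose_response` regime instead converts with
probability `min(0.9, 2.5×10⁻⁴ × CDE)`, giving the risk model a learnable
exposure signal. Converters' diagnosis dates are placed at a latency drawn
from N(29.1, 5.3²) truncated to [5, window] (conditioning on the window
keeps realized subgroup rates unbiased); non-converters are censored at
study end. Deaths before study end are not simulated — life expectancy
enters only the projection stage.

What the generator does **not** emulate: employment gaps, job-transfer
behaviour, competing mortality, within-area concentration heterogeneity
beyond the decade blocks, and any real era × category × age joint structure
(era and category are sampled independently unless the mixes are changed).
Passing tests therefore demonstrate internal statistical correctness of the
estimators on data satisfying the model's assumptions, not agreement with
the unpublished individual-level cohort data.

## Numerical and testing choices

Problem sizes in the test suite follow the properties being checked:
exponential life-table check at n = 10,000 and 40 y against `1 − e^{−0.4}`
(3 binomial SE); subgroup-rate recovery at n = 5,000 per subgroup with a
40-year entry window; log-rank power at a tenfold hazard ratio with 2,000
per arm; projection equivalence against a per-worker per-year brute-force
loop at 10⁻⁹ relative tolerance; CDE additivity under spell splitting at
10⁻⁹ relative. Life-table denominators of 0 yield `q_k = 0`. All randomness
flows through `numpy.random.default_rng` seeds carried in specs and
function arguments; a fixed seed makes cohorts, model weights and pipeline
report files byte-identical across runs.

## Known limitations

The published cohort-level results that depend on the unpublished raw data
(the 31.8/27.5/24.2/2.6 % category cumulative incidences, the 843.6
projected cases, the 91.8 % model accuracy) are reproduced in *scale* by the
synthetic default cohort but cannot be matched exactly and are not asserted.
Era counts differ between two published characteristic tables
(5854/5798/4533 vs 5875/5798/4512 non-cases); inputs are taken as given and
not reconciled. The exact life-table interval width and the exact weighting
variant of the published curve comparisons are unstated; 1-year intervals
and survival-product weights are the defaults, both configurable.
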