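# Methods

## Model structure

The model is an annual-cycle Markov state-transition model of two
treatment strategies for operable stage IA NSCLC. The collapsed annual
state space has nine states: NED after primary treatment; three
recurrence-site states (local, regional, distant failure), each occupied
for exactly one cycle; NED after local salvage (PBT arm only); NED after
regional salvage; progressive disease; and two absorbing death states
(disease/background death and procedure-related death). Lobectomy is
assumed to produce no local-only failures, so its recurrences split
between regional and distant sites only.

Within-cycle event composition: background mortality `q(age)` competes
independently with each disease event, so an alive state's total exit
probability is `1 − (1−q)(1−p)` and the disease share `(1−q)·p` is then
split by site. A failure state resolves on exit: salvage (with the site-
and arm-specific probability) or direct transit to progressive disease.
Salvage lobectomy after a PBT local failure is charged the operative
mortality at the patient's *current* age, not the age at diagnosis;
salvage radiotherapy carries a fixed 0.0010 mortality. Only one round of
salvage is modelled: progression after salvage leads directly to
progressive disease. Progressive-disease mortality (0.6268/yr) compounds
independently with background mortality rather than replacing it — a
slightly conservative choice.

Primary procedure mortality is applied instantaneously at cycle 0;
patients dying of the procedure accrue zero life-years (no half-cycle
credit, since the procedure opens the trace rather than falling halfway
through a cycle).

## Horizon and half-cycle correction

`horizon_cycles` counts annual transitions. Life expectancy is the
trapezoid rule applied to the proportion-alive curve (half-cycle
correction: transitions are assumed to occur mid-cycle), restricted to
the horizon. The default horizon is **16** transitions: the published
model was built in a stage-indexed Markov engine whose "15 cycles" means
stages 0–15 inclusive, i.e. 16 annual evaluations. With 16 transitions
and the default extrapolation schedules below, the deterministic model
reproduces the published per-age life expectancies for both arms to
within ~0.1–0.35 years at every diagnosis age; with 15 it undershoots
systematically by ~0.3 years. Set `horizon_cycles=15` for a strict
15-year restriction.

## Age schedules (the two extrapolated inputs)

Only the age-70 values of two schedules are published; both defaults are
therefore declared approximations, overridable by the user:

- **Background mortality**: `q(a) = q70 · 2^((a−70)/8)`, anchored at
  0.018679. A Gompertz-type shape — adult all-cause mortality roughly
  doubles every 8 years — chosen to keep the package self-contained; a
  national life-table CSV (`age,q`) can replace it.
- **Lobectomy operative (90-day) mortality**:
  `op(a) = 0.0295 · 2^((a−70)/10)`, monotone in age as the surgical
  literature requires; a per-age override mapping in the config wins.

Extrapolated probabilities are clamped to [0,1] with a logged warning.

## Parameters

Every probability is a `(base, low, high)` triple from the source
literature; triples with no published range (PBT procedure mortality
0.001, local-salvage probability 0.6321, salvage-RT mortality 0.0010, and
the background anchor) are held fixed in all sensitivity analyses. The
per-arm site fractions are validated so the distant share
`1 − local − locoregional` remains a probability for every combination
inside the ranges.

## Probabilistic sensitivity analysis

Each outer iteration draws all ranged parameters — `uniform` over
`[low, high]` by default (the printed ranges are literature extremes, not
standard errors), or `beta` with mode at the base value
(concentration 4) — and evaluates both arms deterministically from the
same draw (common random numbers). Because several ranges are strongly
asymmetric around their base values, the PSA mean difference is shifted
relative to the deterministic base case (by about −0.3 years at age 60
under uniform sampling); the distribution choice is therefore the single
most influential reporting decision and is exposed in the config.

`compare_strategies` reports two interval types: the 2.5/97.5 percentile
interval of the per-iteration difference distribution (parameter
uncertainty itself) and the normal-theory CI of the *mean* difference
(mean ± 1.96·SE), which is the trial-readout-style quantity; published
comparison tables of this kind have CI widths on the SE scale, not the
percentile scale. The p-value is the empirical two-sided tail probability
floored at 1/n, with a z-test alternative for tail probabilities below
empirical resolution.

First-order microsimulation is a separate, composable layer: patient
trajectories are sampled from exactly the cohort transition law, so the
cohort trace is the exact expectation of the patient mean (used as an
oracle in the tests at n = 100,000, 3-SE tolerance). Death during cycle
*t* credits *t − 0.5* years, keeping the patient-mean identity with the
trapezoid rule exact.

## Sensitivity and threshold analyses

Preference is the sign of the deterministic LE difference (tie below
1e-9 years), not PSA significance. Thresholds are located with bisection
(`scipy.optimize.bisect`) to 1e-5 on the parameter scale after verifying
a sign change over the bracket; a dense-grid scan serves as the oracle in
the tests. Varying `op_mort_lob_70` rescales the whole operative-age
schedule proportionally (both the primary procedure and later salvage
lobectomies), matching the single-axis framing of the published
operative-mortality analysis.

## Synthetic fixtures

The fixtures module generates every test input: constant-hazard toy
chains with a geometric closed-form life expectancy (engine agreement to
1e-10), random valid parameter sets for property tests, and noisy
five-year-OS validation points scattered around a model curve. The
validation points emulate the *location* of literature survival values,
not real studies: passing the validation pipeline shows the bookkeeping
(patient-weighted mean, model-curve comparison) is correct, and a CSV
slot (`study,median_age,five_year_os,n`) lets users supply actual
literature values by hand.

## Known limitations

- The deterministic LE difference at ages 60–75 is ~0.15–0.25 years more
  lobectomy-favourable than the published values, pushing the age-70
  operative-mortality crossover to ~6.4% rather than ~5%. The published
  model's full 23-state tree includes a nodal-upstaging (pN+) adjuvant
  branch for which no parameters are published; it is absorbed here into
  the single lobectomy progression probability.
- The age schedules above are shape assumptions, not reconstructions of
  the national life table and surgical-mortality tables the original
  analysis used.
- No costs, QALYs, secondary primaries, oligometastasis salvage, monthly
  cycles, or surgical-technique distinctions (VATS/RATS/open) — all
  outside the model's scope.

## Problem sizes

Default analyses: 16-cycle traces; 10,000 PSA iterations per age; 10,000
microsimulated patients per arm (100,000 in the convergence test). The
full acceptance recomputation runs in well under a minute on one CPU.
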