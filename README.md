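# virtrial

A virtual randomized trial comparing **lobectomy** and **particle beam
therapy (PBT)** for medically operable, peripherally located **stage IA
non-small cell lung cancer** — no head-to-head randomized trial of these
two treatments exists, so an annual-cycle Markov state-transition model
stands in for one.

The package is for clinicians and modellers who want to reproduce,
interrogate or extend that comparison: all transition probabilities are
literature-derived and exposed as `(base, low, high)` triples, every
analysis is a plain Python call, and the deciding quantity is restricted
life expectancy (expected years alive within the model horizon; no costs
or QALYs).

## The model

Each year a patient occupies one health state and moves with probability
determined by age and treatment history:

- **NED (primary)** — no evidence of disease after lobectomy or PBT. A
  recurrence occurs with annual probability *p* (0.0400 after lobectomy,
  0.0568 after PBT) and is split by site: local-only (PBT only, 8.43% of
  recurrences — lobectomy is assumed to have no local failures),
  loco-regional (27.84% / 10.76%), remainder distant.
- **Failure states** (one cycle): a local failure after PBT receives
  salvage lobectomy with probability 0.6321; a regional failure receives
  salvage radiotherapy ± chemotherapy with probability 0.3446 (lobectomy
  arm) or 0.3095 (PBT arm); distant failures and unsalvaged patients move
  to progressive disease.
- **NED (post-salvage)** — progression (site-specific: 0.0459 after local
  salvage; 0.2639 / 0.3115 after regional salvage) goes straight to
  progressive disease; only one round of salvage is modelled.
- **Progressive disease** — annual mortality 0.6268 (chemotherapy or best
  supportive care).

One-time procedure mortality is charged at treatment: 0.0295 for
lobectomy at age 70 (an exponential-in-age schedule elsewhere, or a
user-supplied per-age table) versus 0.001 for PBT. Background mortality
(0.018679 at age 70, doubling every 8 years by default, or a user life
table) competes independently with disease events in every alive state:
total exit probability `1 − (1−q)(1−p)`. Life expectancy uses half-cycle
correction (trapezoid rule on the survival curve) over 16 annual
evaluations (Markov stages 0–15).

On top of the deterministic cohort trace sit a first-order
microsimulation (individual virtual patients, 10,000 per arm) and a
second-order Monte Carlo probabilistic sensitivity analysis (parameters
drawn from their literature intervals, both arms evaluated per draw with
common random numbers), plus one-way/tornado/two-way analyses and
bisection-based crossover thresholds.

## Worked example

```python
from virtrial import ModelConfig, ParameterSet, base_case_table
print(base_case_table(ParameterSet(), ModelConfig()).round(3).to_string(index=False))
```

```
 age  le_lob  le_pbt   diff
  60  11.768  11.130  0.637
  65  11.173  10.657  0.516
  70  10.345   9.987  0.358
  75   9.242   9.080  0.162
  80   7.867   7.926 -0.059
  85   6.302   6.580 -0.278
```

A 60-year-old gains about 0.6 life-years from lobectomy; by age 80 the
rising operative mortality hands the advantage to PBT. At age 70 the
crossover is explicit:

```python
from virtrial import find_threshold
r = find_threshold("op_mort_lob_70", ParameterSet(), 70, (0.0, 0.15))
print(f"{r.crossing_value:.4f}  ({r.preferred_below} below, {r.preferred_above} above)")
# 0.0638  (lobectomy below, pbt above)
```

i.e. once a 70-year-old's operative risk exceeds ~6%, PBT offers the
longer expected life. The `examples/` directory walks through each
capability (base case, microsimulation, PSA, sensitivity, validation);
the same analyses are available from the shell:

```bash
virtrial base --out results
virtrial psa --config examples/config_example.yaml --seed 1 --out results
virtrial threshold --param op_mort_lob_70 --bracket 0 0.15 --out results
virtrial sensitivity --age 70 --plot --out results
virtrial validate --points my_points.csv --out results
```

Every command writes CSVs plus a JSON run manifest and is deterministic
given `--seed`.

## Layout

- `src/virtrial/parameters.py` — parameter triples, life tables, YAML config
- `src/virtrial/engine.py` — transition matrices, cohort trace, life expectancy
- `src/virtrial/simulate.py` — microsimulation, PSA, strategy comparison
- `src/virtrial/sensitivity.py` — one-way/tornado/two-way/threshold analyses
- `src/virtrial/fixtures.py` — synthetic inputs (toy chains, validation points)
- `src/virtrial/report.py`, `cli.py` — result tables, plots, `virtrial` CLI
- `docs/methods.md` — modelling assumptions, defaults and limitations
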