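"""First-order microsimulation: individual virtual patients.

Simulates 10,000 virtual patients per arm at age 70 under the same annual
transition law as the deterministic trace, and compares the sample mean
of years lived with the cohort life expectancy (its exact expectation).
The death-cause split shows how many patients die of the procedure itself
versus disease/background causes within the horizon.
"""

import numpy as np

from virtrial import (
    Arm,
    ModelConfig,
    ParameterSet,
    life_expectancy,
    run_cohort,
    simulate_patients,
)
from virtrial.report import life_table_for_age

params, config = ParameterSet(), ModelConfig()
age, n = 70, 10_000
lt = life_table_for_age(params, age, config)
rng = np.random.default_rng(config.rng_seed)

for arm in Arm:
    cohort_le = life_expectancy(run_cohort(arm, params, lt, age, config))
    sim = simulate_patients(arm, params, lt, age, n, rng, config)
    se = sim.years_lived.std(ddof=1) / np.sqrt(n)
    print(f"{arm.value:9s}  cohort LE {cohort_le:6.3f} y   "
          f"microsim mean {sim.years_lived.mean():6.3f} ± {se:.3f} y (n={n})")
    print(f"           death causes: {sim.death_cause.value_counts(normalize=True).round(3).to_dict()}")
print("\nThe microsimulation mean must sit within Monte Carlo error of the "
      "cohort value; the trace is its exact expectation.")
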