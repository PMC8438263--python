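"""Second-order Monte Carlo: parameter uncertainty stratified by age.

Draws every ranged model parameter from its literature interval (uniform
by default), re-evaluates both arms deterministically per draw with common
random numbers, and summarises the life-expectancy difference
(lobectomy - PBT) per diagnosis age: the virtual trial's readout.
`mean_ci_*` is the normal-theory CI of the mean difference; `ci_*` is the
(much wider) percentile interval of the parameter-uncertainty
distribution itself.
"""

import dataclasses

from virtrial import ModelConfig, ParameterSet
from virtrial.report import psa_table

params = ParameterSet()
# 2,000 iterations keep this demo quick; the headline analysis uses 10,000
config = dataclasses.replace(ModelConfig(), psa_iterations=2_000)

table = psa_table(params, config)
cols = ["age", "mean_diff", "mean_ci_low", "mean_ci_high", "ci_low", "ci_high", "p_value_normal"]
print(table[cols].round(4).to_string(index=False))
print("\nPositive mean_diff favours lobectomy; the sign flips with age as "
      "operative mortality grows faster than the background hazard.")
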