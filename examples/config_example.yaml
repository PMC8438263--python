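# Example configuration: override any model parameter (scalar or
# [base, low, high]) and any model setting; everything omitted falls back
# to the built-in literature base case.
p_prog_lob: [0.0400, 0.0133, 0.0742]
op_mort_lob_70: 0.0295

model:
  horizon_cycles: 16
  psa_iterations: 10000
  psa_distribution: uniform
  diagnosis_ages: [60, 65, 70, 75, 80, 85]
  rng_seed: 20210705
  # operative-mortality override per age, e.g. from an institutional audit:
  # op_mort_overrides: {70: 0.012, 75: 0.020}

# optional user life table (CSV with header age,q), resolved relative to
# this file:
# life_table_csv: my_life_table.csv
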