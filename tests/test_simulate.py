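"""Microsimulation and second-order Monte Carlo."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from virtrial import (
    Arm,
    ModelConfig,
    ParamTriple,
    ParameterSet,
    build_life_table,
    compare_strategies,
    life_expectancy,
    run_cohort,
    run_psa,
    sample_parameters,
    simulate_patient,
    simulate_patients,
)
from virtrial.fixtures import ToyChainSpec, make_toy_chain


def degenerate(params: ParameterSet) -> ParameterSet:
    """Collapse every range onto its base value."""
    return ParameterSet(
        **{
            name: getattr(params, name).with_value(getattr(params, name).base)
            for name in params.to_dict()
        }
    )


class TestSimulatePatient:
    def test_zero_event_patient_survives_horizon(self, rng):
        params, lt = make_toy_chain(ToyChainSpec(0.0, 15))
        out = simulate_patient(Arm.PBT, params, lt, 60, rng, ModelConfig(horizon_cycles=15))
        assert out.years_lived == 15.0
        assert out.death_cause == "censored"

    def test_certain_procedure_death(self, rng):
        params, lt = make_toy_chain(ToyChainSpec(0.0, 15))
        params = dataclasses.replace(params, op_mort_pbt=ParamTriple(1.0))
        out = simulate_patient(Arm.PBT, params, lt, 60, rng, ModelConfig(horizon_cycles=15))
        assert out.years_lived == 0.0
        assert out.death_cause == "procedure"

    def test_death_years_use_half_cycle(self, rng):
        params, lt = make_toy_chain(ToyChainSpec(1.0, 15))
        out = simulate_patient(Arm.PBT, params, lt, 60, rng, ModelConfig(horizon_cycles=15))
        assert out.years_lived == 0.5  # dies during the first cycle

    def test_trajectory_and_years_consistent(self, base_params, life_table_70, config, rng):
        for _ in range(50):
            out = simulate_patient(Arm.PBT, base_params, life_table_70, 70, rng, config)
            if out.death_cause == "censored":
                assert out.years_lived == config.horizon_cycles
            elif out.years_lived > 0:
                # death at cycle t -> trajectory has t+1 entries (incl. start)
                assert out.years_lived == len(out.trajectory) - 1 - 0.5


class TestSimulatePatients:
    def test_mean_years_matches_cohort_le(self, base_params, life_table_70, config, rng):
        df = simulate_patients(Arm.LOBECTOMY, base_params, life_table_70, 70, 40_000, rng, config)
        le = life_expectancy(run_cohort(Arm.LOBECTOMY, base_params, life_table_70, 70, config))
        se = df.years_lived.std(ddof=1) / np.sqrt(len(df))
        assert abs(df.years_lived.mean() - le) < 3 * se

    def test_death_cause_rates_match_trace(self, base_params, life_table_70, config, rng):
        df = simulate_patients(Arm.LOBECTOMY, base_params, life_table_70, 70, 40_000, rng, config)
        trace = run_cohort(Arm.LOBECTOMY, base_params, life_table_70, 70, config)
        expected_alive = trace.alive[-1]
        observed = (df.death_cause == "censored").mean()
        assert observed == pytest.approx(expected_alive, abs=0.01)


class TestSampleParameters:
    def test_degenerate_triples_unchanged(self, rng):
        ps = degenerate(ParameterSet())
        assert sample_parameters(ps, "uniform", rng) == ps

    @pytest.mark.parametrize("distribution", ["uniform", "beta"])
    def test_draws_respect_printed_ranges(self, base_params, distribution):
        rng = np.random.default_rng(5)
        draws = np.array(
            [
                sample_parameters(base_params, distribution, rng).p_prog_lob.base
                for _ in range(3000)
            ]
        )
        assert draws.min() >= 0.0133 and draws.max() <= 0.0742
        if distribution == "uniform":
            # flat draws fill the range; empirical extremes approach the bounds
            assert draws.min() < 0.0143 and draws.max() > 0.0732

    def test_uniform_mean_is_midpoint(self, base_params):
        rng = np.random.default_rng(11)
        draws = np.array(
            [sample_parameters(base_params, "uniform", rng).p_prog_pbt.base for _ in range(20000)]
        )
        assert draws.mean() == pytest.approx((0.0374 + 0.0723) / 2, abs=3 * draws.std() / 140)
        assert draws.mean() == pytest.approx(0.05485, abs=5e-4)


class TestRunPsa:
    def test_zero_variance_psa_reproduces_deterministic(self, base_params, life_table_70, config):
        cfg = dataclasses.replace(config, psa_iterations=5)
        ps = degenerate(base_params)
        psa = run_psa(ps, cfg, life_table_70, 70)
        le_l = life_expectancy(run_cohort(Arm.LOBECTOMY, ps, life_table_70, 70, cfg))
        le_p = life_expectancy(run_cohort(Arm.PBT, ps, life_table_70, 70, cfg))
        assert np.allclose(psa.le_lob, le_l) and np.allclose(psa.le_pbt, le_p)
        assert psa["diff"].nunique() == 1

    def test_same_seed_bit_identical(self, base_params, life_table_70, config):
        cfg = dataclasses.replace(config, psa_iterations=20, rng_seed=99)
        a = run_psa(base_params, cfg, life_table_70, 70)
        b = run_psa(base_params, cfg, life_table_70, 70)
        pd.testing.assert_frame_equal(a, b)

    def test_common_random_numbers_reduce_diff_variance(self, base_params, life_table_70, config):
        # sharing one draw per iteration couples the arms through the common
        # parameters, so var(diff) < var(le_lob) + var(le_pbt)
        cfg = dataclasses.replace(config, psa_iterations=800)
        paired = run_psa(base_params, cfg, life_table_70, 70, rng=np.random.default_rng(1))
        assert paired.le_lob.cov(paired.le_pbt) > 0
        assert paired["diff"].var() < paired.le_lob.var() + paired.le_pbt.var()

    def test_table_sign_pattern_across_ages(self, base_params, config):
        # lobectomy ahead at 60, near-parity in the early 70s, PBT ahead by 85
        cfg = dataclasses.replace(config, psa_iterations=400, rng_seed=17)
        means = {}
        for age in (60, 75, 85):
            lt = build_life_table(
                base_params.q70_background.base, age, cfg.horizon_cycles
            )
            means[age] = run_psa(base_params, cfg, lt, age)["diff"].mean()
        assert means[60] > 0 > means[85]
        assert abs(means[75]) < means[60]


class TestCompareStrategies:
    def test_constant_positive_diff(self):
        df = pd.DataFrame({"le_lob": [10.4] * 50, "le_pbt": [10.0] * 50, "diff": [0.4] * 50})
        res = compare_strategies(df, age=70)
        assert res.mean_diff == pytest.approx(0.4)
        assert (res.ci_low, res.ci_high) == (pytest.approx(0.4), pytest.approx(0.4))
        assert res.p_value == pytest.approx(1 / 50)

    def test_symmetric_null_distribution(self, rng):
        d = rng.normal(0.0, 1.0, size=4001)
        d = np.concatenate([d, -d])  # exactly symmetric around 0
        df = pd.DataFrame({"le_lob": d, "le_pbt": np.zeros_like(d), "diff": d})
        res = compare_strategies(df)
        assert res.p_value > 0.9
        assert res.ci_low < 0 < res.ci_high

    def test_zero_variance_zero_mean_reports_p_one(self):
        df = pd.DataFrame({"le_lob": [1.0, 1.0], "le_pbt": [1.0, 1.0], "diff": [0.0, 0.0]})
        assert compare_strategies(df).p_value == 1.0
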