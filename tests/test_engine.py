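"""Cohort engine: matrices, traces, life expectancy, survival curves."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtrial import (
    Arm,
    ModelConfig,
    ParameterSet,
    build_life_table,
    build_transition_matrix,
    health_states,
    life_expectancy,
    run_cohort,
    survival_curve,
)
from virtrial.engine import STATES
from virtrial.fixtures import ToyChainSpec, closed_form_toy_le, make_toy_chain, random_parameter_set

IDX = {s: i for i, s in enumerate(STATES)}


def toy_le_by_direct_summation(p: float, horizon: int) -> float:
    """Independent oracle: trapezoid summation of the explicit geometric
    survival sequence."""
    alive = (1.0 - p) ** np.arange(horizon + 1)
    return float(((alive[:-1] + alive[1:]) / 2).sum())


class TestHealthStates:
    def test_state_catalogue_structure(self):
        all_states = health_states()
        kinds = {s.name: s.kind for s in all_states}
        assert [n for n, k in kinds.items() if k == "absorbing"] == ["death", "procedure_death"]
        assert sorted(n for n, k in kinds.items() if k == "persistent") == [
            "ned_post_local_salvage",
            "ned_post_regional_salvage",
            "ned_primary",
            "progressive",
        ]

    def test_local_failure_only_reachable_under_pbt(self):
        assert "local_failure" not in [s.name for s in health_states("lobectomy")]
        assert "local_failure" in [s.name for s in health_states("pbt")]


class TestTransitionMatrix:
    def test_base_case_recurrence_mass(self, base_params, life_table_70, config):
        # total recurrence probability before competing mortality is 0.0400
        tm = build_transition_matrix(Arm.LOBECTOMY, base_params, life_table_70, 70, config)
        row = tm.probabilities[IDX["ned_primary"]]
        q = life_table_70.q_at(70)
        event = row[[IDX["local_failure"], IDX["regional_failure"], IDX["distant_failure"]]].sum()
        assert event == pytest.approx((1 - q) * 0.0400, abs=1e-12)
        assert row[IDX["local_failure"]] == 0.0  # no local recurrence after lobectomy

    def test_pbt_distant_fraction_is_complement(self, base_params, life_table_70, config):
        tm = build_transition_matrix(Arm.PBT, base_params, life_table_70, 70, config)
        row = tm.probabilities[IDX["ned_primary"]]
        event = row[[IDX["local_failure"], IDX["regional_failure"], IDX["distant_failure"]]].sum()
        assert row[IDX["distant_failure"]] / event == pytest.approx(
            1 - 0.0843 - 0.1076, abs=1e-12
        )

    def test_zero_event_row_reduces_to_background(self, life_table_70, config):
        toy_params, _ = make_toy_chain(ToyChainSpec(0.1))
        tm = build_transition_matrix(Arm.LOBECTOMY, toy_params, life_table_70, 70, config)
        row = tm.probabilities[IDX["ned_primary"]]
        q = life_table_70.q_at(70)
        assert row[IDX["ned_primary"]] == pytest.approx(1 - q)
        assert row[IDX["death"]] == pytest.approx(q)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("arm", list(Arm))
    def test_rows_sum_to_one_for_random_parameters(self, arm, seed, config):
        ps = random_parameter_set(np.random.default_rng(seed))
        lt = build_life_table(ps.q70_background.base, 70, config.horizon_cycles)
        tm = build_transition_matrix(arm, ps, lt, 75, config)
        assert np.allclose(tm.probabilities.sum(axis=1), 1.0, atol=1e-12)
        # absorbing rows are identity rows
        for s in ("death", "procedure_death"):
            row = np.zeros(len(STATES))
            row[IDX[s]] = 1.0
            assert np.array_equal(tm.probabilities[IDX[s]], row)


class TestCohortTrace:
    def test_cycle0_applies_procedure_mortality(self, base_params, life_table_70, config):
        lob = run_cohort(Arm.LOBECTOMY, base_params, life_table_70, 70, config)
        assert 1 - lob.alive[0] == pytest.approx(0.0295, abs=1e-12)
        pbt = run_cohort(Arm.PBT, base_params, life_table_70, 70, config)
        assert pbt.alive[0] == pytest.approx(0.999, abs=1e-12)

    def test_identity_dynamics_when_everything_zero(self):
        params, lt = make_toy_chain(ToyChainSpec(0.0))
        trace = run_cohort(Arm.PBT, params, lt, 60, ModelConfig(horizon_cycles=15))
        assert np.allclose(trace.occupancy[:, IDX["ned_primary"]], 1.0)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("arm", list(Arm))
    def test_occupancy_conservation_random_parameters(self, arm, seed, config):
        ps = random_parameter_set(np.random.default_rng(100 + seed))
        lt = build_life_table(ps.q70_background.base, 60, config.horizon_cycles)
        trace = run_cohort(arm, ps, lt, 60, config)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        for s in ("death", "procedure_death"):
            assert np.all(np.diff(trace.occupancy[:, IDX[s]]) >= -1e-12)

    def test_trace_frame_cumulative_le_matches(self, base_params, life_table_70, config):
        trace = run_cohort(Arm.LOBECTOMY, base_params, life_table_70, 70, config)
        df = trace.to_frame()
        assert df["cumulative_le"].iloc[-1] == pytest.approx(life_expectancy(trace))
        assert set(STATES) <= set(df.columns)


class TestLifeExpectancy:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        horizon=st.integers(min_value=1, max_value=25),
    )
    def test_matches_geometric_closed_form(self, p, horizon):
        params, lt = make_toy_chain(ToyChainSpec(p, horizon))
        trace = run_cohort(Arm.PBT, params, lt, 60, ModelConfig(horizon_cycles=horizon))
        le = life_expectancy(trace, half_cycle=True)
        assert le == pytest.approx(closed_form_toy_le(p, horizon), abs=1e-10)
        assert le == pytest.approx(toy_le_by_direct_summation(p, horizon), abs=1e-10)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.1, 7.5440), (0.0, 15.0), (1.0, 0.5)],
    )
    def test_fifteen_cycle_reference_values(self, p, expected):
        params, lt = make_toy_chain(ToyChainSpec(p, 15))
        trace = run_cohort(Arm.LOBECTOMY, params, lt, 60, ModelConfig(horizon_cycles=15))
        assert life_expectancy(trace) == pytest.approx(expected, abs=5e-5)

    def test_half_cycle_equals_trapezoid_of_survival_curve(self, base_params, life_table_70, config):
        trace = run_cohort(Arm.PBT, base_params, life_table_70, 70, config)
        curve = survival_curve(trace)
        assert life_expectancy(trace, half_cycle=True) == pytest.approx(
            float(np.trapezoid(curve[:, 1], curve[:, 0])), abs=1e-12
        )

    @pytest.mark.parametrize(
        "name",
        ["p_prog_lob", "mort_progression", "frac_locoreg_lob", "q70_background"],
    )
    def test_monotone_nonincreasing_in_mortality_and_progression(
        self, base_params, config, name
    ):
        # frac_locoreg_lob shifts failures from distant to salvageable, so it
        # helps; the others must not increase life expectancy
        base = getattr(base_params, name).base
        def le_at(v):
            ps = base_params.with_value(name, v)
            lt = build_life_table(ps.q70_background.base, 70, config.horizon_cycles)
            return life_expectancy(run_cohort(Arm.LOBECTOMY, ps, lt, 70, config))

        delta = le_at(min(1.0, base + 0.01)) - le_at(base)
        if name == "frac_locoreg_lob":
            assert delta > 0
        else:
            assert delta < 0


class TestSurvivalCurve:
    def test_starts_at_post_procedure_survival(self, base_params, config):
        # at the anchor age the operative mortality is exactly 0.0295
        ps = dataclasses.replace(
            base_params,
            p_prog_lob=base_params.p_prog_lob.with_value(0.0),
            frac_locoreg_lob=base_params.frac_locoreg_lob.with_value(0.0),
        )
        from virtrial import LifeTable

        lt = LifeTable(np.arange(70, 70 + config.horizon_cycles + 1),
                       np.zeros(config.horizon_cycles + 1))
        curve = survival_curve(run_cohort(Arm.LOBECTOMY, ps, lt, 70, config))
        assert curve[0, 1] == pytest.approx(1 - 0.0295)
        assert np.allclose(curve[:, 1], 1 - 0.0295)

    def test_constant_hazard_five_year_point(self):
        params, lt = make_toy_chain(ToyChainSpec(0.1, 15))
        curve = survival_curve(run_cohort(Arm.PBT, params, lt, 60, ModelConfig(horizon_cycles=15)))
        assert curve[5, 1] == pytest.approx(0.9**5, abs=1e-12)

    def test_monotone_nonincreasing(self, base_params, life_table_70, config):
        curve = survival_curve(run_cohort(Arm.PBT, base_params, life_table_70, 70, config))
        assert np.all(np.diff(curve[:, 1]) <= 1e-12)
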