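"""First-order microsimulation and second-order Monte Carlo (PSA).

Two distinct layers of randomness sit on top of the deterministic cohort
engine:

* **first order** — individual virtual patients walk through the same
  annual transition law; their mean years lived converges to the cohort
  trace's life expectancy (the trace is the exact expectation).
* **second order** — model parameters are drawn from their literature
  uncertainty ranges and the model is re-evaluated per draw, quantifying
  parameter uncertainty.  By default each draw is evaluated
  deterministically (cohort trace) for both arms with common random
  numbers, isolating parameter uncertainty from patient-level noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    STATES,
    Arm,
    build_transition_matrix,
    initial_occupancy,
    life_expectancy,
    run_cohort,
)
from .parameters import PARAM_FIELDS, LifeTable, ModelConfig, ParamTriple, ParameterSet

__all__ = [
    "PatientOutcome",
    "ComparisonResult",
    "simulate_patient",
    "simulate_patients",
    "sample_parameters",
    "run_psa",
    "compare_strategies",
]

_IDX = {name: i for i, name in enumerate(STATES)}
_DEATH = _IDX["death"]
_PROC_DEATH = _IDX["procedure_death"]

#: pseudo-mode beta concentration (alpha + beta - 2) for the 'beta' PSA option
BETA_CONCENTRATION = 4.0


@dataclass(frozen=True)
class PatientOutcome:
    """One virtual patient's walk through the model."""

    years_lived: float
    trajectory: tuple[str, ...]
    death_cause: str  # 'procedure' | 'disease_background' | 'censored'


@dataclass(frozen=True)
class ComparisonResult:
    """Mean life-expectancy difference (lobectomy − PBT) with uncertainty.

    ``ci_low``/``ci_high`` are the empirical 2.5/97.5 percentiles of the
    per-iteration difference distribution; ``mean_ci_low``/``mean_ci_high``
    are the normal-theory confidence bounds of the *mean* difference
    (mean ± 1.96·SE), the quantity a two-arm trial readout reports.
    ``p_value`` is the empirical two-sided tail probability of the
    difference distribution against 0, floored at 1/n_iterations;
    ``p_value_normal`` is the two-sided z-test alternative.
    """

    age: int
    le_lob: float
    le_pbt: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    mean_ci_low: float
    mean_ci_high: float
    p_value_normal: float
    n_iterations: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.mean_diff <= self.ci_high + 1e-9):
            raise ValueError("percentile CI must bracket the mean difference")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# first-order microsimulation


def _cycle_matrices(
    arm: Arm, params: ParameterSet, life_table: LifeTable, start_age: int, config: ModelConfig
) -> np.ndarray:
    return np.stack(
        [
            build_transition_matrix(arm, params, life_table, start_age + t, config).probabilities
            for t in range(config.horizon_cycles)
        ]
    )


def _years_lived(death_cycle: int | None, horizon: int, half_cycle: bool) -> float:
    """Death during cycle t (alive at t-1, dead at t) credits t - 0.5 years
    under half-cycle accounting; procedure deaths (cycle 0) credit 0."""
    if death_cycle is None:
        return float(horizon)
    if death_cycle == 0:
        return 0.0
    return death_cycle - 0.5 if half_cycle else float(death_cycle - 1)


def simulate_patient(
    arm: Arm | str,
    params: ParameterSet,
    life_table: LifeTable,
    start_age: int,
    rng: np.random.Generator,
    config: ModelConfig | None = None,
) -> PatientOutcome:
    """Sample one virtual patient trajectory under the cohort transition law."""
    arm = Arm(arm)
    config = config or ModelConfig()
    horizon = config.horizon_cycles
    occ0 = initial_occupancy(arm, params, start_age, config)
    pm = occ0[_PROC_DEATH]
    if rng.random() < pm:
        return PatientOutcome(0.0, ("procedure_death",), "procedure")
    state = _IDX["ned_primary"]
    trajectory = ["ned_primary"]
    death_cycle: int | None = None
    for t in range(1, horizon + 1):
        tm = build_transition_matrix(arm, params, life_table, start_age + t - 1, config)
        state = int(rng.choice(len(STATES), p=tm.probabilities[state]))
        trajectory.append(STATES[state])
        if state in (_DEATH, _PROC_DEATH):
            death_cycle = t
            break
    years = _years_lived(death_cycle, horizon, config.half_cycle_correction)
    if death_cycle is None:
        cause = "censored"
    elif state == _PROC_DEATH:
        cause = "procedure"
    else:
        cause = "disease_background"
    return PatientOutcome(years, tuple(trajectory), cause)


def simulate_patients(
    arm: Arm | str,
    params: ParameterSet,
    life_table: LifeTable,
    start_age: int,
    n_patients: int,
    rng: np.random.Generator,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Vectorised microsimulation of ``n_patients`` independent patients.

    Returns a frame with ``years_lived`` and ``death_cause`` per patient;
    the sample mean of ``years_lived`` is an unbiased estimate of the
    cohort life expectancy.
    """
    arm = Arm(arm)
    config = config or ModelConfig()
    horizon = config.horizon_cycles
    mats = _cycle_matrices(arm, params, life_table, start_age, config)
    cum = np.cumsum(mats, axis=2)

    occ0 = initial_occupancy(arm, params, start_age, config)
    pm = occ0[_PROC_DEATH]
    state = np.full(n_patients, _IDX["ned_primary"], dtype=np.int64)
    proc_dead = rng.random(n_patients) < pm
    state[proc_dead] = _PROC_DEATH
    death_cycle = np.full(n_patients, -1, dtype=np.int64)  # -1: censored
    death_cycle[proc_dead] = 0

    active = state != _PROC_DEATH
    for t in range(1, horizon + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        rows = cum[t - 1][state[idx]]  # (k, n_states) cumulative rows
        nxt = (u[:, None] > rows).sum(axis=1)
        state[idx] = nxt
        died = (nxt == _DEATH) | (nxt == _PROC_DEATH)
        death_cycle[idx[died]] = t
        active[idx[died]] = False

    years = np.where(
        death_cycle < 0,
        float(horizon),
        np.where(
            death_cycle == 0,
            0.0,
            death_cycle - 0.5 if config.half_cycle_correction else death_cycle - 1.0,
        ),
    ).astype(float)
    cause = np.where(
        death_cycle < 0,
        "censored",
        np.where(state == _PROC_DEATH, "procedure", "disease_background"),
    )
    return pd.DataFrame({"years_lived": years, "death_cause": cause})


# ---------------------------------------------------------------------------
# second-order Monte Carlo


def sample_parameters(
    params: ParameterSet,
    distribution: str,
    rng: np.random.Generator,
) -> ParameterSet:
    """Draw one parameter set from the literature ranges.

    Fields with a degenerate range are returned unchanged.  ``uniform``
    draws flat over [low, high]; ``beta`` draws a beta distribution with
    mode at the base value rescaled to [low, high].  Fields are visited in
    declaration order so that one shared stream yields common random
    numbers across the two arms of an iteration.
    """
    if distribution not in ("uniform", "beta"):
        raise ValueError("distribution must be 'uniform' or 'beta'")
    updates: dict[str, ParamTriple] = {}
    for name in PARAM_FIELDS:
        triple: ParamTriple = getattr(params, name)
        if triple.is_fixed:
            continue
        span = triple.high - triple.low
        if distribution == "uniform":
            value = rng.uniform(triple.low, triple.high)
        else:
            mode = (triple.base - triple.low) / span
            a = 1.0 + BETA_CONCENTRATION * mode
            b = 1.0 + BETA_CONCENTRATION * (1.0 - mode)
            value = triple.low + span * rng.beta(a, b)
        updates[name] = dataclasses.replace(triple, base=float(value))
    return params.replace(**updates) if updates else params


def run_psa(
    params: ParameterSet,
    config: ModelConfig,
    life_table: LifeTable,
    start_age: int,
    method: str = "cohort",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Second-order Monte Carlo: one row per outer iteration.

    Each iteration draws a parameter set (common to both arms) and
    evaluates both arms deterministically via the cohort trace
    (``method='cohort'``, default) or by microsimulation of
    ``config.cohort_size`` patients per arm (``method='microsim'``,
    layering first-order noise on top).  Reproducible from
    ``config.rng_seed``.
    """
    if config.psa_iterations < 2:
        raise ValueError("psa_iterations must be >= 2")
    if method not in ("cohort", "microsim"):
        raise ValueError("method must be 'cohort' or 'microsim'")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    sampled_fields = [
        name for name in PARAM_FIELDS if not getattr(params, name).is_fixed
    ]
    rows = []
    for it in range(config.psa_iterations):
        draw = sample_parameters(params, config.psa_distribution, rng)
        if method == "cohort":
            le_l = life_expectancy(
                run_cohort(Arm.LOBECTOMY, draw, life_table, start_age, config),
                config.half_cycle_correction,
            )
            le_p = life_expectancy(
                run_cohort(Arm.PBT, draw, life_table, start_age, config),
                config.half_cycle_correction,
            )
        else:
            le_l = float(
                simulate_patients(
                    Arm.LOBECTOMY, draw, life_table, start_age, config.cohort_size, rng, config
                )["years_lived"].mean()
            )
            le_p = float(
                simulate_patients(
                    Arm.PBT, draw, life_table, start_age, config.cohort_size, rng, config
                )["years_lived"].mean()
            )
        row = {"iteration": it}
        row.update({name: getattr(draw, name).base for name in sampled_fields})
        row.update({"le_lob": le_l, "le_pbt": le_p, "diff": le_l - le_p})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_strategies(psa_output: pd.DataFrame, age: int | None = None) -> ComparisonResult:
    """Summarise a PSA (or microsimulation) difference distribution."""
    diff = np.asarray(psa_output["diff"], dtype=float)
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 iterations to compare strategies")
    mean_diff = float(diff.mean())
    ci_low, ci_high = (float(x) for x in np.percentile(diff, [2.5, 97.5]))
    floor = 1.0 / n
    if np.allclose(diff.std(), 0.0) and abs(mean_diff) < 1e-15:
        p_emp = 1.0
    else:
        p_emp = 2.0 * min(float(np.mean(diff <= 0.0)), float(np.mean(diff >= 0.0)))
        p_emp = min(1.0, max(p_emp, floor))
    se = float(diff.std(ddof=1) / np.sqrt(n))
    if se > 0:
        from scipy.stats import norm

        z = mean_diff / se
        p_norm = float(2.0 * norm.sf(abs(z)))
        p_norm = min(1.0, max(p_norm, np.finfo(float).tiny))
    else:
        p_norm = 1.0 if abs(mean_diff) < 1e-15 else floor
    return ComparisonResult(
        age=int(age) if age is not None else -1,
        le_lob=float(psa_output["le_lob"].mean()),
        le_pbt=float(psa_output["le_pbt"].mean()),
        mean_diff=mean_diff,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_emp,
        mean_ci_low=mean_diff - 1.96 * se,
        mean_ci_high=mean_diff + 1.96 * se,
        p_value_normal=p_norm,
        n_iterations=n,
    )
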