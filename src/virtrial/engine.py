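"""Deterministic Markov cohort engine.

One cycle is one year.  The state space of the annual transition matrix is

* ``ned_primary`` — no evidence of disease after the primary treatment
  (persistent)
* ``local_failure`` / ``regional_failure`` / ``distant_failure`` — the
  recurrence, split by site, spends exactly one cycle in its failure state
  before being resolved (transient, one-cycle states); local failure exists
  only in the PBT arm — the model assumes lobectomy has no local recurrence
* ``ned_post_local_salvage`` — NED after salvage lobectomy for an isolated
  local failure after PBT (persistent)
* ``ned_post_regional_salvage`` — NED after salvage conventional
  radiotherapy ± chemotherapy for a regional failure (persistent)
* ``progressive`` — progressive disease on chemotherapy or best supportive
  care (persistent)
* ``death`` — death from disease or background causes (absorbing)
* ``procedure_death`` — death caused by the primary or a salvage procedure
  (absorbing)

On leaving a failure state the patient either receives radical salvage
treatment (site- and arm-specific probability, charged the salvage
procedure's mortality: age-current operative mortality for salvage
lobectomy, 0.0010 for salvage radiotherapy) or moves to progressive
disease; distant failures are never salvaged.  Only one round of salvage is
allowed, so progression after salvage goes directly to progressive disease.
Background mortality competes independently with disease events in every
alive state (total exit ``1 - (1-q)(1-p)``).

The cohort is evaluated over ``ModelConfig.horizon_cycles`` annual
transitions (default 16: the published model evaluates Markov stages 0-15
inclusive, so a "15-cycle" follow-up spans 16 annual evaluations — see the
methods note).  Life expectancy is therefore restricted to the model
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .parameters import (
    LifeTable,
    ModelConfig,
    ParameterSet,
    operative_mortality_at_age,
)

__all__ = [
    "Arm",
    "HealthState",
    "STATES",
    "TransitionMatrix",
    "CohortTrace",
    "health_states",
    "build_transition_matrix",
    "initial_occupancy",
    "run_cohort",
    "life_expectancy",
    "survival_curve",
]


class Arm(str, Enum):
    LOBECTOMY = "lobectomy"
    PBT = "pbt"


@dataclass(frozen=True)
class HealthState:
    name: str
    kind: str  # transient | persistent | absorbing
    arms: frozenset[str]


def _hs(name: str, kind: str, arms: Iterable[str] = ("lobectomy", "pbt")) -> HealthState:
    return HealthState(name, kind, frozenset(arms))


_CATALOGUE = (
    _hs("ned_primary", "persistent"),
    _hs("local_failure", "transient", ("pbt",)),
    _hs("regional_failure", "transient"),
    _hs("distant_failure", "transient"),
    _hs("ned_post_local_salvage", "persistent", ("pbt",)),
    _hs("ned_post_regional_salvage", "persistent"),
    _hs("progressive", "persistent"),
    _hs("death", "absorbing"),
    _hs("procedure_death", "absorbing"),
)

#: ordered states of the annual transition matrix
STATES: tuple[str, ...] = tuple(s.name for s in _CATALOGUE)
_IDX = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)
ABSORBING = ("death", "procedure_death")


def health_states(arm: Arm | str | None = None) -> list[HealthState]:
    """The state catalogue, optionally restricted to one strategy arm."""
    if arm is None:
        return list(_CATALOGUE)
    arm = Arm(arm).value
    return [s for s in _CATALOGUE if arm in s.arms]


@dataclass(frozen=True)
class TransitionMatrix:
    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        n = len(self.states)
        if p.shape != (n, n):
            raise ValueError("probability matrix must be square over the state list")
        if np.any((p < -1e-15) | (p > 1 + 1e-15)):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsum = p.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            raise ValueError(f"transition rows must sum to 1, got {rowsum}")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of one strategy arm."""

    occupancy: np.ndarray  # (horizon + 1, n_states)
    start_age: int
    arm: Arm
    cycle_length_years: float = 1.0
    states: tuple[str, ...] = STATES

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        dead = sum(self.occupancy[:, _IDX[s]] for s in ABSORBING)
        return 1.0 - dead

    def to_frame(self) -> pd.DataFrame:
        cycles = np.arange(self.occupancy.shape[0])
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", cycles)
        df.insert(1, "age", self.start_age + cycles)
        alive = self.alive
        df["alive"] = alive
        df["cumulative_le"] = np.concatenate(
            [[0.0], np.cumsum((alive[:-1] + alive[1:]) / 2.0 * self.cycle_length_years)]
        )
        return df


def _event_rates(arm: Arm, params: ParameterSet) -> tuple[float, float, float, float]:
    """(p_prog, frac_local, frac_locoreg, frac_distant) for one arm."""
    if arm is Arm.LOBECTOMY:
        p = params.p_prog_lob.base
        f_loc = 0.0
        f_reg = params.frac_locoreg_lob.base
    else:
        p = params.p_prog_pbt.base
        f_loc = params.frac_local_pbt.base
        f_reg = params.frac_locoreg_pbt.base
    f_dist = 1.0 - f_loc - f_reg
    if f_dist < -1e-12:
        raise ValueError(
            f"{arm.value}: local ({f_loc}) + locoregional ({f_reg}) fractions exceed 1"
        )
    return p, f_loc, f_reg, max(f_dist, 0.0)


def build_transition_matrix(
    arm: Arm | str,
    params: ParameterSet,
    life_table: LifeTable,
    age: int,
    config: ModelConfig | None = None,
) -> TransitionMatrix:
    """One-year transition matrix at a given attained age."""
    arm = Arm(arm)
    config = config or ModelConfig()
    q = life_table.q_at(age)
    p_prog, f_loc, f_reg, f_dist = _event_rates(arm, params)

    # salvage lobectomy for a PBT local failure: operative risk at current age
    op_mort_now = operative_mortality_at_age(
        params.op_mort_lob_70.base,
        age,
        config.operative_doubling_years,
        config.op_mort_overrides,
    )
    p_salv_loc = params.p_salv_local_pbt.base
    p_salv_reg = (
        params.p_salv_reg_lob.base if arm is Arm.LOBECTOMY else params.p_salv_reg_pbt.base
    )
    mort_rt = params.mort_salvage_rt.base
    p_post_loc = params.p_prog_post_local_salv.base
    p_post_reg = (
        params.p_prog_post_reg_salv_lob.base
        if arm is Arm.LOBECTOMY
        else params.p_prog_post_reg_salv_pbt.base
    )

    m = np.zeros((N_STATES, N_STATES))

    # NED after primary: recurrence mass (net of background death) splits by site
    event = (1.0 - q) * p_prog
    row = m[_IDX["ned_primary"]]
    row[_IDX["ned_primary"]] = (1.0 - q) * (1.0 - p_prog)
    row[_IDX["death"]] = q
    row[_IDX["local_failure"]] = event * f_loc
    row[_IDX["regional_failure"]] = event * f_reg
    row[_IDX["distant_failure"]] = event * f_dist

    # failure states resolve on exit after their single cycle
    row = m[_IDX["local_failure"]]
    row[_IDX["ned_post_local_salvage"]] = (1.0 - q) * p_salv_loc * (1.0 - op_mort_now)
    row[_IDX["procedure_death"]] = (1.0 - q) * p_salv_loc * op_mort_now
    row[_IDX["progressive"]] = (1.0 - q) * (1.0 - p_salv_loc)
    row[_IDX["death"]] = q

    row = m[_IDX["regional_failure"]]
    row[_IDX["ned_post_regional_salvage"]] = (1.0 - q) * p_salv_reg * (1.0 - mort_rt)
    row[_IDX["procedure_death"]] = (1.0 - q) * p_salv_reg * mort_rt
    row[_IDX["progressive"]] = (1.0 - q) * (1.0 - p_salv_reg)
    row[_IDX["death"]] = q

    row = m[_IDX["distant_failure"]]
    row[_IDX["progressive"]] = 1.0 - q
    row[_IDX["death"]] = q

    # NED after salvage: one salvage only, progression goes straight to
    # progressive disease
    for state, p_post in (
        ("ned_post_local_salvage", p_post_loc),
        ("ned_post_regional_salvage", p_post_reg),
    ):
        row = m[_IDX[state]]
        row[_IDX[state]] = (1.0 - q) * (1.0 - p_post)
        row[_IDX["progressive"]] = (1.0 - q) * p_post
        row[_IDX["death"]] = q

    # progressive disease: disease mortality compounds with background
    row = m[_IDX["progressive"]]
    exit_p = 1.0 - (1.0 - q) * (1.0 - params.mort_progression.base)
    row[_IDX["death"]] = exit_p
    row[_IDX["progressive"]] = 1.0 - exit_p

    for state in ABSORBING:
        m[_IDX[state], _IDX[state]] = 1.0

    return TransitionMatrix(STATES, m)


def initial_occupancy(
    arm: Arm | str,
    params: ParameterSet,
    start_age: int,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Cycle-0 occupancy: the one-time procedure mortality of the primary
    treatment is applied instantly; survivors start in NED.

    Patients dying of the procedure contribute zero life-years (no
    half-cycle credit): the procedure happens at the very start of the
    trace, not halfway through a cycle.
    """
    arm = Arm(arm)
    config = config or ModelConfig()
    if arm is Arm.LOBECTOMY:
        pm = operative_mortality_at_age(
            params.op_mort_lob_70.base,
            start_age,
            config.operative_doubling_years,
            config.op_mort_overrides,
        )
    else:
        pm = params.op_mort_pbt.base
    occ0 = np.zeros(N_STATES)
    occ0[_IDX["ned_primary"]] = 1.0 - pm
    occ0[_IDX["procedure_death"]] = pm
    return occ0


def run_cohort(
    arm: Arm | str,
    params: ParameterSet,
    life_table: LifeTable,
    start_age: int,
    config: ModelConfig | None = None,
) -> CohortTrace:
    """Propagate state-occupancy fractions through the age-advancing annual
    matrices for ``config.horizon_cycles`` transitions."""
    arm = Arm(arm)
    config = config or ModelConfig()
    horizon = config.horizon_cycles
    occ = np.empty((horizon + 1, N_STATES))
    occ[0] = initial_occupancy(arm, params, start_age, config)
    for t in range(1, horizon + 1):
        tm = build_transition_matrix(arm, params, life_table, start_age + t - 1, config)
        occ[t] = occ[t - 1] @ tm.probabilities
    return CohortTrace(occ, int(start_age), arm, config.cycle_length_years)


def life_expectancy(trace: CohortTrace, half_cycle: bool = True) -> float:
    """Restricted life expectancy (years) over the trace horizon.

    With half-cycle correction each cycle credits the trapezoid of the
    proportion alive at its endpoints — transitions are assumed to occur
    mid-cycle.  Equals the trapezoid rule applied to ``survival_curve``.
    """
    alive = trace.alive
    dt = trace.cycle_length_years
    if half_cycle:
        return float(np.sum((alive[:-1] + alive[1:]) / 2.0) * dt)
    return float(np.sum(alive[1:]) * dt)


def survival_curve(trace: CohortTrace) -> np.ndarray:
    """``(years, proportion alive)`` pairs at each integer cycle, starting
    at the post-procedure proportion; monotone non-increasing."""
    years = np.arange(trace.occupancy.shape[0]) * trace.cycle_length_years
    return np.column_stack([years, trace.alive])
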