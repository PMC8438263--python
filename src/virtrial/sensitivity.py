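"""One-way, tornado, two-way and threshold (crossover) analyses.

All analyses here are deterministic: a parameter is pinned to a value, the
cohort trace is re-evaluated for both arms, and the preferred strategy is
the one with the higher restricted life expectancy.  The tie tolerance is
1e-9 years; thresholds are located by bisection to 1e-5 on the parameter
scale.  When the varied parameter is the lobectomy operative-mortality
anchor (``op_mort_lob_70``), the whole age schedule rescales
proportionally with it — the anchor defines the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .engine import Arm, life_expectancy, run_cohort
from .parameters import (
    PARAM_FIELDS,
    LifeTable,
    ModelConfig,
    ParameterSet,
    build_life_table,
)

__all__ = [
    "TornadoEntry",
    "ThresholdResult",
    "NoCrossingError",
    "evaluate_pair",
    "one_way",
    "tornado",
    "two_way",
    "find_threshold",
]

TIE_TOL_YEARS = 1e-9
BISECT_TOL = 1e-5


class NoCrossingError(ValueError):
    """The life-expectancy difference does not change sign in the bracket."""


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    le_at_low: float
    le_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.le_at_high - self.le_at_low)


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    crossing_value: float
    bracket: tuple[float, float]
    tolerance: float
    preferred_below: str
    preferred_above: str


def _default_life_table(params: ParameterSet, age: int, config: ModelConfig) -> LifeTable:
    return build_life_table(
        params.q70_background.base,
        age,
        config.horizon_cycles,
        config.background_doubling_years,
    )


def evaluate_pair(
    params: ParameterSet,
    age: int,
    config: ModelConfig | None = None,
    life_table: LifeTable | None = None,
) -> tuple[float, float]:
    """(LE lobectomy, LE PBT) evaluated deterministically at one age."""
    config = config or ModelConfig()
    lt = life_table if life_table is not None else _default_life_table(params, age, config)
    le_l = life_expectancy(
        run_cohort(Arm.LOBECTOMY, params, lt, age, config), config.half_cycle_correction
    )
    le_p = life_expectancy(
        run_cohort(Arm.PBT, params, lt, age, config), config.half_cycle_correction
    )
    return le_l, le_p


def one_way(
    param_name: str,
    values: np.ndarray,
    base: ParameterSet,
    age: int,
    config: ModelConfig | None = None,
    life_table: LifeTable | None = None,
) -> pd.DataFrame:
    """Re-evaluate both arms with one parameter pinned to each value."""
    if param_name not in PARAM_FIELDS:
        raise KeyError(f"unknown parameter {param_name!r}")
    rows = []
    for v in np.asarray(values, dtype=float):
        le_l, le_p = evaluate_pair(base.with_value(param_name, float(v)), age, config, life_table)
        rows.append({"value": float(v), "le_lob": le_l, "le_pbt": le_p, "diff": le_l - le_p})
    return pd.DataFrame(rows)


def tornado(
    base: ParameterSet,
    age: int,
    arm: Arm | str,
    config: ModelConfig | None = None,
    life_table: LifeTable | None = None,
) -> list[TornadoEntry]:
    """One entry per ranged parameter, evaluated at its printed extremes,
    sorted by descending swing of the chosen arm's life expectancy."""
    arm = Arm(arm)
    pick = 0 if arm is Arm.LOBECTOMY else 1
    entries = []
    for name in PARAM_FIELDS:
        triple = getattr(base, name)
        if triple.is_fixed:
            continue
        le_low = evaluate_pair(base.with_value(name, triple.low), age, config, life_table)[pick]
        le_high = evaluate_pair(base.with_value(name, triple.high), age, config, life_table)[pick]
        entries.append(TornadoEntry(name, le_low, le_high))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def two_way(
    param_a: str,
    param_b: str,
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    base: ParameterSet,
    age: int,
    config: ModelConfig | None = None,
    life_table: LifeTable | None = None,
) -> pd.DataFrame:
    """Preferred strategy over a parameter grid (long format: one row per
    cell, with the LE difference and the preferred label)."""
    for name in (param_a, param_b):
        if name not in PARAM_FIELDS:
            raise KeyError(f"unknown parameter {name!r}")
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.size == 0 or grid_b.size == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for va in grid_a:
        pa = base.with_value(param_a, float(va))
        for vb in grid_b:
            le_l, le_p = evaluate_pair(pa.with_value(param_b, float(vb)), age, config, life_table)
            d = le_l - le_p
            label = "tie" if abs(d) < TIE_TOL_YEARS else ("lobectomy" if d > 0 else "pbt")
            rows.append(
                {param_a: float(va), param_b: float(vb), "diff": d, "preferred": label}
            )
    return pd.DataFrame(rows)


def find_threshold(
    param_name: str,
    base: ParameterSet,
    age: int,
    bracket: tuple[float, float],
    tol: float = BISECT_TOL,
    config: ModelConfig | None = None,
    life_table: LifeTable | None = None,
) -> ThresholdResult:
    """Bisect the parameter value where the preferred strategy flips."""
    if param_name not in PARAM_FIELDS:
        raise KeyError(f"unknown parameter {param_name!r}")
    lo, hi = float(bracket[0]), float(bracket[1])

    def diff(v: float) -> float:
        le_l, le_p = evaluate_pair(base.with_value(param_name, v), age, config, life_table)
        return le_l - le_p

    d_lo, d_hi = diff(lo), diff(hi)
    if np.sign(d_lo) == np.sign(d_hi):
        raise NoCrossingError(
            f"LE difference has the same sign at both ends of {bracket} "
            f"({d_lo:+.4f}, {d_hi:+.4f}); no crossover for {param_name}"
        )
    crossing = float(bisect(diff, lo, hi, xtol=tol))
    below = "lobectomy" if d_lo > 0 else "pbt"
    above = "lobectomy" if d_hi > 0 else "pbt"
    return ThresholdResult(param_name, crossing, (lo, hi), tol, below, above)
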