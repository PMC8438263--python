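"""Synthetic fixtures: analytic toy chains, random parameter sets and
noisy external-validation points.

Everything here is generated programmatically and reproducible from a
seed; nothing is downloaded.  The toy constant-hazard chain gives the
cohort engine an exact geometric-series oracle; the validation points
emulate literature five-year overall-survival values scattered around a
known curve (real study values can be supplied through the documented
``study,median_age,five_year_os,n`` CSV instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import LifeTable, ParamTriple, ParameterSet

__all__ = [
    "ToyChainSpec",
    "ValidationPoint",
    "make_toy_chain",
    "closed_form_toy_le",
    "random_parameter_set",
    "make_validation_points",
    "validation_points_frame",
]


@dataclass(frozen=True)
class ToyChainSpec:
    annual_death: float
    horizon: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_death <= 1.0:
            raise ValueError("annual_death must be a probability")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


def make_toy_chain(spec: ToyChainSpec) -> tuple[ParameterSet, LifeTable]:
    """A pure constant-hazard model: all disease parameters and procedure
    mortalities zero, flat life table at ``annual_death``."""
    zero = ParamTriple(0.0)
    params = ParameterSet(
        q70_background=ParamTriple(spec.annual_death),
        op_mort_lob_70=zero,
        op_mort_pbt=zero,
        mort_salvage_rt=zero,
        p_prog_lob=zero,
        p_prog_pbt=zero,
        frac_local_pbt=zero,
        frac_locoreg_lob=zero,
        frac_locoreg_pbt=zero,
        p_salv_local_pbt=zero,
        p_salv_reg_lob=zero,
        p_salv_reg_pbt=zero,
        p_prog_post_local_salv=zero,
        p_prog_post_reg_salv_lob=zero,
        p_prog_post_reg_salv_pbt=zero,
        mort_progression=zero,
    )
    ages = np.arange(60, 60 + spec.horizon + 1)
    life_table = LifeTable(ages, np.full(ages.shape, spec.annual_death))
    return params, life_table


def closed_form_toy_le(annual_death: float, horizon: int, half_cycle: bool = True) -> float:
    """Geometric-series life expectancy of the constant-hazard chain.

    With survival ``S(t) = (1-p)^t`` the trapezoid (half-cycle) sum is
    ``(1 - p/2) * (1 - (1-p)^T) / p`` for ``p > 0``.
    """
    p = float(annual_death)
    if p == 0.0:
        return float(horizon)
    # -expm1(T*log1p(-p)) computes 1-(1-p)^T without cancellation at tiny p
    one_minus_sT = 1.0 if p == 1.0 else -np.expm1(horizon * np.log1p(-p))
    if half_cycle:
        return (1.0 - p / 2.0) * one_minus_sT / p
    return (1.0 - p) * one_minus_sT / p


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random valid parameter set (for property-based tests).

    Triples are drawn with 0 <= low <= base <= high <= 1 and the site
    fractions constrained so the distant share stays a probability for any
    combination within the ranges.
    """

    def triple(lo: float = 0.0, hi: float = 1.0) -> ParamTriple:
        a, b, c = np.sort(rng.uniform(lo, hi, size=3))
        return ParamTriple(float(b), float(a), float(c))

    # split at most mass 1 between local and locoregional highs per arm
    split_pbt = rng.uniform(0, 1)
    frac_local_pbt = triple(0.0, split_pbt)
    frac_locoreg_pbt = triple(0.0, 1.0 - split_pbt)
    return ParameterSet(
        q70_background=triple(1e-6, 0.5),
        op_mort_lob_70=triple(0.0, 0.3),
        op_mort_pbt=triple(0.0, 0.1),
        mort_salvage_rt=triple(0.0, 0.1),
        p_prog_lob=triple(0.0, 0.5),
        p_prog_pbt=triple(0.0, 0.5),
        frac_local_pbt=frac_local_pbt,
        frac_locoreg_lob=triple(0.0, 1.0),
        frac_locoreg_pbt=frac_locoreg_pbt,
        p_salv_local_pbt=triple(),
        p_salv_reg_lob=triple(),
        p_salv_reg_pbt=triple(),
        p_prog_post_local_salv=triple(0.0, 0.5),
        p_prog_post_reg_salv_lob=triple(0.0, 0.5),
        p_prog_post_reg_salv_pbt=triple(0.0, 0.5),
        mort_progression=triple(0.0, 1.0),
    )


@dataclass(frozen=True)
class ValidationPoint:
    """One literature study's five-year overall survival."""

    study: str
    median_age: float
    five_year_os: float
    n_patients: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.five_year_os <= 1.0:
            raise ValueError("five_year_os must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def make_validation_points(
    true_curve: np.ndarray,
    n_studies: int,
    noise_sd: float,
    rng: np.random.Generator,
    median_age: float = 70.0,
) -> list[ValidationPoint]:
    """Noisy synthetic study points around a model survival curve.

    ``true_curve`` is the (years, proportion alive) array of
    :func:`virtrial.engine.survival_curve`; each synthetic study reports
    the curve's year-5 value plus Gaussian noise clipped to [0, 1], with a
    random patient count weighting the studies.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    curve = np.asarray(true_curve, dtype=float)
    truth = float(np.interp(5.0, curve[:, 0], curve[:, 1]))
    points = []
    for i in range(int(n_studies)):
        os5 = float(np.clip(truth + rng.normal(0.0, noise_sd) if noise_sd > 0 else truth, 0, 1))
        n = int(rng.integers(30, 300))
        points.append(ValidationPoint(f"synthetic-{i + 1}", median_age, os5, n))
    return points


def validation_points_frame(points: list[ValidationPoint]) -> pd.DataFrame:
    """CSV-schema frame: ``study,median_age,five_year_os,n``."""
    return pd.DataFrame(
        {
            "study": [p.study for p in points],
            "median_age": [p.median_age for p in points],
            "five_year_os": [p.five_year_os for p in points],
            "n": [p.n_patients for p in points],
        }
    )
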