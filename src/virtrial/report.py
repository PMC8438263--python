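"""High-level result tables and plots: the four headline analyses.

These functions tie the engine, simulation and sensitivity modules into
the study's experiments: per-age base-case life expectancies, the
stratified PSA comparison table, the operative-mortality crossover scan
and the survival-curve validation against external five-year OS points.
Each returns a plain DataFrame (all numbers live in CSVs; plots are side
effects only).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Arm, run_cohort, survival_curve
from .parameters import LifeTable, ModelConfig, ParameterSet, build_life_table
from .sensitivity import evaluate_pair, find_threshold, one_way
from .simulate import compare_strategies, run_psa

__all__ = [
    "life_table_for_age",
    "base_case_table",
    "psa_table",
    "operative_mortality_scan",
    "validate_survival",
]


def life_table_for_age(
    params: ParameterSet, age: int, config: ModelConfig, life_table: LifeTable | None = None
) -> LifeTable:
    """The user-supplied life table, or the default exponential one anchored
    at the age-70 background mortality."""
    if life_table is not None:
        return life_table
    return build_life_table(
        params.q70_background.base, age, config.horizon_cycles, config.background_doubling_years
    )


def base_case_table(
    params: ParameterSet, config: ModelConfig, life_table: LifeTable | None = None
) -> pd.DataFrame:
    """Deterministic base-case LE per diagnosis age and arm."""
    rows = []
    for age in config.diagnosis_ages:
        lt = life_table_for_age(params, age, config, life_table)
        le_l, le_p = evaluate_pair(params, age, config, lt)
        rows.append({"age": age, "le_lob": le_l, "le_pbt": le_p, "diff": le_l - le_p})
    return pd.DataFrame(rows)


def psa_table(
    params: ParameterSet,
    config: ModelConfig,
    life_table: LifeTable | None = None,
    ages: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Second-order Monte Carlo comparison per diagnosis age.

    Per-age seeds are derived from ``config.rng_seed`` so the whole table
    is reproducible and ages are independent.
    """
    rows = []
    seed_seq = np.random.SeedSequence(config.rng_seed)
    ages = ages if ages is not None else config.diagnosis_ages
    for age, child in zip(ages, seed_seq.spawn(len(ages))):
        lt = life_table_for_age(params, age, config, life_table)
        psa = run_psa(params, config, lt, age, rng=np.random.default_rng(child))
        res = compare_strategies(psa, age)
        rows.append(
            {
                "age": age,
                "le_lob": res.le_lob,
                "le_pbt": res.le_pbt,
                "mean_diff": res.mean_diff,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "mean_ci_low": res.mean_ci_low,
                "mean_ci_high": res.mean_ci_high,
                "p_value": res.p_value,
                "p_value_normal": res.p_value_normal,
            }
        )
    return pd.DataFrame(rows)


def operative_mortality_scan(
    params: ParameterSet,
    config: ModelConfig,
    age: int = 70,
    values: np.ndarray | None = None,
    life_table: LifeTable | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """LE of both arms while the lobectomy operative-mortality anchor varies
    (the whole age schedule rescales with it); returns the scan and the
    crossover value if the preference flips inside the scanned range."""
    values = values if values is not None else np.linspace(0.0, 0.15, 31)
    lt = life_table_for_age(params, age, config, life_table)
    scan = one_way("op_mort_lob_70", values, params, age, config, lt)
    crossing = None
    sign = np.sign(scan["diff"].to_numpy())
    if sign.min() < 0 < sign.max():
        crossing = find_threshold(
            "op_mort_lob_70",
            params,
            age,
            (float(values[0]), float(values[-1])),
            config=config,
            life_table=lt,
        ).crossing_value
    return scan, crossing


def validate_survival(
    params: ParameterSet,
    config: ModelConfig,
    points: pd.DataFrame,
    arm: Arm | str,
    age: int = 70,
    life_table: LifeTable | None = None,
) -> dict[str, float]:
    """Compare the model's five-year OS with external study points.

    ``points`` follows the ``study,median_age,five_year_os,n`` schema; the
    studies' patient-weighted mean five-year OS is compared with the model
    curve at year 5.
    """
    lt = life_table_for_age(params, age, config, life_table)
    curve = survival_curve(run_cohort(Arm(arm), params, lt, age, config))
    model_os5 = float(np.interp(5.0, curve[:, 0], curve[:, 1]))
    w = points["n"].to_numpy(dtype=float)
    observed = float(np.average(points["five_year_os"].to_numpy(dtype=float), weights=w))
    return {
        "model_five_year_os": model_os5,
        "observed_weighted_mean": observed,
        "absolute_difference": abs(model_os5 - observed),
        "n_studies": float(len(points)),
    }


# ---------------------------------------------------------------------------
# plots (side effects only)


def plot_life_expectancy(table: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["age"], table["le_lob"], "o-", label="Lobectomy")
    ax.plot(table["age"], table["le_pbt"], "s--", label="PBT")
    ax.set_xlabel("Age at diagnosis (years)")
    ax.set_ylabel("Restricted life expectancy (years)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_operative_mortality_scan(
    scan: pd.DataFrame, crossing: float | None, path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(scan["value"] * 100, scan["le_lob"], label="Lobectomy")
    ax.plot(scan["value"] * 100, scan["le_pbt"], label="PBT")
    if crossing is not None:
        ax.axvline(crossing * 100, color="gray", ls=":", label=f"crossover {crossing:.1%}")
    ax.set_xlabel("Operative mortality after lobectomy (%)")
    ax.set_ylabel("Restricted life expectancy (years)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_two_way_map(grid: pd.DataFrame, param_a: str, param_b: str, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid.pivot(index=param_b, columns=param_a, values="diff")
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    mesh = ax.pcolormesh(
        pivot.columns, pivot.index, np.sign(pivot.to_numpy()), cmap="coolwarm", vmin=-1, vmax=1
    )
    ax.set_xlabel(param_a)
    ax.set_ylabel(param_b)
    ax.set_title("red: lobectomy preferred, blue: PBT preferred")
    fig.colorbar(mesh, ax=ax, label="sign of LE difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_survival_validation(
    curve: np.ndarray, points: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve[:, 0], curve[:, 1] * 100, label="Markov model")
    w = points["n"].to_numpy(dtype=float)
    ax.scatter(
        np.full(len(points), 5.0), points["five_year_os"] * 100, c="gray", s=20, label="studies"
    )
    mean = np.average(points["five_year_os"], weights=w)
    ax.scatter([5.0], [mean * 100], marker="s", c="black", s=60, label="weighted mean")
    ax.set_xlabel("Years after treatment")
    ax.set_ylabel("Overall survival (%)")
    if title:
        ax.set_title(title)
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
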