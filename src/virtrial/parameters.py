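"""Model parameters, life tables and configuration.

The decision model compares two strategies for medically operable stage IA
non-small cell lung cancer: lobectomy (with mediastinal node dissection) and
particle beam therapy (PBT; protons or carbon ions).  Every transition
probability is stored as a :class:`ParamTriple` — a base-case value together
with the low/high extremes reported across the source literature — so the
same object feeds the deterministic model, the one-way/tornado analyses and
the probabilistic sensitivity analysis.

Two quantities are only anchored at age 70 by the published evidence: the
annual background mortality of the general population (0.018679) and the
operative (90-day) mortality of lobectomy (0.0295).  For other diagnosis
ages the package extrapolates both exponentially in age — a Gompertz-type
schedule with a configurable doubling time — and either schedule can be
replaced by user-supplied values.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("virtrial")

__all__ = [
    "ParamTriple",
    "ParameterSet",
    "LifeTable",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "build_life_table",
    "operative_mortality_at_age",
    "PARAM_FIELDS",
]

#: default mortality doubling time (years) for the background life table
BACKGROUND_DOUBLING_YEARS = 8.0
#: default doubling time (years) for lobectomy operative mortality
OPERATIVE_DOUBLING_YEARS = 10.0


class ConfigError(ValueError):
    """Raised when a configuration file violates the documented schema."""


@dataclass(frozen=True)
class ParamTriple:
    """An annual probability with its literature uncertainty range.

    ``low == base == high`` encodes a parameter that is held fixed in every
    sensitivity analysis.
    """

    base: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        low = self.base if self.low is None else self.low
        high = self.base if self.high is None else self.high
        object.__setattr__(self, "low", float(low))
        object.__setattr__(self, "high", float(high))
        object.__setattr__(self, "base", float(self.base))
        if not (0.0 <= self.low <= self.base <= self.high <= 1.0):
            raise ConfigError(
                f"invalid probability triple base={self.base} "
                f"low={self.low} high={self.high}: need 0 <= low <= base <= high <= 1"
            )

    @property
    def is_fixed(self) -> bool:
        return self.low == self.high

    def with_value(self, value: float) -> "ParamTriple":
        """A degenerate copy pinned at ``value`` (used by one-way scans)."""
        return ParamTriple(value, value, value)

    def as_list(self) -> list[float]:
        return [self.base, self.low, self.high]


@dataclass(frozen=True)
class ParameterSet:
    """All transition probabilities of the model (annual unless noted).

    Field naming: ``p_prog_*`` are annual probabilities of disease
    progression (any recurrence) from the no-evidence-of-disease state;
    ``frac_*`` split a recurrence event by site; ``p_salv_*`` are the
    probabilities that a loco-regional recurrence receives radical salvage
    treatment; ``mort_*`` are mortality probabilities.
    """

    # background mortality anchor: general population, age 70
    q70_background: ParamTriple = ParamTriple(0.018679)
    # one-time procedure-related mortality
    op_mort_lob_70: ParamTriple = ParamTriple(0.0295)
    op_mort_pbt: ParamTriple = ParamTriple(0.001)
    mort_salvage_rt: ParamTriple = ParamTriple(0.0010)
    # annual probability of disease progression after primary treatment
    p_prog_lob: ParamTriple = ParamTriple(0.0400, 0.0133, 0.0742)
    p_prog_pbt: ParamTriple = ParamTriple(0.0568, 0.0374, 0.0723)
    # site split of a recurrence event (remainder is distant failure)
    frac_local_pbt: ParamTriple = ParamTriple(0.0843, 0.0, 0.2222)
    frac_locoreg_lob: ParamTriple = ParamTriple(0.2784, 0.0952, 0.4)
    frac_locoreg_pbt: ParamTriple = ParamTriple(0.1076, 0.0, 0.25)
    # probability of radical salvage treatment given the recurrence site
    p_salv_local_pbt: ParamTriple = ParamTriple(0.6321)
    p_salv_reg_lob: ParamTriple = ParamTriple(0.3446, 0.3172, 0.3888)
    p_salv_reg_pbt: ParamTriple = ParamTriple(0.3095, 0.2941, 0.6321)
    # annual probability of progression after radical salvage treatment
    p_prog_post_local_salv: ParamTriple = ParamTriple(0.0459, 0.0, 0.0799)
    p_prog_post_reg_salv_lob: ParamTriple = ParamTriple(0.2639, 0.2342, 0.2865)
    p_prog_post_reg_salv_pbt: ParamTriple = ParamTriple(0.3115, 0.254, 0.3835)
    # annual mortality in the progressive-disease state (chemo or BSC)
    mort_progression: ParamTriple = ParamTriple(0.6268, 0.4624, 0.8105)

    def __post_init__(self) -> None:
        # the distant-failure share 1 - local - locoregional must stay a
        # probability for every combination the PSA can draw
        for arm, local, locoreg in (
            ("lobectomy", ParamTriple(0.0), self.frac_locoreg_lob),
            ("pbt", self.frac_local_pbt, self.frac_locoreg_pbt),
        ):
            if local.high + locoreg.high > 1.0 + 1e-12:
                raise ConfigError(
                    f"{arm}: local + locoregional failure fractions can exceed 1 "
                    f"({local.high} + {locoreg.high}); the distant fraction would be negative"
                )

    def replace(self, **kwargs: ParamTriple) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy with one field pinned to ``value`` (degenerate triple)."""
        if name not in PARAM_FIELDS:
            raise KeyError(f"unknown parameter {name!r}; valid: {sorted(PARAM_FIELDS)}")
        return self.replace(**{name: ParamTriple(value, value, value)})

    def to_dict(self) -> dict[str, list[float]]:
        return {f.name: getattr(self, f.name).as_list() for f in dataclasses.fields(self)}


PARAM_FIELDS: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(ParameterSet))


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause mortality of the general population."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.shape != q.shape or ages.ndim != 1 or ages.size == 0:
            raise ConfigError("life table needs matching 1-d age and q arrays")
        if np.any((q < 0) | (q > 1)):
            raise ConfigError("life-table mortality probabilities must lie in [0, 1]")
        if np.any(np.diff(ages) != 1):
            raise ConfigError("life-table ages must be consecutive integers")
        if np.any(np.diff(q) < 0):
            warnings.warn("life-table mortality is not non-decreasing in age", stacklevel=2)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    def q_at(self, age: int | float) -> float:
        age = int(age)
        lo, hi = int(self.ages[0]), int(self.ages[-1])
        if not lo <= age <= hi:
            raise ValueError(f"age {age} outside life table range [{lo}, {hi}]")
        return float(self.q[age - lo])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, "q": self.q})

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"age", "q"}.issubset(df.columns):
            raise ConfigError(f"life-table CSV {path} must have columns age,q")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["q"].to_numpy())


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings: horizon, cohort sizes, seeds, PSA options."""

    # number of annual transitions evaluated; the published trace spans
    # Markov stages 0-15 inclusive, i.e. 16 annual evaluations
    horizon_cycles: int = 16
    cycle_length_years: float = 1.0
    half_cycle_correction: bool = True
    cohort_size: int = 10_000
    diagnosis_ages: tuple[int, ...] = (60, 65, 70, 75, 80, 85)
    rng_seed: int = 20210705
    psa_iterations: int = 10_000
    psa_distribution: str = "uniform"
    background_doubling_years: float = BACKGROUND_DOUBLING_YEARS
    operative_doubling_years: float = OPERATIVE_DOUBLING_YEARS
    # optional per-age overrides of lobectomy operative mortality
    op_mort_overrides: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ConfigError("horizon_cycles must be >= 1")
        if self.cohort_size < 1:
            raise ConfigError("cohort_size must be >= 1")
        if self.psa_distribution not in ("uniform", "beta"):
            raise ConfigError("psa_distribution must be 'uniform' or 'beta'")
        for a in self.diagnosis_ages:
            if not 60 <= a <= 85:
                raise ConfigError(f"diagnosis age {a} outside the modelled range 60-85")
        object.__setattr__(self, "diagnosis_ages", tuple(int(a) for a in self.diagnosis_ages))


def build_life_table(
    q70: float,
    start_age: int,
    horizon: int,
    doubling_time: float = BACKGROUND_DOUBLING_YEARS,
) -> LifeTable:
    """Exponential-in-age life table anchored at the age-70 value.

    ``q(a) = min(1, q70 * 2**((a - 70) / doubling_time))`` over
    ``[start_age, start_age + horizon]``.  A Gompertz-type shape: adult
    all-cause mortality roughly doubles every 8 years.
    """
    if not 0.0 < q70 < 1.0:
        raise ValueError("q70 must be in (0, 1)")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    ages = np.arange(int(start_age), int(start_age) + int(horizon) + 1)
    q = q70 * 2.0 ** ((ages - 70) / doubling_time)
    if np.any(q > 1.0):
        logger.warning("life-table extrapolation clamped to 1.0 at high ages")
        q = np.minimum(q, 1.0)
    return LifeTable(ages, q)


def operative_mortality_at_age(
    anchor_70: float,
    age: int | float,
    doubling_time: float = OPERATIVE_DOUBLING_YEARS,
    overrides: Mapping[int, float] | None = None,
) -> float:
    """Lobectomy operative (90-day) mortality at a given age.

    Defaults to the same exponential-in-age form as the life table, anchored
    at ``anchor_70`` at age 70; an explicit per-age override table wins.
    """
    if overrides is not None and int(age) in overrides:
        return float(overrides[int(age)])
    if not 0.0 <= anchor_70 < 1.0:
        raise ValueError("operative-mortality anchor must be in [0, 1)")
    p = anchor_70 * 2.0 ** ((age - 70) / doubling_time)
    if p > 1.0:
        logger.warning("operative mortality clamped to 1.0 at age %s", age)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# configuration file handling


_CONFIG_KEYS = {
    "horizon_cycles",
    "cycle_length_years",
    "half_cycle_correction",
    "cohort_size",
    "diagnosis_ages",
    "rng_seed",
    "psa_iterations",
    "psa_distribution",
    "background_doubling_years",
    "operative_doubling_years",
    "op_mort_overrides",
}


def _parse_triple(name: str, value: object) -> ParamTriple:
    try:
        if isinstance(value, (int, float)):
            return ParamTriple(float(value))
        if isinstance(value, (list, tuple)) and len(value) in (1, 3) and all(
            isinstance(v, (int, float)) for v in value
        ):
            if len(value) == 1:
                return ParamTriple(float(value[0]))
            base, low, high = (float(v) for v in value)
            return ParamTriple(base, low, high)
    except ConfigError as exc:
        raise ConfigError(f"parameter {name!r}: {exc}") from exc
    raise ConfigError(
        f"parameter {name!r} must be a number or a [base, low, high] list, got {value!r}"
    )


def load_config(path: str | Path) -> tuple[ParameterSet, ModelConfig, LifeTable | None]:
    """Parse a YAML configuration file.

    Schema: a top-level mapping whose keys are ParameterSet field names
    (value: scalar or ``[base, low, high]``), an optional ``model`` mapping
    with ModelConfig fields, and an optional ``life_table_csv`` path
    (resolved relative to the config file).  Anything omitted falls back to
    the built-in base case.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    triples: dict[str, ParamTriple] = {}
    model_kwargs: dict[str, object] = {}
    life_table: LifeTable | None = None
    for key, value in raw.items():
        if key in PARAM_FIELDS:
            triples[key] = _parse_triple(key, value)
        elif key == "model":
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: 'model' must be a mapping")
            unknown = set(value) - _CONFIG_KEYS
            if unknown:
                raise ConfigError(f"{path}: unknown model keys {sorted(unknown)}")
            model_kwargs = dict(value)
        elif key == "life_table_csv":
            life_table = LifeTable.from_csv(path.parent / str(value))
        else:
            raise ConfigError(f"{path}: unknown key {key!r}")

    if "diagnosis_ages" in model_kwargs:
        model_kwargs["diagnosis_ages"] = tuple(model_kwargs["diagnosis_ages"])  # type: ignore[arg-type]
    if model_kwargs.get("op_mort_overrides") is not None:
        model_kwargs["op_mort_overrides"] = {
            int(k): float(v) for k, v in dict(model_kwargs["op_mort_overrides"]).items()  # type: ignore[call-overload]
        }
    params = ParameterSet(**triples)
    config = ModelConfig(**model_kwargs)  # type: ignore[arg-type]
    return params, config, life_table


def save_config(
    path: str | Path, params: ParameterSet, config: ModelConfig | None = None
) -> None:
    """Serialize a parameter set (and optional model settings) to YAML."""
    doc: dict[str, object] = {k: v for k, v in params.to_dict().items()}
    if config is not None:
        model = dataclasses.asdict(config)
        model["diagnosis_ages"] = list(config.diagnosis_ages)
        doc["model"] = model
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
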