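"""Model parameter registry: base-case values, sensitivity ranges and
probabilistic distributions.

Every input of the decision model lives here: per-mode PPH probabilities,
the carbetocin relative risk, the downstream cascade proportions, lengths
of stay, disutilities and unit costs. A packaged YAML config
(``data/default_parameters.yaml``) carries the base-case values together
with the deterministic sensitivity ranges and the distribution family used
in probabilistic sensitivity analysis.

Distribution shapes are re-derived deterministically from (base, range):
triangular ranges become ``triangular(low, base, high)``; beta ranges are
moment-matched with mean equal to the base value and the range read as a
central 95% interval (sd = width / 3.92). Degenerate ranges fall back to a
point mass.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Literal, Mapping, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ParameterSet",
    "SensitivityRange",
    "DistributionSpec",
    "ModelConfig",
    "ConfigError",
    "load_parameters",
    "load_config",
    "build_distribution",
    "default_config_path",
]

#: central-interval width, in standard deviations, used when a sensitivity
#: range is reinterpreted as a 95% interval for beta moment matching
_Z95_WIDTH = 2 * 1.959963984540054


class ConfigError(ValueError):
    """A configuration source is missing a required field or is unreadable."""


class ParameterSet(BaseModel):
    """All base-case inputs of the decision model.

    Probabilities are per birth (or conditional, as named); lengths of stay
    in days; costs in 2022 USD; ``wtp_threshold`` in USD per QALY.
    """

    model_config = ConfigDict(frozen=True)

    # clinical cascade
    p_csection: float = Field(ge=0.0, le=1.0)
    p_pph_oxy_vaginal: float = Field(ge=0.0, le=1.0)
    p_pph_oxy_csection: float = Field(ge=0.0, le=1.0)
    rr_carbetocin: float = Field(gt=0.0)
    p_massive_given_pph_vaginal: float = Field(ge=0.0, le=1.0)
    p_massive_given_pph_csection: float = Field(ge=0.0, le=1.0)
    p_hysterectomy_given_massive: float = Field(ge=0.0, le=1.0)
    p_death_given_hysterectomy: float = Field(ge=0.0, le=1.0)
    # utility
    maternal_age: float = Field(ge=0.0)
    utility_baseline: float = Field(ge=0.0, le=1.0)
    disutility_pph_no_hyst: float = Field(ge=0.0)
    disutility_pph_hyst: float = Field(ge=0.0)
    # length of stay (days)
    los_vaginal_no_pph: float = Field(ge=0.0)
    los_csection_no_pph: float = Field(ge=0.0)
    los_second_line: float = Field(ge=0.0)
    los_hysterectomy: float = Field(ge=0.0)
    los_pph_multiplier: float = Field(ge=1.0)
    # unit costs (USD)
    cost_prevention_oxytocin: float = Field(ge=0.0)
    cost_prevention_carbetocin: float = Field(ge=0.0)
    cost_uterotonic_treatment: float = Field(ge=0.0)
    cost_second_line: float = Field(ge=0.0)
    cost_hysterectomy: float = Field(ge=0.0)
    cost_day_general: float = Field(ge=0.0)
    cost_day_hdu: float = Field(ge=0.0)
    cost_day_icu: float = Field(ge=0.0)
    cost_day_pph_no_hyst: float = Field(ge=0.0)
    cost_day_pph_hyst: float = Field(ge=0.0)
    # analysis settings
    annual_discount_rate: float = Field(ge=0.0)
    wtp_threshold: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check_disutilities(self) -> "ParameterSet":
        for name in ("disutility_pph_no_hyst", "disutility_pph_hyst"):
            value = getattr(self, name)
            if value > self.utility_baseline:
                raise ValueError(
                    f"{name} = {value} exceeds utility_baseline = "
                    f"{self.utility_baseline}"
                )
        return self

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with the named fields replaced (re-validated)."""
        return ParameterSet(**{**self.model_dump(), **updates})

    def to_dict(self) -> dict[str, float]:
        return self.model_dump()


class SensitivityRange(BaseModel):
    """Low/high limits over which a parameter is varied in one-way DSA."""

    model_config = ConfigDict(frozen=True)

    parameter_name: str
    low: float
    high: float

    @model_validator(mode="after")
    def _check_order(self) -> "SensitivityRange":
        if self.low > self.high:
            raise ValueError(
                f"{self.parameter_name}: low {self.low} > high {self.high}"
            )
        return self

    @property
    def width(self) -> float:
        return self.high - self.low


class DistributionSpec(BaseModel):
    """A sampling distribution for one parameter in probabilistic analysis.

    ``family`` is ``beta`` (shape parameters ``alpha``/``beta_``),
    ``triangular`` (``minimum``/``mode``/``maximum``), or ``fixed``
    (point mass at ``value``).
    """

    model_config = ConfigDict(frozen=True)

    parameter_name: str
    family: Literal["beta", "triangular", "fixed"]
    alpha: Optional[float] = None
    beta_: Optional[float] = None
    minimum: Optional[float] = None
    mode: Optional[float] = None
    maximum: Optional[float] = None
    value: Optional[float] = None

    @model_validator(mode="after")
    def _check_shape(self) -> "DistributionSpec":
        if self.family == "beta":
            if self.alpha is None or self.beta_ is None:
                raise ValueError("beta family requires alpha and beta_")
            if self.alpha <= 0 or self.beta_ <= 0:
                raise ValueError("beta shape parameters must be positive")
        elif self.family == "triangular":
            if None in (self.minimum, self.mode, self.maximum):
                raise ValueError("triangular family requires min/mode/max")
            if not (self.minimum <= self.mode <= self.maximum):
                raise ValueError(
                    f"triangular requires min <= mode <= max, got "
                    f"({self.minimum}, {self.mode}, {self.maximum})"
                )
        elif self.value is None:
            raise ValueError("fixed family requires value")
        return self

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw from the distribution with the given generator."""
        if self.family == "beta":
            return rng.beta(self.alpha, self.beta_, size=size)
        if self.family == "triangular":
            if self.minimum == self.maximum:  # degenerate support
                return np.full(size, self.minimum) if size else self.minimum
            return rng.triangular(self.minimum, self.mode, self.maximum, size=size)
        return np.full(size, self.value) if size else self.value

    def mean(self) -> float:
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta_)
        if self.family == "triangular":
            return (self.minimum + self.mode + self.maximum) / 3.0
        return self.value


def build_distribution(
    param_name: str,
    base: float,
    range_: SensitivityRange,
    family: str,
) -> DistributionSpec:
    """Construct the sampling spec for one parameter.

    Triangular: min = range low, mode = base, max = range high. Beta: method
    of moments with mean = base and sd = range width / 3.92 (the range read
    as a central 95% interval); if the implied variance is infeasible the
    spec falls back to a triangular over the same range with a warning.
    A zero-width range yields a point mass at the base value.
    """
    if not (range_.low <= base <= range_.high):
        raise ValueError(
            f"{param_name}: base {base} outside range "
            f"[{range_.low}, {range_.high}]"
        )
    if range_.width == 0.0:
        return DistributionSpec(parameter_name=param_name, family="fixed", value=base)
    if family == "triangular":
        return DistributionSpec(
            parameter_name=param_name,
            family="triangular",
            minimum=range_.low,
            mode=base,
            maximum=range_.high,
        )
    if family != "beta":
        raise ValueError(f"unknown distribution family {family!r}")
    sd = range_.width / _Z95_WIDTH
    feasible = 0.0 < base < 1.0 and sd * sd < base * (1.0 - base)
    if feasible:
        nu = base * (1.0 - base) / (sd * sd) - 1.0
        if nu > 0:
            return DistributionSpec(
                parameter_name=param_name,
                family="beta",
                alpha=base * nu,
                beta_=(1.0 - base) * nu,
            )
    warnings.warn(
        f"{param_name}: beta moment matching infeasible for base {base}, "
        f"range [{range_.low}, {range_.high}]; falling back to triangular",
        stacklevel=2,
    )
    return DistributionSpec(
        parameter_name=param_name,
        family="triangular",
        minimum=range_.low,
        mode=base,
        maximum=range_.high,
    )


class ModelConfig:
    """A loaded configuration: base values, DSA ranges, PSA distributions.

    ``ranges`` holds a :class:`SensitivityRange` for every parameter the
    config gives a range; ``distributions`` holds a :class:`DistributionSpec`
    for every parameter the config assigns a distribution family.
    """

    def __init__(
        self,
        params: ParameterSet,
        ranges: Mapping[str, SensitivityRange],
        distributions: Mapping[str, DistributionSpec],
    ) -> None:
        self.params = params
        self.ranges = dict(ranges)
        self.distributions = dict(distributions)

    def iter_ranges(self) -> Iterator[SensitivityRange]:
        return iter(self.ranges.values())

    def iter_distributions(self) -> Iterator[DistributionSpec]:
        return iter(self.distributions.values())


def default_config_path() -> Path:
    """Path of the packaged base-case configuration."""
    return Path(resources.files("pphcea").joinpath("data/default_parameters.yaml"))


def _read_config(source: Union[None, str, Path, Mapping[str, Any]]) -> dict:
    if source is None:
        source = default_config_path()
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
    if "parameters" not in raw:
        raise ConfigError("config is missing the 'parameters' section")
    return raw["parameters"]


def load_parameters(
    config_source: Union[None, str, Path, Mapping[str, Any]] = None,
) -> ParameterSet:
    """Load and validate a :class:`ParameterSet`.

    ``config_source`` may be a YAML/JSON-style mapping, a path to a YAML
    file, or ``None`` for the packaged base-case config. Raises
    :class:`ConfigError` naming the first missing field, or a pydantic
    ``ValidationError`` for out-of-domain values.
    """
    entries = _read_config(config_source)
    values: dict[str, float] = {}
    for name in ParameterSet.model_fields:
        if name not in entries:
            raise ConfigError(f"missing parameter: {name}")
        entry = entries[name]
        values[name] = entry["base"] if isinstance(entry, Mapping) else entry
    return ParameterSet(**values)


def load_config(
    config_source: Union[None, str, Path, Mapping[str, Any]] = None,
) -> ModelConfig:
    """Load the full configuration: base values, ranges and distributions."""
    entries = _read_config(config_source)
    params = load_parameters(config_source)
    ranges: dict[str, SensitivityRange] = {}
    dists: dict[str, DistributionSpec] = {}
    for name, entry in entries.items():
        if not isinstance(entry, Mapping) or "range" not in entry:
            continue
        low, high = entry["range"]
        rng = SensitivityRange(parameter_name=name, low=low, high=high)
        ranges[name] = rng
        family = entry.get("distribution")
        if family is not None:
            dists[name] = build_distribution(
                name, getattr(params, name), rng, family
            )
    return ModelConfig(params, ranges, dists)
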