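"""Model parameters: strata, intake-shift distributions, dose-response, config I/O.

All proportions are stored as fractions in [0, 1]. Percent notation exists
only at the documentation boundary; nothing in the code multiplies or
divides by 100.

The packaged defaults reproduce the published base case: 3% of adult men
and 6% of adult women meeting fiber recommendations, 4.6% constipation
prevalence, 85% responders, a 1.9% prevalence reduction per additional
g/day of fiber, a uniform 9 g/day intake increase among adults not meeting
recommendations, and a 75%/25% prescription/OTC treatment mix at
$10,786.15 and $566.54 per case-year. Population denominators are not part
of the published parameter set; the packaged defaults (240 million adults,
48.5% male; 54 million children aged 5-17) are a documented calibration
choice, not a published value.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    RootModel,
    field_validator,
    model_validator,
)

SCHEMA_VERSION = 1

#: Daily fiber increments (g/day) the model menu offers.
CANONICAL_INCREMENTS = (0.0, 3.0, 5.0, 6.0, 7.5, 8.0, 9.0, 10.0, 15.0)

AgeGroup = Literal["adult", "pediatric"]
PopulationScope = Literal["adult", "pediatric", "all"]


class ConfigError(ValueError):
    """Raised for structural configuration problems (file level, paths)."""


class IntakeShiftDistribution(RootModel[dict[float, float]]):
    """Allocation of a population across daily fiber increments (g/day).

    Keys are nonnegative increments in grams per day; values are population
    fractions that must sum to one. ``{9.0: 1.0}`` means everyone in scope
    raises intake by 9 g/day; ``{0.0: 0.75, 3.0: 0.25}`` means a quarter of
    the population adds 3 g/day and the rest change nothing.
    """

    model_config = ConfigDict(validate_assignment=True)

    @model_validator(mode="after")
    def _check(self) -> "IntakeShiftDistribution":
        if not self.root:
            raise ValueError("shift: at least one increment required")
        for g, frac in self.root.items():
            if g < 0:
                raise ValueError(f"shift: increment {g} g/day is negative")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(
                    f"shift: fraction {frac} for {g} g/day outside [0, 1]"
                )
        total = math.fsum(self.root.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shift: fractions must sum to 1 (got {total!r})")
        return self

    def items(self):
        return self.root.items()

    @property
    def increments(self) -> tuple[float, ...]:
        return tuple(self.root)

    def mean_increment(self) -> float:
        return math.fsum(g * f for g, f in self.root.items())

    def __eq__(self, other) -> bool:  # dict keys may arrive in any order
        if isinstance(other, IntakeShiftDistribution):
            return self.root == other.root
        return NotImplemented

    __hash__ = None


class DoseResponse(BaseModel):
    """Proportional reduction in constipation prevalence per 1 g/day fiber."""

    model_config = ConfigDict(validate_assignment=True)

    per_gram_reduction: float = Field(ge=0.0, le=1.0)


class Stratum(BaseModel):
    """One population segment (sex x age group) and its model parameters.

    ``shift`` optionally overrides the config-level intake-shift
    distribution for this stratum; the packaged defaults use it to give
    children a 6 g/day increase while adults get 9 g/day.

    Note: ``rx_annual_cost >= otc_annual_cost`` happens to hold for the
    packaged defaults but is an empirical fact, not a rule, and is
    deliberately not enforced.
    """

    model_config = ConfigDict(validate_assignment=True)

    label: str
    age_group: Optional[AgeGroup] = None
    population_count: float = Field(ge=0)
    pct_meeting_recs: float = Field(ge=0.0, le=1.0)
    constipation_prev: float = Field(ge=0.0, le=1.0)
    responder_frac: float = Field(ge=0.0, le=1.0)
    rx_frac: float = Field(ge=0.0, le=1.0)
    rx_annual_cost: float = Field(ge=0)
    otc_annual_cost: float = Field(ge=0)
    shift: Optional[IntakeShiftDistribution] = None

    @model_validator(mode="after")
    def _infer_age_group(self) -> "Stratum":
        if self.age_group is None:
            for group in ("adult", "pediatric"):
                if self.label.startswith(group):
                    object.__setattr__(self, "age_group", group)
                    break
            else:
                raise ValueError(
                    f"stratum {self.label!r}: age_group not given and not "
                    "inferrable from the label prefix"
                )
        return self


class ModelConfig(BaseModel):
    """Complete, validated input set for one model run."""

    model_config = ConfigDict(validate_assignment=True)

    schema_version: int = SCHEMA_VERSION
    reporting_year: int = 2012
    population_scope: PopulationScope = "adult"
    dose_response: DoseResponse
    shift: IntakeShiftDistribution
    strata: list[Stratum] = Field(min_length=1)

    @field_validator("strata")
    @classmethod
    def _unique_labels(cls, strata: list[Stratum]) -> list[Stratum]:
        labels = [s.label for s in strata]
        if len(set(labels)) != len(labels):
            raise ValueError(f"strata: duplicate labels in {labels}")
        return strata

    @model_validator(mode="after")
    def _scope_nonempty(self) -> "ModelConfig":
        if not self.strata_in_scope():
            raise ValueError(
                f"population_scope {self.population_scope!r} selects no strata"
            )
        return self

    def strata_in_scope(self) -> list[Stratum]:
        if self.population_scope == "all":
            return list(self.strata)
        return [s for s in self.strata if s.age_group == self.population_scope]

    def stratum(self, label: str) -> Stratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(label)


# --- defaults -------------------------------------------------------------

#: Default population denominators. Not published inputs: chosen once so
#: that the absolute-dollar outputs land on the published figures within
#: rounding, and documented as a calibration.
DEFAULT_ADULT_POPULATION = 240_000_000
DEFAULT_ADULT_MALE_FRACTION = 0.485
DEFAULT_PEDIATRIC_POPULATION = 54_000_000

_ADULT_COSTS = dict(rx_frac=0.75, rx_annual_cost=10_786.15, otc_annual_cost=566.54)
# Pediatric OTC cost defaults to the adult OTC cost (treated as equivalent);
# it is inert while rx_frac is 1.0 but kept so the mix can be varied.
_PED_COSTS = dict(rx_frac=1.0, rx_annual_cost=3_032.97, otc_annual_cost=566.54)


def default_base_case(scope: PopulationScope = "adult") -> ModelConfig:
    """The packaged base case.

    Adults get a uniform 9 g/day intake increase; children (5-17) a uniform
    6 g/day increase via a per-stratum shift. ``scope`` selects which strata
    the model evaluates; all four strata are always present so scenario
    overrides can address any of them.
    """
    male = DEFAULT_ADULT_POPULATION * DEFAULT_ADULT_MALE_FRACTION
    female = DEFAULT_ADULT_POPULATION - male
    ped_shift = IntakeShiftDistribution({6.0: 1.0})
    strata = [
        Stratum(
            label="adult_male", population_count=male,
            pct_meeting_recs=0.03, constipation_prev=0.046,
            responder_frac=0.85, **_ADULT_COSTS,
        ),
        Stratum(
            label="adult_female", population_count=female,
            pct_meeting_recs=0.06, constipation_prev=0.046,
            responder_frac=0.85, **_ADULT_COSTS,
        ),
        Stratum(
            label="pediatric_male", population_count=DEFAULT_PEDIATRIC_POPULATION / 2,
            pct_meeting_recs=0.03, constipation_prev=0.046,
            responder_frac=0.85, shift=ped_shift, **_PED_COSTS,
        ),
        Stratum(
            label="pediatric_female", population_count=DEFAULT_PEDIATRIC_POPULATION / 2,
            pct_meeting_recs=0.03, constipation_prev=0.046,
            responder_frac=0.85, shift=ped_shift, **_PED_COSTS,
        ),
    ]
    return ModelConfig(
        population_scope=scope,
        dose_response=DoseResponse(per_gram_reduction=0.019),
        shift=IntakeShiftDistribution({9.0: 1.0}),
        strata=strata,
    )


# --- serialization --------------------------------------------------------

def _to_dict(cfg: ModelConfig) -> dict:
    d = cfg.model_dump(exclude_none=True)
    d["shift"] = dict(cfg.shift.root)
    for raw, s in zip(d["strata"], cfg.strata):
        if s.shift is not None:
            raw["shift"] = dict(s.shift.root)
    return d


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it losslessly."""
    Path(path).write_text(
        yaml.safe_dump(_to_dict(cfg), sort_keys=False, default_flow_style=False)
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    Raises :class:`ConfigError` for file-level problems and pydantic's
    ``ValidationError`` (naming the offending field) for invariant
    violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    return ModelConfig.model_validate(raw)


def packaged_config_path(name: str) -> Path:
    """Path of a config file shipped with the package (e.g. ``base_case``)."""
    return Path(resources.files("fibersavings").joinpath(f"data/{name}.yaml"))
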