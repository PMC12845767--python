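"""Model parameterisation: scenario settings and input parameter tables.

The exposure model is fully specified by five parameter blocks —
environmental concentrations, soil-to-crop transfer factors, food/water
intakes, anthropometrics and toxicity reference values — plus a scenario
configuration (inorganic-arsenic fraction for terrestrial foods, iteration
count, seed).  All blocks are pydantic models so invalid configurations
fail loudly with field paths, and all round-trip through YAML.

The shipped default configuration encodes the post-eruption Taal study
inputs: well-water, soil, lake-water and clam arsenic ranges, literature
bioaccumulation/transfer factors, Philippine national food-consumption and
anthropometric survey values, and the US EPA oral toxicity values for
inorganic arsenic.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .distributions import DistributionSpec, Family

__all__ = [
    "CROPS",
    "FOODS",
    "ScenarioConfig",
    "EnvironmentalInputs",
    "TransferFactorTable",
    "IntakeParams",
    "AnthropometricParams",
    "RiskParams",
    "ModelParameters",
    "load_default_config",
    "load_config",
    "config_hash",
]

#: Terrestrial crops modelled through soil-to-crop transfer factors.
CROPS = ("rice", "corn", "vegetables", "root_crops")

#: All foods with a dietary intake distribution.
FOODS = ("fish", "clam", "rice", "corn", "vegetables", "root_crops")

#: Fraction of total arsenic assumed inorganic in terrestrial crops.
SCENARIO_TERRESTRIAL_FRACTION = {"LB": 0.5, "UB": 0.9}


class ScenarioConfig(BaseModel):
    """One Monte Carlo scenario.

    ``terrestrial_iAs_fraction`` is the assumed inorganic share of total
    arsenic in terrestrial crops: 0.5 for the lower-bound (LB) scenario and
    0.9 for the upper-bound (UB) scenario.
    """

    model_config = ConfigDict(extra="forbid")

    scenario_id: Literal["LB", "UB"]
    terrestrial_iAs_fraction: Optional[float] = Field(default=None, gt=0, le=1)
    n_iterations: int = Field(default=10_000, ge=1)
    random_seed: int = 0
    subgroup_modifiers: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _default_fraction(self) -> "ScenarioConfig":
        if self.terrestrial_iAs_fraction is None:
            self.terrestrial_iAs_fraction = SCENARIO_TERRESTRIAL_FRACTION[
                self.scenario_id
            ]
        if self.subgroup_modifiers is not None:
            for food, mult in self.subgroup_modifiers.items():
                if food not in FOODS:
                    raise ValueError(f"unknown food in subgroup_modifiers: {food!r}")
                if mult < 0:
                    raise ValueError(f"subgroup multiplier for {food!r} must be >= 0")
        return self

    @classmethod
    def lower_bound(cls, **kw) -> "ScenarioConfig":
        return cls(scenario_id="LB", **kw)

    @classmethod
    def upper_bound(cls, **kw) -> "ScenarioConfig":
        return cls(scenario_id="UB", **kw)


def _expect_units(spec: DistributionSpec, units: str, field: str) -> DistributionSpec:
    if spec.units != units:
        raise ValueError(f"{field} must have units {units!r}, got {spec.units!r}")
    return spec


class EnvironmentalInputs(BaseModel):
    """Sampling distributions for every environmental arsenic input."""

    model_config = ConfigDict(extra="forbid")

    water_As: DistributionSpec  # total As in drinking water, mg/L
    soil_As: DistributionSpec  # total As in agricultural soil, mg/kg
    lake_As: DistributionSpec  # total As in lake water, mg/L
    clam_total_As_dw: DistributionSpec  # total As in clam tissue, mg/kg dw
    BAF: DistributionSpec  # water-to-fish bioaccumulation factor, L/kg
    dry_season_multiplier: DistributionSpec  # dimensionless
    aquatic_iAs_fraction: DistributionSpec  # inorganic share in fish/clam

    @model_validator(mode="after")
    def _check(self) -> "EnvironmentalInputs":
        _expect_units(self.water_As, "mg/L", "water_As")
        _expect_units(self.soil_As, "mg/kg", "soil_As")
        _expect_units(self.lake_As, "mg/L", "lake_As")
        _expect_units(self.clam_total_As_dw, "mg/kg", "clam_total_As_dw")
        _expect_units(self.BAF, "L/kg", "BAF")
        lo, hi = self.aquatic_iAs_fraction.support
        if lo < 0.117 - 1e-12 or hi > 0.142 + 1e-12:
            raise ValueError(
                "aquatic_iAs_fraction support must lie within [0.117, 0.142], "
                f"got [{lo}, {hi}]"
            )
        for name in ("water_As", "soil_As", "lake_As", "clam_total_As_dw"):
            if getattr(self, name).support[0] < 0:
                raise ValueError(f"{name} support must be non-negative")
        return self


class TransferFactorTable(BaseModel):
    """Dimensionless soil-to-crop transfer factors per crop."""

    model_config = ConfigDict(extra="forbid")

    factors: dict[str, DistributionSpec]

    @model_validator(mode="after")
    def _check(self) -> "TransferFactorTable":
        missing = set(CROPS) - set(self.factors)
        if missing:
            raise ValueError(f"missing transfer factors for: {sorted(missing)}")
        unknown = set(self.factors) - set(CROPS)
        if unknown:
            raise ValueError(f"unknown crops: {sorted(unknown)}")
        for crop, spec in self.factors.items():
            if spec.support[0] < 0:
                raise ValueError(f"transfer factor for {crop!r} must be non-negative")
        return self

    def __getitem__(self, crop: str) -> DistributionSpec:
        if crop not in self.factors:
            raise KeyError(f"unknown crop: {crop!r}")
        return self.factors[crop]


class IntakeParams(BaseModel):
    """Daily food intakes (g/day) and the fixed drinking-water intake."""

    model_config = ConfigDict(extra="forbid")

    foods: dict[str, DistributionSpec]
    water_intake_L_day: float = Field(default=1.791, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "IntakeParams":
        missing = set(FOODS) - set(self.foods)
        if missing:
            raise ValueError(f"missing intake distributions for: {sorted(missing)}")
        unknown = set(self.foods) - set(FOODS)
        if unknown:
            raise ValueError(f"unknown foods: {sorted(unknown)}")
        for food, spec in self.foods.items():
            if spec.support[0] < 0:
                raise ValueError(f"intake for {food!r} must be non-negative")
            if spec.family is Family.truncated_normal:
                # convention: intakes bounded at 0 and ~mean + 3 SD (the cap
                # tolerance absorbs rounding in published tables)
                if spec.lo != 0:
                    raise ValueError(f"intake for {food!r} must have lo = 0")
                cap = spec.mean + 3 * spec.sd
                if abs(spec.hi - cap) > 0.005 * cap:
                    raise ValueError(
                        f"intake cap for {food!r} should be mean + 3*sd "
                        f"(~{cap:g}), got {spec.hi:g}"
                    )
        return self

    def __getitem__(self, food: str) -> DistributionSpec:
        if food not in self.foods:
            raise KeyError(f"unknown food: {food!r}")
        return self.foods[food]


class AnthropometricParams(BaseModel):
    """Sex split plus per-sex body weight and height distributions."""

    model_config = ConfigDict(extra="forbid")

    sex_proportion_male: float = Field(default=0.506, ge=0, le=1)
    male_body_weight: DistributionSpec
    female_body_weight: DistributionSpec
    male_height: DistributionSpec
    female_height: DistributionSpec

    @model_validator(mode="after")
    def _check(self) -> "AnthropometricParams":
        for name in ("male_body_weight", "female_body_weight"):
            _expect_units(getattr(self, name), "kg", name)
        for name in ("male_height", "female_height"):
            _expect_units(getattr(self, name), "cm", name)
        return self


class RiskParams(BaseModel):
    """Oral toxicity reference values for inorganic arsenic.

    ``rfd`` — reference dose (µg/kg-day) below which non-cancer effects are
    not expected; ``csf`` — linear cancer slope factor ((µg/kg-day)^-1).
    """

    model_config = ConfigDict(extra="forbid")

    rfd: float = Field(default=0.06, gt=0)
    csf: float = Field(default=0.032, gt=0)


class ModelParameters(BaseModel):
    """Bundle of the five parameter blocks that define the model."""

    model_config = ConfigDict(extra="forbid")

    environmental: EnvironmentalInputs
    transfer_factors: TransferFactorTable
    intakes: IntakeParams
    anthropometrics: AnthropometricParams
    risk: RiskParams


def load_config(path: str | Path) -> ModelParameters:
    """Load and validate a model configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return ModelParameters.model_validate(raw)


def load_default_config() -> ModelParameters:
    """The shipped default parameterisation (post-eruption Taal inputs)."""
    ref = resources.files("iasrisk").joinpath("data/default_config.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


def config_hash(params: ModelParameters) -> str:
    """Stable sha256 of a canonical JSON dump of the parameters."""
    dump = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(dump.encode("utf-8")).hexdigest()
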