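"""Declarative sampling distributions and reproducible random streams.

Every stochastic input to the exposure model (environmental concentrations,
transfer factors, food intakes, anthropometrics) is described by a
:class:`DistributionSpec` — a validated, serialisable record of a
distribution family, its parameters and its physical units.  Four families
cover everything the model needs:

``point``
    A degenerate distribution (fixed parameter, e.g. drinking-water intake).
``uniform``
    Maximum-entropy choice when only a bounded range is known (soil and
    lake-water arsenic, transfer factors, bioaccumulation factor).
``truncated_normal``
    Mean/SD with hard plausibility bounds (food intakes, body weight,
    height, the dry-season concentration factor, clam tissue arsenic).
``lognormal``
    Right-skewed environmental concentrations (well-water arsenic),
    parameterised by geometric mean and log-scale sigma, optionally
    calibrated from a printed min–max range.

Random streams are keyed by *name*: each input variable draws from an
independent child generator derived from one master seed, so adding or
removing a variable never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
import math
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy import stats

__all__ = [
    "Family",
    "DistributionSpec",
    "UNIT_WHITELIST",
    "sample_distribution",
    "truncated_normal_mean",
    "calibrate_lognormal_from_range",
    "child_rng",
    "spawn_seed",
]

#: Units accepted on a DistributionSpec.  Micro signs are normalised to "u".
UNIT_WHITELIST = frozenset(
    {
        "mg/L",
        "mg/kg",
        "ug/g",
        "ug/L",
        "g/day",
        "L/day",
        "L/kg",
        "kg",
        "cm",
        "dimensionless",
    }
)


class Family(str, Enum):
    point = "point"
    uniform = "uniform"
    truncated_normal = "truncated_normal"
    lognormal = "lognormal"


def _normalise_units(units: str) -> str:
    return units.replace("µ", "u").replace("μ", "u")


class DistributionSpec(BaseModel):
    """A sampling distribution with units.

    Family-specific parameters:

    - ``point``: ``value``
    - ``uniform``: ``lo``, ``hi``
    - ``truncated_normal``: ``mean``, ``sd``, ``lo``, ``hi``
    - ``lognormal``: ``geometric_mean``, ``sigma_log``; when instead
      ``lo``/``hi`` (and optionally ``coverage``) are given, the parameters
      are calibrated so the central ``coverage`` interval spans ``(lo, hi)``
      (see :func:`calibrate_lognormal_from_range`).  ``lo``/``hi`` on a
      lognormal record the calibration range; they do not truncate.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    family: Family
    units: str = "dimensionless"
    value: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    geometric_mean: Optional[float] = None
    sigma_log: Optional[float] = None
    coverage: Optional[float] = None

    @field_validator("units")
    @classmethod
    def _check_units(cls, v: str) -> str:
        norm = _normalise_units(v)
        if norm not in UNIT_WHITELIST:
            raise ValueError(
                f"unknown units {v!r}; allowed: {sorted(UNIT_WHITELIST)}"
            )
        return norm

    @model_validator(mode="after")
    def _check_family_params(self) -> "DistributionSpec":
        f = self.family
        if f is Family.point:
            if self.value is None:
                raise ValueError("point distribution requires 'value'")
        elif f is Family.uniform:
            if self.lo is None or self.hi is None:
                raise ValueError("uniform distribution requires 'lo' and 'hi'")
            if self.lo > self.hi:
                raise ValueError(f"lo ({self.lo}) must be <= hi ({self.hi})")
        elif f is Family.truncated_normal:
            for name in ("mean", "sd", "lo", "hi"):
                if getattr(self, name) is None:
                    raise ValueError(f"truncated_normal requires '{name}'")
            if self.sd <= 0:
                raise ValueError(f"sd must be > 0, got {self.sd}")
            if self.lo > self.hi:
                raise ValueError(f"lo ({self.lo}) must be <= hi ({self.hi})")
        elif f is Family.lognormal:
            if self.geometric_mean is None:
                if self.lo is None or self.hi is None:
                    raise ValueError(
                        "lognormal requires 'geometric_mean'/'sigma_log' or a "
                        "'lo'/'hi' calibration range"
                    )
                calibrated = calibrate_lognormal_from_range(
                    self.lo,
                    self.hi,
                    coverage=self.coverage if self.coverage is not None else 0.95,
                    units=self.units,
                )
                object.__setattr__(self, "geometric_mean", calibrated.geometric_mean)
                object.__setattr__(self, "sigma_log", calibrated.sigma_log)
                object.__setattr__(self, "coverage", calibrated.coverage)
            if self.geometric_mean <= 0:
                raise ValueError(
                    f"geometric_mean must be > 0, got {self.geometric_mean}"
                )
            if self.sigma_log is None or self.sigma_log < 0:
                raise ValueError(f"sigma_log must be >= 0, got {self.sigma_log}")
        return self

    # -- queries ---------------------------------------------------------

    @property
    def support(self) -> tuple[float, float]:
        """Hard bounds respected by every draw (inf where unbounded)."""
        if self.family is Family.point:
            return (self.value, self.value)
        if self.family in (Family.uniform, Family.truncated_normal):
            return (self.lo, self.hi)
        return (0.0, math.inf)

    def analytic_mean(self) -> float:
        """Expected value of the distribution (closed form per family)."""
        if self.family is Family.point:
            return self.value
        if self.family is Family.uniform:
            return 0.5 * (self.lo + self.hi)
        if self.family is Family.truncated_normal:
            return truncated_normal_mean(self.mean, self.sd, self.lo, self.hi)
        return self.geometric_mean * math.exp(0.5 * self.sigma_log**2)

    def quantile(self, q) -> np.ndarray | float:
        if self.family is Family.point:
            return np.broadcast_to(self.value, np.shape(q)).astype(float) if np.ndim(q) else self.value
        if self.family is Family.uniform:
            return stats.uniform.ppf(q, loc=self.lo, scale=self.hi - self.lo)
        if self.family is Family.truncated_normal:
            a = (self.lo - self.mean) / self.sd
            b = (self.hi - self.mean) / self.sd
            return stats.truncnorm.ppf(q, a, b, loc=self.mean, scale=self.sd)
        return stats.lognorm.ppf(q, s=self.sigma_log, scale=self.geometric_mean)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_distribution(self, n, rng)


def sample_distribution(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``spec`` using the generator ``rng``.

    Draws are reproducible: the same generator state yields bit-identical
    output, and every value respects the spec's hard bounds.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    f = spec.family
    if f is Family.point:
        return np.full(n, float(spec.value))
    if f is Family.uniform:
        return rng.uniform(spec.lo, spec.hi, size=n)
    if f is Family.truncated_normal:
        a = (spec.lo - spec.mean) / spec.sd
        b = (spec.hi - spec.mean) / spec.sd
        return stats.truncnorm.rvs(
            a, b, loc=spec.mean, scale=spec.sd, size=n, random_state=rng
        )
    if f is Family.lognormal:
        if spec.sigma_log == 0:
            return np.full(n, float(spec.geometric_mean))
        return rng.lognormal(
            mean=math.log(spec.geometric_mean), sigma=spec.sigma_log, size=n
        )
    raise ValueError(f"unknown distribution family: {spec.family!r}")


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Analytic mean of a normal(mean, sd) truncated to [lo, hi].

    Uses the standard closed form
    ``mean + sd * (phi(a) - phi(b)) / (Phi(b) - Phi(a))`` with
    ``a = (lo - mean)/sd`` and ``b = (hi - mean)/sd``.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if not lo < hi:
        raise ValueError(f"degenerate interval: lo ({lo}) must be < hi ({hi})")
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def calibrate_lognormal_from_range(
    lo: float,
    hi: float,
    coverage: float = 0.95,
    units: str = "dimensionless",
) -> DistributionSpec:
    """Build a lognormal whose central ``coverage`` interval is ``(lo, hi)``.

    The geometric mean is the geometric midpoint ``sqrt(lo*hi)`` and the
    log-scale sigma is ``ln(hi/gm) / z`` with ``z`` the standard-normal
    quantile of ``(1+coverage)/2``, so by construction
    ``quantile((1-coverage)/2) == lo`` and ``quantile((1+coverage)/2) == hi``.

    This is how a printed concentration range is turned into a full
    sampling distribution.  ``coverage`` encodes how the range is read: a
    stated 95% interval uses 0.95, while the min–max of ``n`` field samples
    is best read with Hazen plotting positions, ``coverage = 1 - 1/n``.
    """
    if lo <= 0:
        raise ValueError(f"lo must be > 0 for a lognormal, got {lo}")
    if not lo < hi:
        raise ValueError(f"lo ({lo}) must be < hi ({hi})")
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    gm = math.sqrt(lo * hi)
    z = float(stats.norm.ppf(0.5 * (1.0 + coverage)))
    sigma = math.log(hi / gm) / z
    return DistributionSpec(
        family=Family.lognormal,
        geometric_mean=gm,
        sigma_log=sigma,
        lo=lo,
        hi=hi,
        coverage=coverage,
        units=units,
    )


# -- named child streams -------------------------------------------------


def spawn_seed(master_seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for the named child stream of ``master_seed``.

    The child key is a stable hash of ``name``, so streams for different
    variables are statistically independent and adding a new named variable
    leaves existing streams untouched.
    """
    key = int.from_bytes(hashlib.sha256(name.encode("utf-8")).digest()[:8], "little")
    return np.random.SeedSequence(entropy=(int(master_seed), key))


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Independent generator for the named input variable."""
    return np.random.default_rng(spawn_seed(master_seed, name))
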