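"""Synthetic field-measurement tables and input calibration from them.

``generate_field_tables`` produces raw-looking measurement tables
(sample_id, medium, value, units, site_label) with the statistical
structure of the study inputs: 72 right-skewed well-water total-As values
within 0.000735–0.11 mg/L, plus soil, lake-water and clam values inside
their respective survey ranges.  The values are synthetic draws from the
model's own input distributions — a stand-in for unpublished raw field
data, not the original measurements.

``fit_inputs_from_tables`` closes the loop: it reads per-medium ranges off
such a table and rebuilds an :class:`EnvironmentalInputs` block, using the
same conventions as the shipped default configuration (lognormal range
calibration for well water with Hazen coverage 1 - 1/n; uniform over the
observed range for soil and lake water; fixed-SD truncated normal for
clams).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import EnvironmentalInputs
from .distributions import (
    DistributionSpec,
    calibrate_lognormal_from_range,
    child_rng,
)

__all__ = ["generate_field_tables", "fit_inputs_from_tables", "write_field_tables"]

REQUIRED_MEDIA = ("well_water", "soil", "lake_water", "clam")

_MEDIUM_UNITS = {
    "well_water": "mg/L",
    "soil": "mg/kg",
    "lake_water": "mg/L",
    "clam": "mg/kg",
}

# survey ranges emulated by the generator
_WELL_RANGE = (0.000735, 0.11)
_SOIL_RANGE = (1.92, 7.91)
_LAKE_RANGE = (0.005, 0.0097)
_CLAM_RANGE = (5.0, 6.3)

_CLAM_SD_CONVENTION = 3.0  # fixed tissue-As SD used by the exposure model


def generate_field_tables(
    seed: int = 0,
    n_well: int = 72,
    n_soil: int = 6,
    n_lake: int = 6,
    n_clam: int = 6,
) -> pd.DataFrame:
    """Deterministically generate one synthetic field-measurement table.

    Well-water values are drawn from the range-calibrated lognormal,
    truncated to the survey range by inverse-CDF sampling between the
    range quantiles, so the fit/calibrate round trip is self-consistent.
    Soil, lake and clam values are uniform within their survey ranges.
    """
    frames = []

    water_spec = calibrate_lognormal_from_range(
        *_WELL_RANGE, coverage=1 - 1 / n_well, units="mg/L"
    )
    rng = child_rng(seed, "fixture_well_water")
    q_lo = 0.5 / n_well
    q_hi = 1 - 0.5 / n_well
    u = rng.uniform(q_lo, q_hi, size=n_well)
    well = np.asarray(water_spec.quantile(u))
    frames.append(("well_water", well))

    for medium, (lo, hi), n in (
        ("soil", _SOIL_RANGE, n_soil),
        ("lake_water", _LAKE_RANGE, n_lake),
        ("clam", _CLAM_RANGE, n_clam),
    ):
        vals = child_rng(seed, f"fixture_{medium}").uniform(lo, hi, size=n)
        frames.append((medium, vals))

    rows = []
    for medium, values in frames:
        prefix = medium[0].upper()
        for i, v in enumerate(values):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:03d}",
                    "medium": medium,
                    "value": float(v),
                    "units": _MEDIUM_UNITS[medium],
                    "site_label": f"site_{i % 3 + 1}",
                }
            )
    return pd.DataFrame(rows)


def fit_inputs_from_tables(
    tables: pd.DataFrame,
    defaults: EnvironmentalInputs | None = None,
) -> EnvironmentalInputs:
    """Calibrate environmental input distributions from a field table.

    Ranges are the per-medium min/max.  BAF, the dry-season factor and
    the aquatic iAs fraction are not field-measurable from such tables and
    are taken from ``defaults`` (the shipped configuration if omitted).
    """
    missing = [m for m in REQUIRED_MEDIA if m not in set(tables["medium"])]
    if missing:
        raise ValueError(f"missing media in field tables: {missing}")

    ranges: dict[str, tuple[float, float, int]] = {}
    for medium in REQUIRED_MEDIA:
        vals = tables.loc[tables["medium"] == medium, "value"].to_numpy(float)
        if np.any(vals <= 0):
            raise ValueError(f"non-positive values in medium {medium!r}")
        lo, hi = float(vals.min()), float(vals.max())
        if not lo < hi:
            raise ValueError(
                f"degenerate range for medium {medium!r}: need at least two "
                f"distinct values, got [{lo}, {hi}]"
            )
        ranges[medium] = (lo, hi, vals.size)

    if defaults is None:
        from .config import load_default_config

        defaults = load_default_config().environmental

    w_lo, w_hi, w_n = ranges["well_water"]
    clam_lo, clam_hi, _ = ranges["clam"]
    clam_mean = float(
        tables.loc[tables["medium"] == "clam", "value"].mean()
    )
    clam_sd = _CLAM_SD_CONVENTION
    return EnvironmentalInputs(
        water_As=calibrate_lognormal_from_range(
            w_lo, w_hi, coverage=1 - 1 / w_n, units="mg/L"
        ),
        soil_As=DistributionSpec(
            family="uniform", lo=ranges["soil"][0], hi=ranges["soil"][1],
            units="mg/kg",
        ),
        lake_As=DistributionSpec(
            family="uniform", lo=ranges["lake_water"][0],
            hi=ranges["lake_water"][1], units="mg/L",
        ),
        clam_total_As_dw=DistributionSpec(
            family="truncated_normal", mean=clam_mean, sd=clam_sd,
            lo=0.0, hi=clam_mean + 3 * clam_sd, units="mg/kg",
        ),
        BAF=defaults.BAF,
        dry_season_multiplier=defaults.dry_season_multiplier,
        aquatic_iAs_fraction=defaults.aquatic_iAs_fraction,
    )


def write_field_tables(tables: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write the synthetic table to ``out_dir/field_measurements.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "field_measurements.csv"
    tables.to_csv(path, index=False)
    return path
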