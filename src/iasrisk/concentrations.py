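"""Reconstruction of inorganic-arsenic concentrations per exposure medium.

Measured data give *total* arsenic in environmental media (well water,
soil, lake water, clam tissue).  Edible-medium inorganic-arsenic (iAs)
concentrations are reconstructed per Monte Carlo iteration:

- fish:   lake water (mg/L) x BAF (L/kg) x seasonal factor x aquatic iAs
          fraction, where the seasonal factor is 1 in the rainy season and
          a truncated-normal draw in the dry season;
- clam:   tissue total As (mg/kg dw) x the same aquatic iAs fraction draw;
- crops:  soil As (mg/kg) x crop transfer factor x scenario terrestrial
          iAs fraction (0.5 LB / 0.9 UB); one soil draw per iteration is
          shared across all four crops (one soil environment per simulated
          individual);
- water:  well-water total As (mg/L -> µg/L); total As is used directly
          (iAs fraction 1).

mg/kg and µg/g are numerically identical, so food columns are in µg/g
without conversion; the water column is in µg/L.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .config import CROPS, EnvironmentalInputs, ScenarioConfig, TransferFactorTable
from .distributions import child_rng

__all__ = [
    "FOOD_COLUMNS",
    "AUX_COLUMNS",
    "fish_iAs",
    "reconstruct_fish_iAs",
    "reconstruct_clam_iAs",
    "reconstruct_crop_iAs",
    "sample_drinking_water_iAs",
    "build_concentration_table",
    "concentration_units",
    "write_concentration_csv",
]

FOOD_COLUMNS = ("fish", "clam", "rice", "corn", "vegetables", "root_crops")

AUX_COLUMNS = (
    "water_total_As",
    "soil_As",
    "lake_As",
    "clam_total_As",
    "BAF",
    "dry_season_multiplier",
    "season",
    "aquatic_iAs_fraction",
    "TF_rice",
    "TF_corn",
    "TF_vegetables",
    "TF_root",
)


def _check_season_flags(flags: np.ndarray) -> np.ndarray:
    flags = np.asarray(flags)
    if flags.dtype.kind == "b":
        return flags  # True == dry
    bad = set(np.unique(flags)) - {"rainy", "dry"}
    if bad:
        raise ValueError(f"season flags must be 'rainy' or 'dry', got {sorted(bad)}")
    return flags == "dry"


def fish_iAs(
    lake_As: np.ndarray,
    baf: np.ndarray,
    aquatic_fraction: np.ndarray,
    dry_multiplier: np.ndarray,
    season_flags: np.ndarray,
) -> np.ndarray:
    """Combine already-sampled factors into fish iAs (µg/g), row-wise."""
    dry = _check_season_flags(season_flags)
    mult = np.where(dry, dry_multiplier, 1.0)
    return np.asarray(lake_As) * np.asarray(baf) * mult * np.asarray(aquatic_fraction)


def reconstruct_fish_iAs(
    env: EnvironmentalInputs,
    season_flags: Iterable,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the fish chain for ``n`` iterations; returns µg/g.

    Rainy-season rows use seasonal factor 1; dry rows multiply by a draw
    from the dry-season distribution.
    """
    flags = np.asarray(list(season_flags) if not isinstance(season_flags, np.ndarray) else season_flags)
    if flags.shape[0] != n:
        raise ValueError(f"season_flags must have length n={n}, got {flags.shape[0]}")
    lake = env.lake_As.sample(n, rng)
    baf = env.BAF.sample(n, rng)
    mult = env.dry_season_multiplier.sample(n, rng)
    frac = env.aquatic_iAs_fraction.sample(n, rng)
    return fish_iAs(lake, baf, frac, mult, flags)


def reconstruct_clam_iAs(
    env: EnvironmentalInputs, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Clam iAs (µg/g): tissue total As draw x aquatic iAs fraction draw."""
    total = env.clam_total_As_dw.sample(n, rng)
    frac = env.aquatic_iAs_fraction.sample(n, rng)
    return total * frac


def reconstruct_crop_iAs(
    crop: str,
    env: EnvironmentalInputs,
    tf: TransferFactorTable,
    scenario: ScenarioConfig,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Crop iAs (µg/g): soil As x transfer factor x terrestrial iAs fraction."""
    if crop not in CROPS:
        raise KeyError(f"unknown crop: {crop!r}")
    soil = env.soil_As.sample(n, rng)
    factor = tf[crop].sample(n, rng)
    return soil * factor * scenario.terrestrial_iAs_fraction


def sample_drinking_water_iAs(
    env: EnvironmentalInputs, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Drinking-water iAs (µg/L); total As is used directly (fraction 1)."""
    return env.water_As.sample(n, rng) * 1000.0


_TF_COL = {"rice": "TF_rice", "corn": "TF_corn", "vegetables": "TF_vegetables",
           "root_crops": "TF_root"}


def build_concentration_table(
    env: EnvironmentalInputs,
    tf: TransferFactorTable,
    scenario: ScenarioConfig,
    n: int | None = None,
    seed: int | None = None,
    p_dry: float = 0.5,
) -> pd.DataFrame:
    """Sample all environmental primitives and reconstruct every medium.

    One named child stream per input variable (keyed off the scenario's
    master seed), so the environmental draws are identical between LB and
    UB runs with the same seed — the scenarios differ only in the
    terrestrial iAs fraction.  Each simulated individual is assigned a
    rainy or dry season with probability ``p_dry`` of dry.

    Returns a DataFrame with reconstructed food columns (µg/g), the
    drinking-water column (µg/L), and all sampled auxiliary columns.
    """
    n = scenario.n_iterations if n is None else n
    seed = scenario.random_seed if seed is None else seed

    draws = {
        "water_total_As": env.water_As.sample(n, child_rng(seed, "water_As")),
        "soil_As": env.soil_As.sample(n, child_rng(seed, "soil_As")),
        "lake_As": env.lake_As.sample(n, child_rng(seed, "lake_As")),
        "clam_total_As": env.clam_total_As_dw.sample(
            n, child_rng(seed, "clam_total_As")
        ),
        "BAF": env.BAF.sample(n, child_rng(seed, "BAF")),
        "dry_season_multiplier": env.dry_season_multiplier.sample(
            n, child_rng(seed, "dry_season_multiplier")
        ),
        "aquatic_iAs_fraction": env.aquatic_iAs_fraction.sample(
            n, child_rng(seed, "aquatic_iAs_fraction")
        ),
    }
    for crop in CROPS:
        draws[_TF_COL[crop]] = tf[crop].sample(n, child_rng(seed, _TF_COL[crop]))

    dry = child_rng(seed, "season").random(n) < p_dry
    table = pd.DataFrame(draws)
    table["season"] = np.where(dry, "dry", "rainy")

    table["fish"] = fish_iAs(
        table["lake_As"].to_numpy(),
        table["BAF"].to_numpy(),
        table["aquatic_iAs_fraction"].to_numpy(),
        table["dry_season_multiplier"].to_numpy(),
        dry,
    )
    table["clam"] = table["clam_total_As"] * table["aquatic_iAs_fraction"]
    frac = scenario.terrestrial_iAs_fraction
    for crop in CROPS:
        table[crop] = table["soil_As"] * table[_TF_COL[crop]] * frac
    table["drinking_water"] = table["water_total_As"] * 1000.0

    order = list(FOOD_COLUMNS) + ["drinking_water"] + list(AUX_COLUMNS)
    return table[order]


def concentration_units() -> dict[str, str]:
    units = {c: "ug/g" for c in FOOD_COLUMNS}
    units.update(
        drinking_water="ug/L",
        water_total_As="mg/L",
        soil_As="mg/kg",
        lake_As="mg/L",
        clam_total_As="mg/kg",
        BAF="L/kg",
        dry_season_multiplier="dimensionless",
        season="flag",
        aquatic_iAs_fraction="dimensionless",
        TF_rice="dimensionless",
        TF_corn="dimensionless",
        TF_vegetables="dimensionless",
        TF_root="dimensionless",
    )
    return units


def write_concentration_csv(table: pd.DataFrame, path) -> None:
    """CSV export with a units row under the header."""
    units = concentration_units()
    unit_row = pd.DataFrame([[units.get(c, "") for c in table.columns]],
                            columns=table.columns)
    out = pd.concat([unit_row, table], ignore_index=True)
    out.to_csv(path, index=False)
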