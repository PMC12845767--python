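"""Simulated population: sex, anthropometrics, food and water intakes.

Each Monte Carlo iteration is one simulated individual.  Sex is a
Bernoulli draw at the census male proportion; body weight and height come
from sex-specific truncated normals; food intakes are independent
truncated-normal draws per food.  Drinking-water intake is a fixed survey
value with no modelled variability.  Height is carried for descriptive
parity with the anthropometric model but enters no dose computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FOODS, AnthropometricParams, IntakeParams
from .distributions import child_rng

__all__ = [
    "INTAKE_COLUMNS",
    "sample_population",
    "apply_subgroup_modifiers",
    "designate_pregnant",
]

INTAKE_COLUMNS = {
    "fish": "intake_fish",
    "clam": "intake_clam",
    "rice": "intake_rice",
    "corn": "intake_corn",
    "vegetables": "intake_vegetables",
    "root_crops": "intake_root",
}


def sample_population(
    n: int,
    anthro: AnthropometricParams,
    intakes: IntakeParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` simulated individuals.

    Named child streams (one per variable) keyed off ``seed`` keep the
    population draws aligned with the concentration draws of the same
    scenario run and independent across variables.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    male = child_rng(seed, "sex").random(n) < anthro.sex_proportion_male

    # draw both sexes full-length from separate streams, then select, so
    # one individual's values do not depend on the sex draws of others
    bw_m = anthro.male_body_weight.sample(n, child_rng(seed, "body_weight_male"))
    bw_f = anthro.female_body_weight.sample(n, child_rng(seed, "body_weight_female"))
    ht_m = anthro.male_height.sample(n, child_rng(seed, "height_male"))
    ht_f = anthro.female_height.sample(n, child_rng(seed, "height_female"))

    pop = pd.DataFrame(
        {
            "sex": np.where(male, "male", "female"),
            "body_weight_kg": np.where(male, bw_m, bw_f),
            "height_cm": np.where(male, ht_m, ht_f),
        }
    )
    for food in FOODS:
        col = INTAKE_COLUMNS[food]
        pop[col] = intakes[food].sample(n, child_rng(seed, col))
    pop["water_intake_L_day"] = intakes.water_intake_L_day
    pop["subgroup"] = "general"
    return pop


def apply_subgroup_modifiers(
    pop: pd.DataFrame,
    modifiers: dict[str, float],
    subgroup_label: str = "pregnant",
) -> pd.DataFrame:
    """Scale the intakes of rows labelled ``subgroup_label``.

    ``modifiers`` maps food name to a non-negative multiplier; foods not
    listed are left unchanged, unknown food names raise.  Returns a new
    table; unflagged rows are untouched.
    """
    unknown = set(modifiers) - set(FOODS)
    if unknown:
        raise KeyError(f"unknown foods in modifiers: {sorted(unknown)}")
    for food, mult in modifiers.items():
        if mult < 0:
            raise ValueError(f"multiplier for {food!r} must be >= 0, got {mult}")
    out = pop.copy()
    mask = out["subgroup"] == subgroup_label
    for food, mult in modifiers.items():
        col = INTAKE_COLUMNS[food]
        out.loc[mask, col] = out.loc[mask, col] * mult
    return out


def designate_pregnant(
    pop: pd.DataFrame,
    proportion: float,
    anthro: AnthropometricParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Label a random fraction of rows as pregnant, with female anthropometrics.

    Selected rows are relabelled ``subgroup='pregnant'``, set to female,
    and their body weight and height redrawn from the female
    distributions.  The intake profile of the subgroup is controlled
    separately via :func:`apply_subgroup_modifiers`; the default profile
    (no modifiers) is exploratory, not a calibrated model of pregnancy.
    """
    if not 0 <= proportion <= 1:
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    out = pop.copy()
    n = len(out)
    rng = child_rng(seed, "pregnant_flag")
    flagged = rng.random(n) < proportion
    idx = out.index[flagged]
    k = len(idx)
    if k:
        out.loc[idx, "subgroup"] = "pregnant"
        out.loc[idx, "sex"] = "female"
        out.loc[idx, "body_weight_kg"] = anthro.female_body_weight.sample(
            k, child_rng(seed, "pregnant_body_weight")
        )
        out.loc[idx, "height_cm"] = anthro.female_height.sample(
            k, child_rng(seed, "pregnant_height")
        )
    return out
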