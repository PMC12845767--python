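"""Non-cancer and cancer risk characterisation.

Hazard quotient: HQ = dose / RfD, with RfD the oral reference dose for
inorganic arsenic (default 0.06 µg/kg-day).  HQ > 1 flags potential
non-cancer concern.

Excess lifetime cancer risk: ECR = dose x CSF, with CSF the oral cancer
slope factor (default 0.032 (µg/kg-day)^-1).  ECR is reported as computed
and not capped at 1; at the doses simulated here it is a linear risk
index rather than a literal probability, and values above ~0.1 should be
read as "far beyond the 1e-6..1e-4 benchmark range" rather than as
calibrated lifetime probabilities.

Exceedance counting uses strict inequality (HQ > threshold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RiskParams

__all__ = [
    "hazard_quotient",
    "excess_cancer_risk",
    "attach_risk",
    "exceedance_summary",
]


def hazard_quotient(dose, risk: RiskParams):
    """HQ = dose / RfD; accepts scalars or arrays."""
    if risk.rfd <= 0:
        raise ValueError(f"RfD must be > 0, got {risk.rfd}")
    return np.asarray(dose, dtype=float) / risk.rfd if np.ndim(dose) else float(dose) / risk.rfd


def excess_cancer_risk(dose, risk: RiskParams):
    """ECR = dose x CSF; accepts scalars or arrays."""
    if risk.csf <= 0:
        raise ValueError(f"CSF must be > 0, got {risk.csf}")
    return np.asarray(dose, dtype=float) * risk.csf if np.ndim(dose) else float(dose) * risk.csf


def attach_risk(doses: pd.DataFrame, risk: RiskParams) -> pd.DataFrame:
    """Per-individual risk table: total dose, HQ and ECR columns."""
    out = pd.DataFrame(index=doses.index)
    out["total_dose"] = doses["total_dose"]
    out["HQ"] = hazard_quotient(doses["total_dose"].to_numpy(), risk)
    out["ECR"] = excess_cancer_risk(doses["total_dose"].to_numpy(), risk)
    for col in ("scenario_id", "sex", "subgroup"):
        if col in doses.columns:
            out[col] = doses[col]
    return out


def exceedance_summary(
    risk_table: pd.DataFrame,
    hq_thresholds=(1.0,),
    ecr_thresholds=(1e-6, 1e-4),
    grid_points: int = 1001,
) -> dict:
    """Exceedance fractions plus empirical CDF grids for HQ and ECR.

    Fractions use strict inequality (value > threshold).  The CDF grid is
    an equally spaced ``grid_points``-point grid from 0 to the sample
    maximum with the empirical CDF evaluated at each point, suitable for
    plotting or export.
    """
    if len(risk_table) == 0:
        raise ValueError("empty risk table")
    for th in (list(hq_thresholds), list(ecr_thresholds)):
        if th != sorted(th):
            raise ValueError("thresholds must be sorted ascending")

    hq = risk_table["HQ"].to_numpy()
    ecr = risk_table["ECR"].to_numpy()

    def cdf_grid(x: np.ndarray) -> pd.DataFrame:
        grid = np.linspace(0.0, float(np.max(x)), grid_points)
        xs = np.sort(x)
        cdf = np.searchsorted(xs, grid, side="right") / x.size
        return pd.DataFrame({"value": grid, "cdf": cdf})

    return {
        "n": int(len(risk_table)),
        "hq_exceedance": {
            str(t): float(np.mean(hq > t)) for t in hq_thresholds
        },
        "ecr_exceedance": {
            str(t): float(np.mean(ecr > t)) for t in ecr_thresholds
        },
        "hq_cdf": cdf_grid(hq),
        "ecr_cdf": cdf_grid(ecr),
    }
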