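"""Global sensitivity analysis of the total dose: SRC and PRCC.

Two complementary measures over the model's 18 sampled input primitives
(4 environmental concentrations, BAF, dry-season factor, aquatic iAs
fraction, 4 crop transfer factors, 6 food intakes, body weight):

SRC — standardized regression coefficients: OLS of the z-scored response
on the z-scored inputs; for a near-linear model with independent inputs
the squared SRCs approximate variance fractions.

PRCC — partial rank correlation coefficients: every column is rank
transformed (average ranks for ties) and, for each input, the correlation
between its ranks and the response ranks is computed controlling for all
other inputs' ranks.  The implementation uses the precision-matrix form
of partial correlation, algebraically identical to correlating the
residuals of the two rank vectors regressed on the remaining columns.
PRCC is invariant under monotone transforms of the inputs.

p-values: SRC from the OLS t statistics (df = n - 19, 18 slopes + an
intercept).  PRCC from t = r * sqrt(df / (1 - r^2)) with df = n - 19
(n minus 2 minus the 17 controlled covariates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "INPUT_COLUMNS",
    "build_design_matrix",
    "src",
    "prcc",
    "sensitivity_analysis",
    "tornado_table",
]

#: The 18 sampled primitives entering the sensitivity analysis.  The binary
#: season flag is excluded (not a continuous input); its multiplier is in.
INPUT_COLUMNS = (
    "water_As",
    "soil_As",
    "lake_As",
    "clam_total_As",
    "BAF",
    "dry_season_multiplier",
    "aquatic_iAs_fraction",
    "TF_rice",
    "TF_corn",
    "TF_vegetables",
    "TF_root",
    "intake_fish",
    "intake_clam",
    "intake_rice",
    "intake_corn",
    "intake_vegetables",
    "intake_root",
    "body_weight",
)

_CONC_SOURCES = {
    "water_As": "water_total_As",
    "soil_As": "soil_As",
    "lake_As": "lake_As",
    "clam_total_As": "clam_total_As",
    "BAF": "BAF",
    "dry_season_multiplier": "dry_season_multiplier",
    "aquatic_iAs_fraction": "aquatic_iAs_fraction",
    "TF_rice": "TF_rice",
    "TF_corn": "TF_corn",
    "TF_vegetables": "TF_vegetables",
    "TF_root": "TF_root",
}


def build_design_matrix(
    conc: pd.DataFrame, pop: pd.DataFrame, doses: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the 18-column input matrix and total-dose response.

    Rows of the three tables must be aligned (same iteration order).
    """
    if not (len(conc) == len(pop) == len(doses)):
        raise ValueError("conc, pop and doses must have equal row counts")
    X = pd.DataFrame(index=doses.index)
    for name, source in _CONC_SOURCES.items():
        X[name] = conc[source].to_numpy()
    for food, col in (
        ("fish", "intake_fish"),
        ("clam", "intake_clam"),
        ("rice", "intake_rice"),
        ("corn", "intake_corn"),
        ("vegetables", "intake_vegetables"),
        ("root_crops", "intake_root"),
    ):
        X[col] = pop[col].to_numpy()
    X["body_weight"] = pop["body_weight_kg"].to_numpy()
    X = X[list(INPUT_COLUMNS)]
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        raise ValueError(f"constant input columns: {constant}")
    y = pd.Series(doses["total_dose"].to_numpy(), index=doses.index, name="total_dose")
    return X, y


def _check_design(X: pd.DataFrame, y: pd.Series) -> None:
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} rows, got {n}")
    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if rank < k:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "rank-deficient design matrix; most collinear columns: "
            f"{X.columns[i]!r}, {X.columns[j]!r}"
        )


def src(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Standardized regression coefficients with two-sided p-values."""
    _check_design(X, y)
    Z = (X - X.mean()) / X.std(ddof=1)
    z_y = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(z_y.to_numpy(), sm.add_constant(Z.to_numpy())).fit()
    return pd.DataFrame(
        {"src": model.params[1:], "src_p": model.pvalues[1:]},
        index=X.columns,
    )


def prcc(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Partial rank correlation coefficients with two-sided p-values."""
    _check_design(X, y)
    n, k = X.shape
    R = np.column_stack(
        [rankdata(X[c].to_numpy()) for c in X.columns]
        + [rankdata(y.to_numpy())]
    )
    corr = np.corrcoef(R, rowvar=False)
    precision = np.linalg.inv(corr)
    y_idx = k
    coefs = np.array(
        [
            -precision[j, y_idx] / np.sqrt(precision[j, j] * precision[y_idx, y_idx])
            for j in range(k)
        ]
    )
    df = n - 2 - (k - 1)  # controlling the other k-1 inputs
    with np.errstate(divide="ignore"):
        t = coefs * np.sqrt(df / np.clip(1.0 - coefs**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"prcc": coefs, "prcc_p": p}, index=X.columns)


def sensitivity_analysis(
    conc: pd.DataFrame,
    pop: pd.DataFrame,
    doses: pd.DataFrame,
    scenario_id: str | None = None,
) -> pd.DataFrame:
    """SRC and PRCC for all 18 inputs, with per-method ranks.

    Rank 1 is the largest absolute coefficient; ties break alphabetically
    on the input name.
    """
    X, y = build_design_matrix(conc, pop, doses)
    out = src(X, y).join(prcc(X, y))
    for method in ("src", "prcc"):
        order = sorted(
            out.index, key=lambda name: (-abs(out.loc[name, method]), name)
        )
        out[f"{method}_rank"] = pd.Series(
            {name: i + 1 for i, name in enumerate(order)}
        )
    if scenario_id is not None:
        out["scenario"] = scenario_id
    out.index.name = "input"
    return out


def tornado_table(result: pd.DataFrame, method: str = "src") -> pd.DataFrame:
    """Inputs ordered by |coefficient| descending for tornado plotting.

    Keeps every input regardless of significance; adds a boolean
    ``significant`` flag at p < 0.05.  Ties in |coefficient| break
    alphabetically.
    """
    if method not in ("src", "prcc"):
        raise ValueError(f"method must be 'src' or 'prcc', got {method!r}")
    order = sorted(
        result.index, key=lambda name: (-abs(result.loc[name, method]), name)
    )
    table = result.loc[order, [method, f"{method}_p"]].copy()
    table["significant"] = table[f"{method}_p"] < 0.05
    return table
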