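"""Condition-level summaries, factorial tests, and the lift-delta
regression.

Summaries follow the published reporting style: per algorithm x object
size x weight cell, the median and inter-quartile range of the lift
delay in ms (linear-interpolation quartiles).  The factorial tests treat
weight as an equally spaced numeric contrast (-1, 0, +1 over 400/700/
1000 g) and size as -1/+1, so each factor carries a single numerator
degree of freedom, and report F, p and eta squared from sums of squares.
The stratified regression models the per-cell lift-delta as

    lift_delta ~ finger_index + finger_index:size + finger_index:weight

by ordinary least squares, reporting coefficient estimates, standard
errors, p-values, the model F and adjusted R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

ALGORITHMS = ("finger_force", "finger_distance", "lift_delta")
_WEIGHT_CODE = {400: -1.0, 700: 0.0, 1000: 1.0}
_SIZE_CODE = {"small": -1.0, "large": 1.0}


def code_weight(weight_g) -> np.ndarray:
    return np.asarray(pd.Series(weight_g).map(_WEIGHT_CODE), float)


def code_size(size) -> np.ndarray:
    return np.asarray(pd.Series(size).map(_SIZE_CODE), float)


def iqr(x) -> float:
    """Inter-quartile range with linear-interpolation quartiles."""
    q1, q3 = np.percentile(np.asarray(x, float), [25, 75])
    return float(q3 - q1)


# ---------------------------------------------------------------------------
# condition summaries


def condition_summary(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Median / IQR per algorithm x size x weight cell.

    ``per_trial`` needs columns size, weight_g, delay_force_ms,
    delay_distance_ms, lift_delta_ms.  Empty cells are omitted.
    """
    value_cols = {
        "finger_force": "delay_force_ms",
        "finger_distance": "delay_distance_ms",
        "lift_delta": "lift_delta_ms",
    }
    rows = []
    for (size, weight), g in per_trial.groupby(["size", "weight_g"]):
        for algo, col in value_cols.items():
            vals = g[col].dropna()
            if vals.empty:
                continue
            rows.append(
                dict(
                    algorithm=algo,
                    size=size,
                    weight_g=int(weight),
                    median_ms=float(np.median(vals)),
                    iqr_ms=iqr(vals),
                    n=int(len(vals)),
                )
            )
    out = pd.DataFrame(rows)
    order = {a: i for i, a in enumerate(ALGORITHMS)}
    return out.sort_values(
        ["algorithm", "size", "weight_g"],
        key=lambda s: s.map(order) if s.name == "algorithm" else s,
    ).reset_index(drop=True)


def summary_pivot(summary: pd.DataFrame) -> pd.DataFrame:
    """Arrange a condition summary as the published wide layout:
    algorithms as rows, size x weight as columns, 'median/IQR' cells."""
    s = summary.copy()
    s["cell"] = s["median_ms"].round(1).astype(str) + "/" + s["iqr_ms"].round(1).astype(str)
    wide = s.pivot(index="algorithm", columns=["size", "weight_g"], values="cell")
    return wide.reindex(ALGORITHMS)


# ---------------------------------------------------------------------------
# factorial tests


@dataclass(frozen=True)
class FactorTest:
    factor: str
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    eta_squared: float


def dyad_aggregates(
    per_trial: pd.DataFrame, value_col: str, agg: str = "median"
) -> pd.DataFrame:
    """One aggregate per dyad x size x weight cell (default median)."""
    out = (
        per_trial.groupby(["dyad", "size", "weight_g"])[value_col]
        .agg(agg)
        .reset_index()
    )
    return out


def factorial_test(aggregates: pd.DataFrame, value_col: str) -> dict[str, FactorTest]:
    """Single-df F-tests for weight and size on per-cell aggregates.

    Fits y ~ 1 + weight_lin + size_pm by OLS; each factor's F is the
    extra-sum-of-squares test of dropping it (1 numerator df, matching
    the published contrast coding), eta squared its share of the total
    sum of squares.
    """
    cells = aggregates.dropna(subset=[value_col])
    counts = cells.groupby(["size", "weight_g"]).size()
    if len(counts) < 6:
        raise ValueError("missing size x weight cells; design incomplete")
    y = cells[value_col].to_numpy(float)
    w = code_weight(cells["weight_g"])
    s = code_size(cells["size"])
    X_full = np.column_stack([np.ones_like(y), w, s])
    results = {}
    fit_full = sm.OLS(y, X_full).fit()
    ss_res_full = float(fit_full.ssr)
    df_den = int(fit_full.df_resid)
    ss_total = float(((y - y.mean()) ** 2).sum())
    for name, drop in (("weight", 1), ("size", 2)):
        X_red = np.delete(X_full, drop, axis=1)
        ss_res_red = float(sm.OLS(y, X_red).fit().ssr)
        ss_effect = ss_res_red - ss_res_full
        f = (ss_effect / 1.0) / (ss_res_full / df_den)
        p = float(sps.f.sf(f, 1, df_den))
        results[name] = FactorTest(
            factor=name,
            f_value=float(f),
            df_num=1,
            df_den=df_den,
            p_value=p,
            eta_squared=float(ss_effect / ss_total) if ss_total > 0 else np.nan,
        )
    return results


# ---------------------------------------------------------------------------
# stratified regression


@dataclass(frozen=True)
class RegressionTable:
    """OLS fit of lift-delta on finger index stratified by size and weight."""

    coefficients: pd.DataFrame  # index: term; columns: estimate, std_error, p_value
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    adj_r_squared: float

    TERMS = ("intercept", "finger_index", "finger_index:size", "finger_index:weight")


def regression_lift_delta(cells: pd.DataFrame) -> RegressionTable:
    """OLS of per-cell lift-delta on finger index and its size/weight
    interactions (numeric contrast coding as in the factorial tests).

    ``cells`` needs columns lift_delta_ms, finger_index, size, weight_g.
    Raises on a rank-deficient design (e.g. constant finger index).
    """
    data = cells.dropna(subset=["lift_delta_ms", "finger_index"])
    y = data["lift_delta_ms"].to_numpy(float)
    fi = data["finger_index"].to_numpy(float)
    X = np.column_stack(
        [
            np.ones_like(y),
            fi,
            fi * code_size(data["size"]),
            fi * code_weight(data["weight_g"]),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (is finger_index constant?)")
    fit = sm.OLS(y, X).fit()
    coefs = pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "p_value": fit.pvalues,
        },
        index=list(RegressionTable.TERMS),
    )
    return RegressionTable(
        coefficients=coefs,
        f_value=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        adj_r_squared=float(fit.rsquared_adj),
    )
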