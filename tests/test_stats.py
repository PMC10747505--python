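"""Condition summaries, factorial contrasts and the stratified
regression, checked against hand computations and a normal-equations
oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from handover import stats
from handover.stats import (
    code_size, code_weight, condition_summary, dyad_aggregates,
    factorial_test, iqr, regression_lift_delta,
)


# --- independent normal-equations oracle -----------------------------------

def ols_oracle(X, y):
    """Plain normal-equations OLS: estimates, SEs, t p-values, model F."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), n - p)
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    f = ((ss_tot - ss_res) / (p - 1)) / (ss_res / (n - p))
    return beta, se, pvals, f


def make_cells(rng, n_participants=40, beta=(145.0, -64.0, 23.0, 18.0), noise_sd=50.0):
    """Per-cell lift-delta data in the published regression's regime."""
    rows = []
    grid = np.round(np.linspace(-1, 1, 11), 10)
    for pid in range(n_participants):
        for size in ("small", "large"):
            for w in (400, 700, 1000):
                rows.append(dict(participant=pid, size=size, weight_g=w,
                                 finger_index=rng.choice(grid)))
    df = pd.DataFrame(rows)
    fi = df["finger_index"].to_numpy()
    mu = (beta[0] + beta[1] * fi + beta[2] * fi * code_size(df["size"])
          + beta[3] * fi * code_weight(df["weight_g"]))
    df["lift_delta_ms"] = mu + rng.normal(0, noise_sd, len(df))
    return df


class TestConditionSummary:
    def test_hand_computed_median_iqr(self):
        df = pd.DataFrame(
            dict(size=["small"] * 3, weight_g=[400] * 3,
                 delay_force_ms=[100.0, 200.0, 300.0],
                 delay_distance_ms=[50.0, 60.0, 70.0],
                 lift_delta_ms=[50.0, 140.0, 230.0])
        )
        s = condition_summary(df).set_index("algorithm")
        assert s.loc["finger_force", "median_ms"] == 200.0
        assert s.loc["finger_force", "iqr_ms"] == 100.0  # type-7 quartiles
        assert s.loc["finger_force", "n"] == 3

    def test_single_record_iqr_zero(self):
        assert iqr([123.0]) == 0.0

    def test_medians_increase_with_weight(self, small_cohort):
        s = condition_summary(small_cohort)
        for algo in ("finger_force", "finger_distance"):
            for size in ("small", "large"):
                cells = s[(s.algorithm == algo) & (s["size"] == size)]
                med = cells.sort_values("weight_g")["median_ms"].to_numpy()
                assert med[0] < med[1] < med[2]


class TestFactorial:
    def test_matches_normal_equations_oracle_small_n(self):
        rng = np.random.default_rng(3)
        aggs = pd.DataFrame(
            dict(
                dyad=np.repeat(np.arange(3), 6),
                size=np.tile(np.repeat(["small", "large"], 3), 3),
                weight_g=np.tile([400, 700, 1000], 6),
            )
        )
        aggs["y"] = rng.normal(300, 40, len(aggs)) + 30 * code_weight(aggs.weight_g)
        res = factorial_test(aggs, "y")
        y = aggs["y"].to_numpy()
        X = np.column_stack([np.ones(len(y)), code_weight(aggs.weight_g), code_size(aggs["size"])])
        # extra-sum-of-squares F for the weight contrast, by hand
        b_full = np.linalg.solve(X.T @ X, X.T @ y)
        ss_full = ((y - X @ b_full) ** 2).sum()
        Xr = X[:, [0, 2]]
        b_red = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
        ss_red = ((y - Xr @ b_red) ** 2).sum()
        f_oracle = (ss_red - ss_full) / (ss_full / (len(y) - 3))
        assert res["weight"].f_value == pytest.approx(f_oracle, rel=1e-8)
        assert res["weight"].df_num == 1
        assert res["weight"].df_den == len(y) - 3
        eta_oracle = (ss_red - ss_full) / ((y - y.mean()) ** 2).sum()
        assert res["weight"].eta_squared == pytest.approx(eta_oracle, rel=1e-8)

    def test_pure_linear_weight_effect_eta_near_one(self):
        aggs = pd.DataFrame(
            dict(
                dyad=np.repeat(np.arange(4), 6),
                size=np.tile(np.repeat(["small", "large"], 3), 4),
                weight_g=np.tile([400, 700, 1000], 8),
            )
        )
        aggs["y"] = 200.0 + 50.0 * code_weight(aggs.weight_g)
        res = factorial_test(aggs, "y")
        assert res["weight"].eta_squared == pytest.approx(1.0)

    def test_missing_cells_signaled(self):
        aggs = pd.DataFrame(
            dict(dyad=[0, 0], size=["small", "small"], weight_g=[400, 700], y=[1.0, 2.0])
        )
        with pytest.raises(ValueError, match="cells"):
            factorial_test(aggs, "y")

    def test_dyad_aggregation_is_cellwise_median(self, small_cohort):
        aggs = dyad_aggregates(small_cohort, "delay_force_ms")
        one = small_cohort[
            (small_cohort.dyad == 0)
            & (small_cohort["size"] == "small")
            & (small_cohort.weight_g == 400)
        ]["delay_force_ms"].median()
        got = aggs[
            (aggs.dyad == 0) & (aggs["size"] == "small") & (aggs.weight_g == 400)
        ]["delay_force_ms"].iloc[0]
        assert got == one


class TestRegression:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        cells = make_cells(rng, n_participants=4)  # n = 24 <= small instance
        res = regression_lift_delta(cells)
        fi = cells["finger_index"].to_numpy()
        X = np.column_stack(
            [np.ones(len(cells)), fi, fi * code_size(cells["size"]),
             fi * code_weight(cells["weight_g"])]
        )
        beta, se, pvals, f = ols_oracle(X, cells["lift_delta_ms"].to_numpy())
        np.testing.assert_allclose(res.coefficients["estimate"], beta, rtol=1e-8)
        np.testing.assert_allclose(res.coefficients["std_error"], se, rtol=1e-8)
        np.testing.assert_allclose(res.coefficients["p_value"], pvals, rtol=1e-8)
        assert res.f_value == pytest.approx(f, rel=1e-8)
        assert res.df_num == 3 and res.df_den == len(cells) - 4

    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(2)
        beta = (145.0, -64.0, 23.0, 18.0)
        cells = make_cells(rng, beta=beta, noise_sd=0.0)
        res = regression_lift_delta(cells)
        np.testing.assert_allclose(res.coefficients["estimate"], beta, atol=1e-9)

    def test_constant_finger_index_rank_deficient(self):
        rng = np.random.default_rng(4)
        cells = make_cells(rng)
        cells["finger_index"] = 0.4
        with pytest.raises(ValueError, match="rank"):
            regression_lift_delta(cells)

    def test_df_consistent_with_sample_size(self):
        rng = np.random.default_rng(6)
        cells = make_cells(rng, n_participants=40)
        res = regression_lift_delta(cells)
        assert res.df_den == 240 - 4
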