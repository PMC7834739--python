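"""Regression ladder: KPSS, best subsets, ARMA errors, selection, CV, intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from zooptrends.regression import (
    ArimaRegressionSearch,
    arima_evaluate,
    best_subsets,
    finalize_ols,
    kpss_check,
    predict_intervals,
    repeated_cv,
    select_top_model,
)


def test_kpss_noise_vs_random_walk():
    rng = np.random.default_rng(0)
    noise = kpss_check(rng.normal(size=23))
    assert noise.level_p > 0.05 and not noise.differenced
    walk = kpss_check(np.cumsum(rng.normal(size=100)))
    assert walk.level_p < 0.05 and walk.differenced
    with pytest.raises(ValueError):
        kpss_check(np.arange(5.0))


def _frame(rng, n, p):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
    )


def test_best_subsets_perfect_fit_and_oracle():
    rng = np.random.default_rng(1)
    X = _frame(rng, 30, 6)
    y = X["x3"].copy()
    winners = best_subsets(y, X, max_size=2)
    assert winners[1][0] == ("x3",)
    assert winners[1][1] == pytest.approx(0.0, abs=1e-18)
    # independent enumeration oracle via statsmodels OLS on every pair
    best_pair, best_rss = None, np.inf
    y2 = y + rng.normal(0, 1.0, len(y))
    winners2 = best_subsets(y2, X, max_size=2)
    for pair in itertools.combinations(X.columns, 2):
        res = sm.OLS(y2, sm.add_constant(X[list(pair)])).fit()
        if res.ssr < best_rss:
            best_pair, best_rss = pair, res.ssr
    assert winners2[2][0] == best_pair
    assert winners2[2][1] == pytest.approx(best_rss)


def test_best_subsets_orthonormal_design_closed_form():
    rng = np.random.default_rng(2)
    n, p = 64, 8
    Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    Q = Q - Q.mean(axis=0)  # centred, near-orthogonal columns
    X = pd.DataFrame(Q, columns=[f"x{i}" for i in range(p)])
    beta = np.array([3.0, -2.5, 2.0, 1.5, 0.8, 0.3, 0.1, 0.05])
    y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 0.05, n))
    corr_rank = (
        X.apply(lambda c: abs(np.corrcoef(c, y)[0, 1])).sort_values(ascending=False)
    )
    winners = best_subsets(y, X, max_size=3)
    for size in (1, 2, 3):
        assert set(winners[size][0]) == set(corr_rank.index[:size])


def test_best_subsets_equals_independent_enumeration_12_covariates():
    rng = np.random.default_rng(3)
    X = _frame(rng, 40, 12)
    y = pd.Series(
        1.2 * X["x1"] - 0.7 * X["x7"] + rng.normal(0, 0.8, 40)
    )
    winners = best_subsets(y, X, max_size=3)
    yv = y.to_numpy()
    for size in (1, 2, 3):
        best, best_rss = None, np.inf
        for cols in itertools.combinations(X.columns, size):
            A = np.column_stack([np.ones(len(yv)), X[list(cols)].to_numpy()])
            resid = yv - A @ np.linalg.solve(A.T @ A, A.T @ yv)
            rss = float(resid @ resid)
            if rss < best_rss:
                best, best_rss = cols, rss
        assert winners[size][0] == best


def test_arima_white_noise_selects_000_in_majority():
    # order selection on uncorrelated errors is stochastic at n = 23; the
    # plain-regression order should win in the clear majority of replicates
    rng = np.random.default_rng(4)
    plain = 0
    for _ in range(10):
        X = _frame(rng, 23, 2)
        y = pd.Series(0.3 + 1.2 * X["x0"] + rng.normal(0, 0.4, 23))
        cand = arima_evaluate(y, X[["x0"]])
        plain += cand.arima_order == (0, 0, 0)
    assert plain >= 6


def test_arima_detects_ar1_errors():
    rng = np.random.default_rng(5)
    n = 200
    X = _frame(rng, n, 1)
    e = np.zeros(n)
    for t in range(1, n):
        e[t] = 0.8 * e[t - 1] + rng.normal(0, 0.5)
    y = pd.Series(1.0 * X["x0"] + e)
    cand = arima_evaluate(y, X)
    assert cand.arima_order[0] >= 1


def test_zero_covariate_aicc_matches_gaussian_closed_form():
    rng = np.random.default_rng(6)
    y = pd.Series(rng.normal(size=40))
    cand = arima_evaluate(y, pd.DataFrame(index=y.index), stepwise=False, max_p=0, max_q=0)
    n = len(y)
    sigma2 = ((y - y.mean()) ** 2).mean()
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    k = 2  # mean + variance
    expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    assert cand.aicc == pytest.approx(expected, rel=1e-6)


def test_select_top_model_single_and_nested():
    rng = np.random.default_rng(7)
    X = _frame(rng, 40, 3)
    y = pd.Series(2.0 * X["x0"] + rng.normal(0, 0.5, 40))
    good = arima_evaluate(y, X[["x0"]])
    assert select_top_model([good]) is good
    # a nested candidate with a superfluous covariate loses to the small model
    padded = arima_evaluate(y, X[["x0", "x1"]])
    chosen = select_top_model([good, padded], data=X, y=y)
    assert chosen.covariates == ("x0",)


def test_select_top_model_filters_nonsignificant():
    rng = np.random.default_rng(8)
    X = _frame(rng, 25, 2)
    y = pd.Series(rng.normal(size=25))  # no relationship
    cand = arima_evaluate(y, X)
    if not cand.all_covariates_significant:
        assert select_top_model([cand]) is None


def test_finalize_ols_properties():
    rng = np.random.default_rng(9)
    X = _frame(rng, 30, 2)
    y_perfect = pd.Series(1.0 + 2.0 * X["x0"] - 1.0 * X["x1"])
    adj, p, diag, _ = finalize_ols(y_perfect, X)
    assert adj == pytest.approx(1.0)
    y_noise = pd.Series(rng.normal(size=300))
    Xn = _frame(rng, 300, 2)
    adj_n, p_n, _, _ = finalize_ols(y_noise, Xn)
    assert abs(adj_n) < 0.05
    # adjusted R^2 invariant to affine rescaling of covariates
    X_resc = X * 3.7 + 11.0
    y = pd.Series(2.0 * X["x0"] + rng.normal(0, 0.5, 30))
    adj_a, _, _, _ = finalize_ols(y, X)
    adj_b, _, _, _ = finalize_ols(y, X_resc)
    assert adj_a == pytest.approx(adj_b, abs=1e-12)
    assert set(diag.columns) >= {"fitted", "residual", "leverage", "qq_theoretical"}


def test_repeated_cv_bounds_and_perfect_fit():
    rng = np.random.default_rng(10)
    X = _frame(rng, 25, 1)
    y = X["x0"].copy()
    rep = repeated_cv(y, X, seed=0)
    assert rep.cv_r2 == pytest.approx(1.0)
    y_noise = pd.Series(rng.normal(size=25))
    rep_n = repeated_cv(y_noise, X, seed=0)
    assert rep_n.cv_r2 <= 1.0


def test_prediction_intervals_shape_and_width():
    rng = np.random.default_rng(11)
    X = _frame(rng, 40, 1)
    y = pd.Series(1.0 + 2.0 * X["x0"] + rng.normal(0, 0.5, 40))
    res = sm.OLS(y, sm.add_constant(X)).fit()
    grid = pd.DataFrame({"x0": [X["x0"].mean(), X["x0"].min(), X["x0"].max()]})
    out = predict_intervals(res, grid)
    assert ((out["lower95"] <= out["point"]) & (out["point"] <= out["upper95"])).all()
    widths = out["upper95"] - out["lower95"]
    assert widths.iloc[0] == widths.min()  # narrowest at the covariate mean
    # degenerate: perfect fit gives an (essentially) zero-width interval
    res0 = sm.OLS(2.0 * X["x0"], sm.add_constant(X)).fit()
    out0 = predict_intervals(res0, grid)
    assert (out0["upper95"] - out0["lower95"]).max() == pytest.approx(0.0, abs=1e-8)


def test_prediction_interval_coverage_near_95():
    rng = np.random.default_rng(12)
    hits = trials = 0
    for _ in range(300):
        X = _frame(rng, 25, 1)
        y = pd.Series(1.0 + 2.0 * X["x0"] + rng.normal(0, 0.7, 25))
        res = sm.OLS(y, sm.add_constant(X)).fit()
        xnew = pd.DataFrame({"x0": rng.normal(size=2)})
        out = predict_intervals(res, xnew)
        ynew = 1.0 + 2.0 * xnew["x0"] + rng.normal(0, 0.7, 2)
        hits += ((ynew >= out["lower95"]) & (ynew <= out["upper95"])).sum()
        trials += 2
    assert 0.92 <= hits / trials <= 0.98


def test_back_transform_preserves_interval_order():
    from zooptrends.survival import inv_logit

    rng = np.random.default_rng(13)
    X = _frame(rng, 30, 1)
    y = pd.Series(-1.0 + 1.5 * X["x0"] + rng.normal(0, 0.5, 30))
    res = sm.OLS(y, sm.add_constant(X)).fit()
    out = predict_intervals(res, pd.DataFrame({"x0": [0.3]}),
                            back_transform=lambda a: inv_logit(a * 0.5 - 4.8))
    assert 0 < out["lower95"].iloc[0] < out["point"].iloc[0] < out["upper95"].iloc[0] < 1


def test_search_estimator_recovers_strong_signal():
    rng = np.random.default_rng(14)
    n = 30
    X = _frame(rng, n, 6)
    y = pd.Series(1.5 * X["x2"] - 1.2 * X["x4"] + rng.normal(0, 0.4, n))
    search = ArimaRegressionSearch(max_subset_size=3, random_state=0).fit(X, y)
    assert search.best_ is not None
    assert set(search.best_.covariates) >= {"x2", "x4"}
    assert search.adj_r2_ > 0.7
    assert search.cv_.cv_r2 > 0.6
    preds = search.predict(X.iloc[:3])
    assert preds.shape == (3,)
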