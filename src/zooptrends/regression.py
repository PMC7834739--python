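"""Best-subsets regression with ARIMA error checking and cross-validation.

The model-building ladder for relating an annual response (latent trend,
total-biomass anomaly, or scaled-logit salmon survival) to candidate annual
covariates:

1. KPSS tests for trend and level stationarity of the response; rejection
   (p < 0.05, with a logged tolerance just below it) first-differences the
   response and every covariate.
2. Exhaustive best-subsets regression: the minimum-RSS covariate subset of
   each size 1..5 (no interactions).
3. Each size winner is refit as a regression with ARIMA errors over a grid
   of (p, d, q) orders, selected by AICc under MLE.  Order (0,0,0) means no
   autocorrelation/differencing/moving-average correction was needed.
4. The overall winner must have every covariate 95% CI excluding zero and a
   Ljung-Box residual p-value above 0.05; among those, lowest AICc wins,
   with a nested-model F-test breaking near-ties (within 2 AICc units).
5. If the winning order is (0,0,0), an OLS refit supplies adjusted R^2, the
   overall F-test p-value, and residual diagnostics.

Predictive skill is summarized by 5-repeat 5-fold cross-validation (R^2 of
pooled out-of-fold predictions against observations, averaged over repeats),
and out-of-sample years get 95% prediction intervals that account for both
parameter and residual uncertainty.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import kpss as _kpss

logger = logging.getLogger(__name__)


@dataclass
class KPSSResult:
    trend_p: float
    level_p: float
    differenced: bool


def kpss_check(series, alpha: float = 0.05, tolerance: float = 0.045) -> KPSSResult:
    """KPSS trend- and level-stationarity check of an annual series.

    ``differenced`` flags that either null was rejected at ``alpha``;
    p-values in [tolerance, alpha) are accepted with a logged warning
    (slight non-stationarity is tolerated because the later ARIMA stage
    re-checks autocorrelation).  Note the KPSS p-value is interpolated and
    clipped to [0.01, 0.1] by convention.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise ValueError("KPSS needs at least 10 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, trend_p, *_ = _kpss(x, regression="ct", nlags="auto")
        _, level_p, *_ = _kpss(x, regression="c", nlags="auto")
    diff = False
    for p in (trend_p, level_p):
        if p < tolerance:
            diff = True
        elif p < alpha:
            logger.warning("KPSS p=%.3f is close to %.2f; accepted as stationary", p, alpha)
    return KPSSResult(float(trend_p), float(level_p), diff)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X])
    coef, rss, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("rank deficient design")
    if rss.size == 0:  # perfect fit
        resid = y - A @ coef
        return float(resid @ resid)
    return float(rss[0])


def best_subsets(y: pd.Series, X: pd.DataFrame, max_size: int = 5) -> dict:
    """Minimum-RSS covariate subset of each size 1..max_size (exhaustive).

    Rows with any missing value in y or X are dropped (complete cases), so
    RSS values are comparable across subsets.  Rank-deficient subsets are
    skipped with a warning.  Returns {size: (columns tuple, rss)}.
    """
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    if len(data) < max_size + 2:
        raise ValueError("too few complete cases for best-subsets search")
    yv = data["__y__"].to_numpy(dtype=float)
    cols = list(X.columns)
    winners = {}
    for size in range(1, max_size + 1):
        best = None
        for subset in itertools.combinations(cols, size):
            try:
                rss = _ols_rss(yv, data[list(subset)].to_numpy(dtype=float))
            except np.linalg.LinAlgError:
                logger.warning("skipping rank-deficient subset %s", subset)
                continue
            if best is None or rss < best[1]:
                best = (subset, rss)
        if best is not None:
            winners[size] = best
    return winners


@dataclass
class RegressionCandidate:
    """One candidate model from the search ladder."""

    response: str
    covariates: tuple
    rss: float
    arima_order: tuple
    aicc: float
    ljung_box_p: float
    coefficients: dict  # name -> (estimate, lo95, hi95, p_value)
    intercept: tuple | None
    n_obs: int
    adj_r2: float = np.nan
    p_value: float = np.nan
    results: object = field(default=None, repr=False)

    @property
    def all_covariates_significant(self) -> bool:
        return all(lo * hi > 0 for (_, lo, hi, _) in self.coefficients.values())


def _ljung_box_p(resid: np.ndarray) -> float:
    n = len(resid)
    lag = max(1, min(10, n // 5))
    table = acorr_ljungbox(resid, lags=[lag])
    return float(table["lb_pvalue"].iloc[0])


def _fit_order(yv, Xv, order):
    p, d, q = order
    if len(yv) <= p + q + Xv.shape[1] + d + 2:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(
                yv, exog=Xv, order=order, trend="c" if d == 0 else None,
            ).fit(method_kwargs={"maxiter": 200})
    except (np.linalg.LinAlgError, ValueError):
        return None
    return res if np.isfinite(res.aicc) else None


def arima_evaluate(
    y: pd.Series,
    X: pd.DataFrame,
    response_name: str = "y",
    max_p: int = 3,
    max_q: int = 3,
    d: int = 0,
    stepwise: bool = True,
) -> RegressionCandidate:
    """Regression with ARMA errors: search (p, q) orders by AICc under MLE.

    The differencing order ``d`` is decided upstream by the KPSS stage (AICc
    is not comparable across differencing, so d is not free in the search).
    The default search is the conventional stepwise walk: start from the
    basic orders (0,0), (1,0), (0,1), (2,2) and move to the best improving
    neighbour until none improves; ``stepwise=False`` scans the full grid.
    Orders whose MLE fails to converge are skipped.  Returns the winning
    order with its coefficient 95% CIs and a Ljung-Box residual p-value.
    """
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    yv = data["__y__"].astype(float)
    Xv = data[list(X.columns)].astype(float)

    cache: dict = {}

    def evaluate(p, q):
        if (p, q) in cache:
            return cache[(p, q)]
        res = _fit_order(yv, Xv, (p, d, q))
        cache[(p, q)] = res
        return res

    if stepwise:
        for p0, q0 in ((0, 0), (1, 0), (0, 1), (2, 2)):
            evaluate(p0, q0)
        current = min(
            (pq for pq, r in cache.items() if r is not None),
            key=lambda pq: cache[pq].aicc,
        )
        improved = True
        while improved:
            improved = False
            p0, q0 = current
            for dp, dq in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)):
                p1, q1 = p0 + dp, q0 + dq
                if not (0 <= p1 <= max_p and 0 <= q1 <= max_q):
                    continue
                res = evaluate(p1, q1)
                if res is not None and res.aicc < cache[current].aicc - 1e-9:
                    current = (p1, q1)
                    improved = True
        best_pq = current
    else:
        for p1 in range(max_p + 1):
            for q1 in range(max_q + 1):
                evaluate(p1, q1)
        converged = {pq: r for pq, r in cache.items() if r is not None}
        if not converged:
            raise RuntimeError("no ARIMA order converged")
        best_pq = min(converged, key=lambda pq: converged[pq].aicc)

    res = cache[best_pq]
    if res is None:
        raise RuntimeError("no ARIMA order converged")
    order = (best_pq[0], d, best_pq[1])
    aicc_val = float(res.aicc)
    ci = res.conf_int(alpha=0.05)
    pvals = res.pvalues
    params = res.params
    coefficients = {}
    for name in X.columns:
        coefficients[name] = (
            float(params[name]), float(ci.loc[name, 0]), float(ci.loc[name, 1]),
            float(pvals[name]),
        )
    intercept = None
    for iname in ("const", "intercept"):
        if iname in params.index:
            intercept = (
                float(params[iname]), float(ci.loc[iname, 0]), float(ci.loc[iname, 1]),
                float(pvals[iname]),
            )
            break
    rss = _ols_rss(yv.to_numpy(), Xv.to_numpy()) if order[1] == 0 else np.nan
    return RegressionCandidate(
        response=response_name,
        covariates=tuple(X.columns),
        rss=rss,
        arima_order=order,
        aicc=aicc_val,
        ljung_box_p=_ljung_box_p(np.asarray(res.resid)),
        coefficients=coefficients,
        intercept=intercept,
        n_obs=len(yv),
        results=res,
    )


def _nested(a: RegressionCandidate, b: RegressionCandidate):
    """Return (small, large) if one candidate's covariates nest the other's."""
    sa, sb = set(a.covariates), set(b.covariates)
    if sa < sb:
        return a, b
    if sb < sa:
        return b, a
    return None


def select_top_model(
    candidates,
    lb_alpha: float = 0.05,
    aicc_window: float = 2.0,
    data: pd.DataFrame | None = None,
    y: pd.Series | None = None,
) -> RegressionCandidate | None:
    """Pick the winner: all covariates significant, white residuals, low AICc.

    Candidates failing the significance or Ljung-Box filters are discarded;
    among survivors the lowest AICc wins.  If the runner-up is within
    ``aicc_window`` AICc units and nested with the winner (and ``data``/``y``
    are supplied for an OLS F-test), a significant F keeps the larger model,
    otherwise the smaller one.  Returns None when nothing passes.
    """
    passing = [
        c for c in candidates
        if c.all_covariates_significant and c.ljung_box_p > lb_alpha
    ]
    if not passing:
        return None
    passing.sort(key=lambda c: c.aicc)
    best = passing[0]
    for other in passing[1:]:
        if other.aicc - best.aicc > aicc_window:
            break
        pair = _nested(best, other)
        if pair is None or data is None or y is None:
            continue
        small, large = pair
        frame = pd.concat([y.rename("__y__"), data[list(large.covariates)]], axis=1).dropna()
        ols_small = sm.OLS(
            frame["__y__"], sm.add_constant(frame[list(small.covariates)])
        ).fit()
        ols_large = sm.OLS(
            frame["__y__"], sm.add_constant(frame[list(large.covariates)])
        ).fit()
        f_p = float(
            sm.stats.anova_lm(ols_small, ols_large)["Pr(>F)"].iloc[1]
        )
        best = large if f_p < 0.05 else small
    return best


def finalize_ols(y: pd.Series, X: pd.DataFrame):
    """OLS refit of a (0,0,0)-order winner: adj R^2, overall p, diagnostics."""
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    res = sm.OLS(frame["__y__"], sm.add_constant(frame[list(X.columns)])).fit()
    influence = res.get_influence()
    resid = np.asarray(res.resid)
    diagnostics = pd.DataFrame(
        {
            "fitted": np.asarray(res.fittedvalues),
            "residual": resid,
            "std_residual": influence.resid_studentized_internal,
            "leverage": influence.hat_matrix_diag,
            "qq_theoretical": stats.norm.ppf(
                (np.argsort(np.argsort(resid)) + 0.5) / len(resid)
            ),
        },
        index=frame.index,
    )
    return float(res.rsquared_adj), float(res.f_pvalue), diagnostics, res


@dataclass
class CrossValReport:
    repeats: int
    folds: int
    cv_r2: float
    per_repeat: list


def repeated_cv(
    y: pd.Series,
    X: pd.DataFrame,
    repeats: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> CrossValReport:
    """Repeated k-fold CV of the OLS model on the selected covariates.

    Within each repeat the years are shuffled into ``folds`` folds; the
    model is refit without each fold and predicts it.  The repeat's score is
    the squared Pearson correlation between pooled out-of-fold predictions
    and observations; the report averages over repeats.
    """
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    if len(frame) < folds:
        raise ValueError("need at least as many observations as folds")
    yv = frame["__y__"].to_numpy(dtype=float)
    Xv = frame[list(X.columns)].to_numpy(dtype=float)
    scores = []
    for r in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + r)
        pred = np.empty_like(yv)
        for train, test in kf.split(Xv):
            A = np.column_stack([np.ones(len(train)), Xv[train]])
            coef, *_ = np.linalg.lstsq(A, yv[train], rcond=None)
            pred[test] = np.column_stack([np.ones(len(test)), Xv[test]]) @ coef
        r_p = np.corrcoef(yv, pred)[0, 1]
        scores.append(float(r_p**2))
    return CrossValReport(repeats, folds, float(np.mean(scores)), scores)


def predict_intervals(
    ols_results,
    X_new: pd.DataFrame,
    back_transform=None,
) -> pd.DataFrame:
    """Point predictions with 95% prediction intervals for new covariates.

    Years with missing covariates are skipped with a warning.  When a
    ``back_transform`` callable is given (e.g. a scaled-logit inverse), all
    three columns pass through it; monotone transforms preserve the interval
    ordering.
    """
    complete = X_new.dropna()
    skipped = X_new.index.difference(complete.index)
    if len(skipped):
        logger.warning("skipping years with missing covariates: %s", list(skipped))
    exog = sm.add_constant(complete, has_constant="add")
    sf = ols_results.get_prediction(exog).summary_frame(alpha=0.05)
    out = pd.DataFrame(
        {
            "point": sf["mean"].to_numpy(),
            "lower95": sf["obs_ci_lower"].to_numpy(),
            "upper95": sf["obs_ci_upper"].to_numpy(),
        },
        index=complete.index,
    )
    if back_transform is not None:
        for col in out.columns:
            out[col] = back_transform(out[col].to_numpy())
    return out


class ArimaRegressionSearch(BaseEstimator):
    """The full five-step search as an sklearn-style estimator.

    ``fit(X, y)`` expects a DataFrame of candidate annual covariates and an
    annual response aligned on year.  Fitted attributes: ``kpss_``,
    ``differenced_``, ``subset_winners_``, ``candidates_``, ``best_``,
    ``adj_r2_``, ``p_value_``, ``diagnostics_``, ``cv_``, ``ols_results_``.
    ``best_`` is None when no candidate passes the validity criteria.
    """

    def __init__(
        self,
        max_subset_size: int = 5,
        max_p: int = 3,
        max_q: int = 3,
        stepwise: bool = True,
        kpss_alpha: float = 0.05,
        lb_alpha: float = 0.05,
        aicc_window: float = 2.0,
        cv_repeats: int = 5,
        cv_folds: int = 5,
        random_state: int = 0,
        response_name: str = "y",
    ):
        self.max_subset_size = max_subset_size
        self.max_p = max_p
        self.max_q = max_q
        self.stepwise = stepwise
        self.kpss_alpha = kpss_alpha
        self.lb_alpha = lb_alpha
        self.aicc_window = aicc_window
        self.cv_repeats = cv_repeats
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.response_name = response_name

    def fit(self, X: pd.DataFrame, y: pd.Series):
        X = X.copy()
        y = pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y
        self.kpss_ = kpss_check(y.dropna(), alpha=self.kpss_alpha)
        self.differenced_ = self.kpss_.differenced
        if self.differenced_:
            y = y.diff()
            X = X.diff()
            self.kpss_after_diff_ = kpss_check(y.dropna(), alpha=self.kpss_alpha)
        max_size = min(self.max_subset_size, X.shape[1])
        self.subset_winners_ = best_subsets(y, X, max_size=max_size)
        self.candidates_ = [
            arima_evaluate(
                y, X[list(cols)], response_name=self.response_name,
                max_p=self.max_p, max_q=self.max_q, stepwise=self.stepwise,
            )
            for cols, _ in self.subset_winners_.values()
        ]
        self.best_ = select_top_model(
            self.candidates_, lb_alpha=self.lb_alpha,
            aicc_window=self.aicc_window, data=X, y=y,
        )
        self.adj_r2_ = np.nan
        self.p_value_ = np.nan
        self.cv_ = None
        self.ols_results_ = None
        self.diagnostics_ = None
        if self.best_ is not None:
            sel = X[list(self.best_.covariates)]
            if self.best_.arima_order == (0, 0, 0):
                self.adj_r2_, self.p_value_, self.diagnostics_, self.ols_results_ = (
                    finalize_ols(y, sel)
                )
                self.best_.adj_r2 = self.adj_r2_
                self.best_.p_value = self.p_value_
            self.cv_ = repeated_cv(
                y, sel, repeats=self.cv_repeats, folds=self.cv_folds,
                seed=self.random_state,
            )
        self._y = y
        self._X = X
        return self

    def predict(self, X_new: pd.DataFrame) -> np.ndarray:
        if self.best_ is None:
            raise RuntimeError("no valid model was selected")
        if self.ols_results_ is None:
            raise RuntimeError("prediction requires an OLS-finalized (0,0,0) model")
        exog = sm.add_constant(
            X_new[list(self.best_.covariates)], has_constant="add"
        )
        return np.asarray(self.ols_results_.predict(exog))

    def predict_interval(self, X_new: pd.DataFrame, back_transform=None) -> pd.DataFrame:
        if self.best_ is None or self.ols_results_ is None:
            raise RuntimeError("no OLS-finalized model available")
        return predict_intervals(
            self.ols_results_, X_new[list(self.best_.covariates)], back_transform
        )
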