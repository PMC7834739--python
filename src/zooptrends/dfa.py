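"""Dynamic factor analysis by EM-fitted Gaussian state space models.

A DFA expresses m observed time series as linear combinations of k << m
shared latent trends that evolve as random walks:

    x_t = x_{t-1} + w_t,          w_t ~ N(0, I_k)
    y_t = Z x_t + v_t,            v_t ~ N(0, R)

Identifiability is obtained the conventional way: the trend innovation
variance is fixed at the identity, and the loading matrix Z has zeros above
the diagonal in its first k rows during fitting.  The observation error
covariance R can be constrained to one of four structures (diagonal and
equal, diagonal and unequal, equal variance + common covariance, or
unconstrained).  Estimation is by EM: the E-step is an exact Kalman
filter/smoother that handles missing observations, and the M-steps for Z
(with its zero constraints) and structured R are closed form, so the exact
Gaussian log-likelihood is non-decreasing across iterations.

Candidate models over (k, R structure) are ranked by AICc with Akaike
weights; the chosen solution is varimax-rotated for interpretability, with
the inverse rotation applied to the trends so the fitted values Z @ x are
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.multivariate.factor_rotation import rotate_factors

R_STRUCTURES = ("diagonal_equal", "diagonal_unequal", "equalvarcov", "unconstrained")


def aicc(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2K + 2K(K+1)/(n - K - 1)."""
    if n_obs <= n_params + 1:
        raise ValueError("AICc undefined: n_obs must exceed n_params + 1")
    k = n_params
    return -2.0 * log_likelihood + 2 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _n_r_params(structure: str, m: int) -> int:
    return {
        "diagonal_equal": 1,
        "diagonal_unequal": m,
        "equalvarcov": 2,
        "unconstrained": m * (m + 1) // 2,
    }[structure]


def _project_r(S: np.ndarray, structure: str) -> np.ndarray:
    """Closed-form constrained M-step for R given the residual moment S."""
    m = S.shape[0]
    if structure == "diagonal_unequal":
        return np.diag(np.diag(S).copy())
    if structure == "diagonal_equal":
        return np.eye(m) * float(np.diag(S).mean())
    if structure == "equalvarcov":
        alpha = float(np.diag(S).mean())
        off = S[~np.eye(m, dtype=bool)]
        beta = float(off.mean()) if off.size else 0.0
        # keep R positive definite (eigenvalues alpha-beta, alpha+(m-1)beta)
        lo, hi = -alpha / max(m - 1, 1), alpha
        beta = float(np.clip(beta, lo * 0.999, hi * 0.999))
        return alpha * np.eye(m) + beta * (np.ones((m, m)) - np.eye(m))
    if structure == "unconstrained":
        return 0.5 * (S + S.T)
    raise ValueError(f"unknown R structure: {structure}")


def _free_mask(m: int, k: int) -> np.ndarray:
    """Boolean m x k mask of free loading entries (upper triangle zeroed)."""
    mask = np.ones((m, k), dtype=bool)
    for i in range(min(k, m)):
        mask[i, i + 1:] = False
    return mask


def _kalman(y, Z, R, init_var):
    """Kalman filter + RTS smoother for the DFA random-walk state space.

    ``y`` is m x T with NaN marking missing entries.  Returns the exact
    log-likelihood and the smoothed moments needed by the M-step.
    """
    m, T = y.shape
    k = Z.shape[1]
    Ik = np.eye(k)

    xf = np.zeros((T, k))        # x_{t|t}
    Pf = np.zeros((T, k, k))
    xp = np.zeros((T, k))        # x_{t|t-1}
    Pp = np.zeros((T, k, k))
    loglik = 0.0

    x_prev = np.zeros(k)
    P_prev = init_var * Ik       # Var(x_0)
    for t in range(T):
        x_pred = x_prev
        P_pred = P_prev + Ik
        obs = ~np.isnan(y[:, t])
        if obs.any():
            Zo = Z[obs]
            Ro = R[np.ix_(obs, obs)]
            e = y[obs, t] - Zo @ x_pred
            F = Zo @ P_pred @ Zo.T + Ro
            F = 0.5 * (F + F.T)
            cF = np.linalg.cholesky(F)
            sol = np.linalg.solve(cF, e)
            loglik -= 0.5 * (
                obs.sum() * np.log(2 * np.pi)
                + 2 * np.log(np.diag(cF)).sum()
                + sol @ sol
            )
            K = P_pred @ Zo.T @ np.linalg.inv(F)
            x_curr = x_pred + K @ e
            P_curr = (Ik - K @ Zo) @ P_pred
            P_curr = 0.5 * (P_curr + P_curr.T)
        else:
            x_curr, P_curr = x_pred, P_pred
        xp[t], Pp[t] = x_pred, P_pred
        xf[t], Pf[t] = x_curr, P_curr
        x_prev, P_prev = x_curr, P_curr

    # RTS smoother
    xs = np.zeros((T, k))
    Ps = np.zeros((T, k, k))
    xs[-1], Ps[-1] = xf[-1], Pf[-1]
    J = np.zeros((T, k, k))
    for t in range(T - 2, -1, -1):
        J[t] = np.linalg.solve(Pp[t + 1].T, Pf[t].T).T  # Pf[t] @ inv(Pp[t+1])
        xs[t] = xf[t] + J[t] @ (xs[t + 1] - xp[t + 1])
        Ps[t] = Pf[t] + J[t] @ (Ps[t + 1] - Pp[t + 1]) @ J[t].T
        Ps[t] = 0.5 * (Ps[t] + Ps[t].T)

    # lag-one smoothed covariances Cov(x_t, x_{t-1} | Y), t = 1..T-1 index
    Plag = np.zeros((T, k, k))  # Plag[t] = Cov(x_t, x_{t-1}); Plag[0] unused
    for t in range(T - 1, 0, -1):
        Plag[t] = Ps[t] @ J[t - 1].T

    return loglik, xs, Ps, Plag


def _estep_stats(y, Z, R, xs, Ps):
    """Complete-data sufficient statistics, filling in missing y moments.

    For a time point with observed block o and missing block m the missing
    observations satisfy  y_m = A x_t + G y_o + u  with
    G = R_mo R_oo^{-1}, A = Z_m - G Z_o and u independent noise with
    variance R_mm - G R_om; expectations follow directly.
    """
    m, T = y.shape
    k = Z.shape[1]
    S_xx = np.zeros((k, k))
    S_yx = np.zeros((m, k))
    S_yy = np.zeros((m, m))
    for t in range(T):
        Ext = xs[t]
        Pxx = Ps[t] + np.outer(Ext, Ext)
        S_xx += Pxx
        obs = ~np.isnan(y[:, t])
        ey = np.empty(m)
        ey[obs] = y[obs, t]
        Eyx = np.zeros((m, k))
        Eyy = np.zeros((m, m))
        if obs.all():
            Eyx = np.outer(ey, Ext)
            Eyy = np.outer(ey, ey)
        else:
            miss = ~obs
            if obs.any():
                Roo = R[np.ix_(obs, obs)]
                G = np.linalg.solve(Roo.T, R[np.ix_(obs, miss)]).T  # R_mo Roo^-1
                A = Z[miss] - G @ Z[obs]
                b = G @ y[obs, t]
                Vu = R[np.ix_(miss, miss)] - G @ R[np.ix_(obs, miss)]
            else:
                A = Z[miss]
                b = np.zeros(miss.sum())
                Vu = R[np.ix_(miss, miss)]
            ey[miss] = A @ Ext + b
            AV = A @ Ps[t]
            Eyx[obs] = np.outer(y[obs, t], Ext)
            Eyx[miss] = np.outer(ey[miss], Ext) + AV
            Eyy[np.ix_(obs, obs)] = np.outer(y[obs, t], y[obs, t])
            Eyy[np.ix_(obs, miss)] = np.outer(y[obs, t], ey[miss])
            Eyy[np.ix_(miss, obs)] = Eyy[np.ix_(obs, miss)].T
            Eyy[np.ix_(miss, miss)] = np.outer(ey[miss], ey[miss]) + AV @ A.T + Vu
        S_yx += Eyx
        S_yy += Eyy
    return S_xx, S_yx, S_yy


def _em_fit(y, k, structure, em_tol, max_iter, init_var, Z0, R0):
    """Run EM to convergence; returns Z, R, trends, loglik path, converged."""
    m, T = y.shape
    mask = _free_mask(m, k)
    D = np.flatnonzero(mask.T.ravel())  # free positions in column-stacked vec(Z)
    Z, R = Z0.copy(), R0.copy()
    Z[~mask] = 0.0
    logliks = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, xs, Ps, _ = _kalman(y, Z, R, init_var)
        logliks.append(ll)
        if np.isfinite(prev) and abs(ll - prev) < em_tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = ll
        S_xx, S_yx, S_yy = _estep_stats(y, Z, R, xs, Ps)
        # constrained GLS update of the free loading entries
        Rinv = np.linalg.inv(R)
        H = np.kron(S_xx, Rinv)[np.ix_(D, D)]
        g = (Rinv @ S_yx).T.ravel()[D]
        zeta = np.linalg.solve(H, g)
        Zv = np.zeros(m * k)
        Zv[D] = zeta
        Z = Zv.reshape(k, m).T
        # structured R update
        S = (S_yy - Z @ S_yx.T - S_yx @ Z.T + Z @ S_xx @ Z.T) / T
        R = _project_r(S, structure)
    ll, xs, _, _ = _kalman(y, Z, R, init_var)
    logliks.append(ll)
    return Z, R, xs.T, np.asarray(logliks), converged


def _moment_init(y, k, structure, rng=None, jitter=0.0):
    """Deterministic SVD-based starting values (optionally jittered)."""
    m, T = y.shape
    filled = np.where(np.isnan(y), 0.0, y)
    U, s, _ = np.linalg.svd(filled, full_matrices=False)
    Z0 = U[:, :k] * (s[:k] / np.sqrt(T))
    if Z0.shape[1] < k:
        Z0 = np.pad(Z0, ((0, 0), (0, k - Z0.shape[1])))
    if jitter and rng is not None:
        Z0 = Z0 + jitter * rng.standard_normal(Z0.shape)
    resid_var = np.nanvar(y, axis=1)
    R0 = _project_r(np.diag(np.maximum(resid_var * 0.5, 0.05)), structure)
    return Z0, R0


def varimax_rotate(loadings: np.ndarray, trends: np.ndarray):
    """Varimax-rotate loadings, counter-rotating trends so Z @ x is unchanged.

    Returns (rotated_loadings, rotated_trends, rotation_matrix).
    """
    loadings = np.asarray(loadings, dtype=float)
    trends = np.asarray(trends, dtype=float)
    k = loadings.shape[1]
    if k == 1:
        return loadings.copy(), trends.copy(), np.eye(1)
    L_rot, rot = rotate_factors(loadings, "varimax")
    return L_rot, rot.T @ trends, rot


def _apply_sign_convention(Z, x):
    """Flip each trend so its largest-magnitude loading is positive."""
    Z, x = Z.copy(), x.copy()
    for j in range(Z.shape[1]):
        i = np.argmax(np.abs(Z[:, j]))
        if Z[i, j] < 0:
            Z[:, j] *= -1
            x[j] *= -1
    return Z, x


class DynamicFactorAnalysis(BaseEstimator):
    """Dynamic factor analysis estimator (sklearn-style).

    Parameters
    ----------
    n_trends : int
        Number of latent random-walk trends k.
    r_structure : str
        Observation error covariance structure: ``diagonal_equal``,
        ``diagonal_unequal``, ``equalvarcov`` or ``unconstrained``.
    em_tol : float
        Relative log-likelihood change declaring EM convergence.
    max_iter : int
        EM iteration cap; non-convergence is flagged, not raised.
    zscore : bool
        Centre/scale each series before fitting (recommended: makes loadings
        comparable across series measured on different scales).
    init_var : float
        Prior variance of the initial state (diffuse-ish, MARSS-style 5).
    n_restarts, random_state
        Optional jittered restarts around the deterministic SVD start;
        the best log-likelihood wins.

    Attributes
    ----------
    loadings_ : (m, k) varimax-rotated loadings, sign convention applied.
    trends_ : (k, T) rotated latent trends.
    raw_loadings_, raw_trends_ : the unrotated ML solution.
    obs_variance_ : (m, m) estimated R.
    log_likelihood_, n_params_, aicc_, converged_, n_iter_
    """

    def __init__(
        self,
        n_trends: int = 1,
        r_structure: str = "diagonal_equal",
        em_tol: float = 1e-6,
        max_iter: int = 2000,
        zscore: bool = True,
        init_var: float = 5.0,
        n_restarts: int = 0,
        random_state: int | None = None,
    ):
        self.n_trends = n_trends
        self.r_structure = r_structure
        self.em_tol = em_tol
        self.max_iter = max_iter
        self.zscore = zscore
        self.init_var = init_var
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit to a (T, m) matrix of time-by-series observations (NaN = missing)."""
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            self.time_index_ = X.index.to_numpy()
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = None
            self.time_index_ = np.arange(X.shape[0])
        T, m = X.shape
        k = int(self.n_trends)
        if not 1 <= k <= max(m - 1, 1):  # m = 1, k = 1 is the local-level model
            raise ValueError(f"n_trends must be in [1, m-1]; got k={k}, m={m}")
        if T < 4:
            raise ValueError("need at least 4 time points")
        if (np.sum(~np.isnan(X), axis=0) < 2).any():
            raise ValueError("each series needs at least 2 non-missing values")
        if self.r_structure not in R_STRUCTURES:
            raise ValueError(f"unknown r_structure {self.r_structure!r}")

        Y = X.T.copy()  # m x T internally
        if self.zscore:
            self.means_ = np.nanmean(Y, axis=1)
            self.scales_ = np.nanstd(Y, axis=1, ddof=1)
            if np.any(self.scales_ == 0):
                raise ValueError("cannot z-score a constant series")
            Y = (Y - self.means_[:, None]) / self.scales_[:, None]
        else:
            self.means_ = np.zeros(m)
            self.scales_ = np.ones(m)

        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(self.n_restarts + 1):
            Z0, R0 = _moment_init(
                Y, k, self.r_structure, rng=rng, jitter=0.2 if restart else 0.0
            )
            fit = _em_fit(Y, k, self.r_structure, self.em_tol, self.max_iter,
                          self.init_var, Z0, R0)
            if best is None or fit[3][-1] > best[3][-1]:
                best = fit
        Z, R, trends, logliks, converged = best

        self.raw_loadings_ = Z
        self.raw_trends_ = trends
        self.obs_variance_ = R
        self.log_likelihood_ = float(logliks[-1])
        self.loglik_path_ = logliks
        self.converged_ = bool(converged)
        self.n_iter_ = len(logliks) - 1
        self.n_params_ = (m * k - k * (k - 1) // 2) + _n_r_params(self.r_structure, m)
        self.n_obs_ = int(np.sum(~np.isnan(Y)))
        self.aicc_ = aicc(self.log_likelihood_, self.n_params_, self.n_obs_)

        L_rot, x_rot, rot = varimax_rotate(Z, trends)
        L_rot, x_rot = _apply_sign_convention(L_rot, x_rot)
        self.loadings_ = L_rot
        self.trends_ = x_rot
        self.rotation_ = rot
        return self

    def fitted_values(self) -> np.ndarray:
        """Model-implied observations Z @ x on the (possibly z-scored) scale, (T, m)."""
        return (self.loadings_ @ self.trends_).T

    def transform(self, X=None) -> np.ndarray:
        """Return the rotated latent trends as a (T, k) matrix."""
        return self.trends_.T


@dataclass
class DFAFit:
    """One row of a DFA model-comparison table."""

    n_trends: int
    r_structure: str
    log_likelihood: float
    n_params: int
    aicc: float
    converged: bool
    model: DynamicFactorAnalysis = field(repr=False)
    delta_aicc: float = np.nan
    akaike_weight: float = np.nan
    cumulative_weight: float = np.nan


def dfa_model_search(
    data,
    k_range=None,
    structures=R_STRUCTURES,
    em_tol: float = 1e-6,
    max_iter: int = 2000,
    zscore: bool = True,
    n_restarts: int = 0,
    random_state: int | None = None,
) -> list[DFAFit]:
    """Fit every (k, R structure) candidate and rank by AICc.

    Default k ranges over 1..m-1, so 12 series yield 44 trials and 10 series
    36 trials over the four structures.  Returns DFAFit records sorted by
    AICc with delta-AICc, Akaike weights and cumulative weights filled in;
    non-converged fits are retained and flagged.
    """
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    m = X.shape[1]
    if k_range is None:
        k_range = range(1, m)
    fits = []
    for structure in structures:
        for k in k_range:
            model = DynamicFactorAnalysis(
                n_trends=k, r_structure=structure, em_tol=em_tol,
                max_iter=max_iter, zscore=zscore, n_restarts=n_restarts,
                random_state=random_state,
            ).fit(data)
            fits.append(
                DFAFit(
                    n_trends=k,
                    r_structure=structure,
                    log_likelihood=model.log_likelihood_,
                    n_params=model.n_params_,
                    aicc=model.aicc_,
                    converged=model.converged_,
                    model=model,
                )
            )
    fits.sort(key=lambda f: f.aicc)
    weights = akaike_weights([f.aicc for f in fits])
    cum = np.cumsum(weights)
    best = fits[0].aicc
    for f, w, c in zip(fits, weights, cum):
        f.delta_aicc = f.aicc - best
        f.akaike_weight = float(w)
        f.cumulative_weight = float(c)
    return fits


def model_table(fits: list[DFAFit]) -> pd.DataFrame:
    """Model-comparison table (one row per candidate, best first)."""
    return pd.DataFrame(
        {
            "r_structure": [f.r_structure for f in fits],
            "n_trends": [f.n_trends for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "delta_aicc": [f.delta_aicc for f in fits],
            "akaike_weight": [f.akaike_weight for f in fits],
            "cumulative_weight": [f.cumulative_weight for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
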