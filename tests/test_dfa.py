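"""DFA: AICc conventions, EM correctness, rotation, model search."""

import numpy as np
import pytest

from zooptrends.dfa import (
    DynamicFactorAnalysis,
    R_STRUCTURES,
    _kalman,
    aicc,
    akaike_weights,
    dfa_model_search,
    varimax_rotate,
)


def test_aicc_hand_example():
    # -2(-10) + 2*2 + 2*2*3/(20-3) = 24.7059
    assert aicc(-10.0, 2, 20) == pytest.approx(20 + 4 + 12 / 17)
    assert aicc(-10.0, 0, 20) == pytest.approx(20.0)
    with pytest.raises(ValueError):
        aicc(-10.0, 10, 11)


def test_aicc_reproduces_published_dfa_deltas():
    # 12 series x 23 years fully observed (n = 276); parameter counts:
    # loadings m*k - k(k-1)/2, plus 1 / 2 / 12 R parameters.  The published
    # model-comparison deltas for the zooplankton block follow exactly.
    n = 276
    a_de2 = aicc(-338.83, 23 + 1, n)   # diagonal & equal, 2 trends (best)
    a_du2 = aicc(-326.08, 23 + 12, n)  # diagonal & unequal, 2 trends
    a_ev2 = aicc(-338.83, 23 + 2, n)   # equal variance + covariance, 2 trends
    assert a_du2 - a_de2 == pytest.approx(2.21, abs=0.02)
    assert a_ev2 - a_de2 == pytest.approx(2.42, abs=0.02)
    # weights over the top trio: a worse-ranked model has a lower weight
    w = akaike_weights([a_de2, a_du2, a_ev2])
    assert w[0] > w[1] > w[2]


def test_akaike_weights():
    assert akaike_weights([12.3]) == pytest.approx([1.0])
    w = akaike_weights([100.0, 102.21])
    assert w == pytest.approx([0.751, 0.249], abs=5e-4)
    assert akaike_weights([5.0] * 4) == pytest.approx([0.25] * 4)


def _simulate_dfa(T, m, k, noise_sd, seed):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(size=(T, k)), axis=0)
    Z = rng.normal(size=(m, k))
    return (x @ Z.T + rng.normal(0, noise_sd, size=(T, m))), Z, x


def test_em_loglik_monotone_small_random_instances():
    rng = np.random.default_rng(0)
    for rep in range(20):
        m, T, k = 4, 15, int(rng.integers(1, 3))
        structure = R_STRUCTURES[rep % 4]
        Y, _, _ = _simulate_dfa(T, m, k, 0.8, rep)
        if rep % 3 == 0:
            Y[rng.uniform(size=Y.shape) < 0.1] = np.nan
        fit = DynamicFactorAnalysis(
            n_trends=k, r_structure=structure, max_iter=40
        ).fit(Y)
        diffs = np.diff(fit.loglik_path_)
        assert (diffs >= -1e-7 * (1 + np.abs(fit.loglik_path_[:-1]))).all()


def test_one_trend_recovery():
    Y, Z, x = _simulate_dfa(T=120, m=6, k=1, noise_sd=0.5, seed=3)
    fit = DynamicFactorAnalysis(n_trends=1, max_iter=400).fit(Y)
    r = abs(np.corrcoef(fit.trends_[0], x[:, 0])[0, 1])
    assert r > 0.95
    # undo the per-series z-scoring before comparing loadings with truth
    rl = abs(np.corrcoef(fit.loadings_[:, 0] * fit.scales_, Z[:, 0])[0, 1])
    assert rl > 0.95


def test_local_level_loglik_matches_independent_filter():
    # m = 1, k = 1 is a local-level model; re-derive the Gaussian likelihood
    # with a hand-coded scalar Kalman filter at the fitted parameters
    rng = np.random.default_rng(7)
    y = np.cumsum(rng.normal(size=30)) + rng.normal(0, 0.5, 30)
    fit = DynamicFactorAnalysis(n_trends=1, max_iter=150, zscore=True).fit(y[:, None])
    z = float(fit.raw_loadings_[0, 0])
    r = float(fit.obs_variance_[0, 0])
    ys = (y - fit.means_[0]) / fit.scales_[0]
    # scalar filter: x0 ~ N(0, 5), x_t = x_{t-1} + w, y_t = z x_t + v
    mean, var, ll = 0.0, 5.0, 0.0
    for obs in ys:
        var += 1.0
        f = z * var * z + r
        e = obs - z * mean
        ll += -0.5 * (np.log(2 * np.pi) + np.log(f) + e * e / f)
        gain = var * z / f
        mean += gain * e
        var *= 1 - gain * z
    assert fit.log_likelihood_ == pytest.approx(ll, abs=1e-8)


def test_varimax_preserves_fit_and_improves_criterion():
    rng = np.random.default_rng(11)
    L = rng.normal(size=(6, 2))
    x = rng.normal(size=(2, 30))

    def criterion(A):
        s = A**2
        return float(np.sum(s.var(axis=0)))

    L_rot, x_rot, rot = varimax_rotate(L, x)
    assert np.allclose(L_rot @ x_rot, L @ x, atol=1e-8)
    assert np.allclose(rot @ rot.T, np.eye(2), atol=1e-10)
    assert criterion(L_rot) >= criterion(L) - 1e-10
    # oracle: exhaustive scan over rotation angles (with sign flips) for k = 2
    best = -np.inf
    for theta in np.linspace(0, 2 * np.pi, 2881):
        c, s = np.cos(theta), np.sin(theta)
        for flip in (1.0, -1.0):
            Rm = np.array([[c, -s * flip], [s, c * flip]])
            best = max(best, criterion(L @ Rm))
    assert criterion(L_rot) == pytest.approx(best, abs=1e-4)


def test_varimax_identity_for_single_trend():
    L = np.array([[1.0], [2.0]])
    x = np.ones((1, 5))
    L_rot, x_rot, rot = varimax_rotate(L, x)
    assert np.array_equal(rot, np.eye(1))
    assert np.array_equal(L_rot, L)


def test_sign_convention_largest_loading_positive():
    Y, _, _ = _simulate_dfa(T=40, m=5, k=2, noise_sd=0.6, seed=5)
    fit = DynamicFactorAnalysis(n_trends=2, max_iter=150).fit(Y)
    for j in range(2):
        col = fit.loadings_[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_unconstrained_r_dominates_structured_at_same_k():
    Y, _, _ = _simulate_dfa(T=40, m=4, k=1, noise_sd=0.7, seed=9)
    lls = {
        s: DynamicFactorAnalysis(n_trends=1, r_structure=s, max_iter=400).fit(Y)
        .log_likelihood_
        for s in ("diagonal_equal", "unconstrained")
    }
    assert lls["unconstrained"] >= lls["diagonal_equal"] - 1e-3


def test_model_search_counts_and_ranking():
    Y, _, _ = _simulate_dfa(T=25, m=4, k=2, noise_sd=0.4, seed=13)
    fits = dfa_model_search(Y, max_iter=150)
    assert len(fits) == (4 - 1) * 4  # k = 1..m-1 over four structures
    aiccs = [f.aicc for f in fits]
    assert aiccs == sorted(aiccs)
    assert fits[0].delta_aicc == 0.0
    assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0)
    assert fits[-1].cumulative_weight == pytest.approx(1.0)


def test_missing_data_handled_and_counted():
    Y, _, _ = _simulate_dfa(T=30, m=5, k=1, noise_sd=0.5, seed=17)
    Y[::4, 2] = np.nan
    fit = DynamicFactorAnalysis(n_trends=1, max_iter=100).fit(Y)
    assert fit.n_obs_ == np.sum(~np.isnan(Y))
    assert np.isfinite(fit.log_likelihood_)


def test_invalid_inputs_rejected():
    Y = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        DynamicFactorAnalysis(n_trends=3).fit(Y)  # k must stay below m
    with pytest.raises(ValueError):
        DynamicFactorAnalysis(n_trends=1, r_structure="banana").fit(Y)
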