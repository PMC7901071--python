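"""Weibull-emission HMM: density primitives, likelihood, decoding, fitting
and diagnostics, checked against closed forms and exhaustive-path oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from imustate import (HMMParams, TransitionModel, compare_aic, emission_matrix,
                      fit_hmm, forward_loglik, label_states,
                      pseudo_residuals, stationary_distribution,
                      transition_matrices, viterbi, weibull_cdf,
                      weibull_logpdf)
from imustate.hmm import FitResult, n_free_parameters
from imustate.synthetic import (MODEL1_TPM, default_emission_params,
                                simulate_feature_windows)

FEATS = ("hf", "p5", "sh")


def _params(shapes, scales, gamma, delta, levels=("A",)):
    return HMMParams(n_states=len(delta), feature_names=FEATS[:np.atleast_2d(shapes).shape[1]],
                     shapes=shapes, scales=scales,
                     transition=TransitionModel.from_matrix(np.asarray(gamma),
                                                            levels=levels),
                     delta=np.asarray(delta, float))


def _random_instance(rng, T=None, S=3, F=2):
    T = T or rng.integers(1, 7)
    shapes = rng.uniform(0.6, 5.0, size=(S, F))
    scales = rng.uniform(0.3, 3.0, size=(S, F))
    G = rng.dirichlet(np.ones(S), size=S)
    delta = rng.dirichlet(np.ones(S))
    X = rng.uniform(0.05, 4.0, size=(T, F))
    miss = rng.random(T) < 0.15
    miss[0] = False
    return shapes, scales, G, delta, X, miss


def _brute_force(X, miss, shapes, scales, G, delta):
    """Exhaustive log-space sum/argmax over all state paths."""
    from scipy.special import logsumexp
    with np.errstate(divide="ignore"):
        logE = np.log(emission_matrix(X, miss, shapes, scales))
        # rebuild extreme log-densities analytically to dodge underflow
        for t in range(len(X)):
            if not miss[t]:
                for s in range(shapes.shape[0]):
                    logE[t, s] = sum(
                        weibull_logpdf(X[t, f], shapes[s, f], scales[s, f])
                        for f in range(X.shape[1]))
        lG, ld = np.log(G), np.log(delta)
    T, S = logE.shape
    logps = []
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=T):
        lp = ld[path[0]] + logE[0, path[0]]
        for t in range(1, T):
            lp += lG[path[t - 1], path[t]] + logE[t, path[t]]
        logps.append(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return float(logsumexp(logps)), np.array(best_path)


# ---------------------------------------------------------------------------
# Weibull primitives
# ---------------------------------------------------------------------------

def test_weibull_logpdf_exponential_special_case():
    assert weibull_logpdf(1.0, 1.0, 1.0) == pytest.approx(-1.0, abs=1e-14)


@pytest.mark.parametrize("k", [0.5, 1.0, 2.0, 5.0])
@pytest.mark.parametrize("lam", [0.5, 1.0, 3.0])
def test_weibull_density_integrates_to_one(k, lam):
    # upper limit where the survival function reaches 1e-12 (for k = 0.5
    # the tail is heavy and stretches to ~760 scale units)
    hi = lam * (-np.log(1e-12)) ** (1.0 / k)
    val = sum(integrate.quad(lambda x: np.exp(weibull_logpdf(x, k, lam)),
                             a, b, limit=200)[0]
              for a, b in [(1e-300, lam), (lam, hi)])
    assert val == pytest.approx(1.0, abs=1e-6)


def test_weibull_median_closed_form():
    for k, lam in [(0.5, 0.5), (2.0, 1.3), (5.0, 3.0)]:
        med = lam * np.log(2.0) ** (1.0 / k)
        assert weibull_cdf(med, k, lam) == pytest.approx(0.5, abs=1e-12)


def test_weibull_logpdf_matches_scipy_reference():
    rng = np.random.default_rng(0)
    for _ in range(20):
        k, lam, x = rng.uniform(0.3, 6), rng.uniform(0.1, 5), rng.uniform(0.01, 10)
        assert weibull_logpdf(x, k, lam) == pytest.approx(
            stats.weibull_min.logpdf(x, k, scale=lam), rel=1e-12, abs=1e-10)


def test_weibull_logpdf_rejects_nonpositive_x():
    with pytest.raises(ValueError, match="x > 0"):
        weibull_logpdf(0.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def test_emission_single_feature_equals_scalar_density():
    E = emission_matrix(np.array([[0.7]]), np.array([False]),
                        np.array([[1.5], [2.5]]), np.array([[1.0], [0.5]]))
    assert E[0, 0] == pytest.approx(np.exp(weibull_logpdf(0.7, 1.5, 1.0)))
    assert E[0, 1] == pytest.approx(np.exp(weibull_logpdf(0.7, 2.5, 0.5)))


def test_missing_window_contributes_all_ones_row():
    X = np.array([[0.7, 1.2], [1.0, 1.0], [0.4, 2.0]])
    miss = np.array([False, True, False])
    shapes = np.array([[1.5, 2.0], [2.5, 0.8]])
    scales = np.array([[1.0, 1.0], [0.5, 2.0]])
    E = emission_matrix(X, miss, shapes, scales)
    assert np.allclose(E[1], 1.0)


def test_conditionally_independent_features_factorize():
    rng = np.random.default_rng(1)
    X = rng.uniform(0.1, 3, size=(4, 2))
    miss = np.zeros(4, bool)
    shapes = rng.uniform(0.5, 4, (3, 2))
    scales = rng.uniform(0.3, 3, (3, 2))
    E = emission_matrix(X, miss, shapes, scales)
    E0 = emission_matrix(X[:, :1], miss, shapes[:, :1], scales[:, :1])
    E1 = emission_matrix(X[:, 1:], miss, shapes[:, 1:], scales[:, 1:])
    assert np.max(np.abs(E - E0 * E1)) < 1e-12


def test_nan_in_non_missing_row_rejected():
    X = np.array([[0.7], [np.nan]])
    with pytest.raises(ValueError, match="row 1"):
        emission_matrix(X, np.array([False, False]),
                        np.array([[1.0]]), np.array([[1.0]]))


# ---------------------------------------------------------------------------
# transition model
# ---------------------------------------------------------------------------

def test_zero_coefficients_give_uniform_rows():
    tm = TransitionModel(n_states=3)
    assert np.allclose(tm.gamma("A"), 1 / 3)


def test_large_negative_intercepts_give_near_identity():
    beta0 = np.full((3, 3), -10.0)
    tm = TransitionModel(n_states=3, beta0=beta0)
    G = tm.gamma("A")
    assert np.all(np.diag(G) > 0.9999)


def test_link_inversion_reproduces_published_matrix():
    tm = TransitionModel.from_matrix(MODEL1_TPM)
    assert np.max(np.abs(tm.gamma("A") - MODEL1_TPM)) < 1e-12
    assert np.allclose(tm.gamma("A").sum(axis=1), 1.0, atol=1e-12)


def test_unknown_covariate_level_rejected():
    tm = TransitionModel(n_states=3, levels=("A", "B"))
    with pytest.raises(ValueError, match="unknown"):
        transition_matrices(tm, "C")


def test_covariate_offsets_shift_only_their_level():
    beta = np.zeros((3, 3))
    beta[0, 1] = 1.0
    tm = TransitionModel(n_states=3, levels=("A", "B"),
                         beta_level={"B": beta})
    GA, GB = tm.gamma("A"), tm.gamma("B")
    assert np.allclose(GA, 1 / 3)
    assert GB[0, 1] > GA[0, 1]
    assert np.allclose(GB.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# forward likelihood and Viterbi vs exhaustive oracle
# ---------------------------------------------------------------------------

def test_single_step_forward_is_mixture_density():
    rng = np.random.default_rng(2)
    shapes, scales, G, delta, X, miss = _random_instance(rng, T=1)
    p = _params(shapes, scales, G, delta)
    E = emission_matrix(X, miss, shapes, scales)
    assert forward_loglik([(X, miss, "A")], p) == \
        pytest.approx(np.log(np.sum(delta * E[0])), abs=1e-12)


def test_forward_and_viterbi_match_exhaustive_enumeration():
    """200 random small instances: scaled forward equals the brute-force
    path sum to 1e-10 and Viterbi equals the brute-force argmax exactly."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        shapes, scales, G, delta, X, miss = _random_instance(rng)
        p = _params(shapes, scales, G, delta)
        ll_brute, path_brute = _brute_force(X, miss, shapes, scales, G, delta)
        ll = forward_loglik([(X, miss, "A")], p)
        assert ll == pytest.approx(ll_brute, abs=1e-10)
        path = viterbi([(X, miss, "A")], p)[0]
        assert (path == path_brute).all()


def test_identical_emissions_make_loglik_transition_free():
    rng = np.random.default_rng(3)
    S, T = 3, 40
    shapes = np.tile(rng.uniform(0.8, 3, (1, 2)), (S, 1))
    scales = np.tile(rng.uniform(0.5, 2, (1, 2)), (S, 1))
    X = rng.uniform(0.1, 3, size=(T, 2))
    miss = np.zeros(T, bool)
    for G in [np.full((S, S), 1 / S), rng.dirichlet(np.ones(S), S)]:
        p = _params(shapes, scales, G, np.full(S, 1 / S))
        expected = emission_matrix(X, miss, shapes, scales)[:, 0]
        assert forward_loglik([(X, miss, "A")], p) == \
            pytest.approx(np.log(expected).sum(), abs=1e-8)


def test_empty_chain_rejected():
    p = _params(np.ones((3, 2)), np.ones((3, 2)), np.full((3, 3), 1 / 3),
                np.full(3, 1 / 3))
    with pytest.raises(ValueError, match="empty"):
        forward_loglik([(np.zeros((0, 2)), np.zeros(0, bool), "A")], p)


def test_loglik_invariant_under_state_permutation():
    rng = np.random.default_rng(4)
    shapes, scales, G, delta, X, miss = _random_instance(rng, T=30)
    p = _params(shapes, scales, G, delta)
    ll = forward_loglik([(X, miss, "A")], p)
    perm = np.array([2, 0, 1])
    p2 = _params(shapes[perm], scales[perm], G[np.ix_(perm, perm)],
                 delta[perm])
    assert forward_loglik([(X, miss, "A")], p2) == pytest.approx(ll, abs=1e-10)


def test_viterbi_absorbing_initial_state_forces_constant_path():
    rng = np.random.default_rng(5)
    shapes, scales, _, _, X, miss = _random_instance(rng, T=6)
    p = _params(shapes, scales, np.eye(3), np.array([1.0, 0.0, 0.0]))
    assert (viterbi([(X, miss, "A")], p)[0] == 0).all()


def test_viterbi_uniform_chain_reduces_to_emission_argmax():
    rng = np.random.default_rng(6)
    shapes, scales, _, _, X, miss = _random_instance(rng, T=12)
    p = _params(shapes, scales, np.full((3, 3), 1 / 3), np.full(3, 1 / 3))
    E = emission_matrix(X, miss, shapes, scales)
    assert (viterbi([(X, miss, "A")], p)[0] == np.argmax(E, axis=1)).all()


def test_viterbi_beats_random_paths():
    rng = np.random.default_rng(7)
    shapes, scales, G, delta, X, miss = _random_instance(rng, T=6)
    p = _params(shapes, scales, G, delta)
    path = viterbi([(X, miss, "A")], p)[0]
    with np.errstate(divide="ignore"):
        E = np.log(emission_matrix(X, miss, shapes, scales))
        lG, ld = np.log(G), np.log(delta)

    def joint(pp):
        v = ld[pp[0]] + E[0, pp[0]]
        for t in range(1, len(pp)):
            v += lG[pp[t - 1], pp[t]] + E[t, pp[t]]
        return v

    best = joint(path)
    for _ in range(1000):
        assert joint(rng.integers(0, 3, size=len(path))) <= best + 1e-12


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_fit():
    shapes, scales = default_emission_params()
    delta = stationary_distribution(MODEL1_TPM)
    tab, truth = simulate_feature_windows(shapes, scales, {"A": MODEL1_TPM},
                                          delta, 5, 400, seed=31)
    fit = fit_hmm(tab, covariate=False, n_restarts=6, seed=2)
    return tab, truth, fit, shapes, scales


def test_fit_is_deterministic_for_fixed_seed(small_fit):
    tab, _, fit, _, _ = small_fit
    fit2 = fit_hmm(tab, covariate=False, n_restarts=6, seed=2)
    assert fit2.loglik == fit.loglik
    assert fit2.restart_logliks == fit.restart_logliks
    assert np.array_equal(fit2.params.shapes, fit.params.shapes)


def test_fit_recovers_generating_parameters(small_fit):
    tab, truth, fit, shapes, scales = small_fit
    mapping = label_states(fit)
    inv = {v: k for k, v in mapping.items()}
    order = [inv["flap"], inv["soar"], inv["water"]]
    assert np.max(np.abs(fit.params.shapes[order] - shapes) / shapes) < 0.10
    assert np.max(np.abs(fit.params.scales[order] - scales) / scales) < 0.10
    G = fit.params.transition.gamma(fit.params.transition.levels[0])
    assert np.max(np.abs(G[np.ix_(order, order)] - MODEL1_TPM)) < 0.05


def test_best_of_k_restarts_is_monotone(small_fit):
    _, _, fit, _, _ = small_fit
    lls = np.array(fit.restart_logliks)
    assert (np.maximum.accumulate(lls) <= fit.loglik + 1e-9).all()


def test_aic_uses_free_parameter_count(small_fit):
    _, _, fit, _, _ = small_fit
    k = n_free_parameters(3, 3, 1)
    assert k == 3 * 3 * 2 + 3 * 2 * 1 + 2
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)


def test_one_state_fit_matches_univariate_weibull_mle():
    """With a single state the HMM collapses to independent Weibull fits;
    a high-precision score-equation solve is the oracle."""
    from scipy.optimize import brentq
    rng = np.random.default_rng(8)
    x = 1.3 * rng.weibull(2.2, size=600)
    tab = pd.DataFrame({"individual_id": "a", "window_index": np.arange(600),
                        "covariate": "A", "missing": False, "hf": x})
    fit = fit_hmm(tab, feature_set=("hf",), covariate=False, n_states=1,
                  n_restarts=3, seed=0)
    lx = np.log(x)

    def score(k):
        xk = x ** k
        return 1.0 / k + lx.mean() - np.sum(xk * lx) / np.sum(xk)

    k_hat = brentq(score, 0.1, 50.0, xtol=1e-12)
    lam_hat = (np.mean(x ** k_hat)) ** (1.0 / k_hat)
    ll_oracle = weibull_logpdf(x, k_hat, lam_hat).sum()
    assert fit.loglik == pytest.approx(ll_oracle, abs=1e-6)


def test_label_mapping_is_a_bijection(small_fit):
    _, _, fit, _, _ = small_fit
    mapping = label_states(fit)
    assert sorted(mapping.keys()) == [0, 1, 2]
    assert sorted(mapping.values()) == ["flap", "soar", "water"]


def test_compare_aic_identical_and_mismatched():
    p = _params(np.ones((2, 1)), np.ones((2, 1)), np.full((2, 2), 0.5),
                np.array([0.5, 0.5]))
    a = FitResult(params=p, loglik=-100.0, aic=210.0, n_free_params=5,
                  restart_logliks=[-100.0], converged=[True], n_stable=1,
                  data_hash="x", feature_set=("hf",), covariate=False)
    b = FitResult(params=p, loglik=-100.0, aic=212.0, n_free_params=6,
                  restart_logliks=[-100.0], converged=[True], n_stable=1,
                  data_hash="x", feature_set=("hf",), covariate=True)
    pref, d = compare_aic(a, b)
    assert pref is a and d == pytest.approx(-2.0)  # one extra parameter
    pref, d = compare_aic(a, a)
    assert d == 0.0
    c = FitResult(**{**a.__dict__, "data_hash": "y"})
    with pytest.raises(ValueError, match="hash"):
        compare_aic(a, c)


# ---------------------------------------------------------------------------
# pseudo-residuals
# ---------------------------------------------------------------------------

def test_single_observation_residual_is_probit_of_cdf():
    p = _params(np.array([[2.0]]), np.array([[1.5]]), np.array([[1.0]]),
                np.array([1.0]))
    x = 0.8
    res = pseudo_residuals([(np.array([[x]]), np.array([False]), "A")], p)
    expected = stats.norm.ppf(weibull_cdf(x, 2.0, 1.5))
    assert res.iloc[0]["hf"] == pytest.approx(expected, abs=1e-10)


def test_pseudo_residuals_calibrated_under_truth_and_powerful_under_misfit():
    """Under the generating model, forecast residuals pass a KS test against
    the standard normal in >= 95/100 replicates at alpha = 0.01; halving all
    shapes makes the test reject in >= 95/100."""
    shapes, scales = default_emission_params()
    delta = stationary_distribution(MODEL1_TPM)
    p_true = HMMParams(n_states=3, feature_names=FEATS, shapes=shapes,
                       scales=scales,
                       transition=TransitionModel.from_matrix(MODEL1_TPM),
                       delta=delta)
    p_bad = HMMParams(n_states=3, feature_names=FEATS, shapes=shapes / 2.0,
                      scales=scales,
                      transition=TransitionModel.from_matrix(MODEL1_TPM),
                      delta=delta)
    pass_true = pass_bad_reject = 0
    for rep in range(100):
        tab, _ = simulate_feature_windows(shapes, scales, {"A": MODEL1_TPM},
                                          delta, 1, 1000, seed=1000 + rep)
        chain = [(tab[list(FEATS)].to_numpy(), np.zeros(1000, bool), "A")]
        r_true = pseudo_residuals(chain, p_true)["hf"].to_numpy()
        r_bad = pseudo_residuals(chain, p_bad)["hf"].to_numpy()
        if stats.kstest(r_true, "norm").pvalue > 0.01:
            pass_true += 1
        if stats.kstest(r_bad, "norm").pvalue <= 0.01:
            pass_bad_reject += 1
    assert pass_true >= 95
    assert pass_bad_reject >= 95


def test_missing_windows_yield_missing_residuals():
    p = _params(np.array([[2.0], [1.0]]), np.array([[1.5], [0.5]]),
                np.full((2, 2), 0.5), np.array([0.5, 0.5]))
    X = np.array([[0.8], [1.0], [0.3]])
    miss = np.array([False, True, False])
    res = pseudo_residuals([(X, miss, "A")], p)
    assert np.isnan(res.iloc[1]["hf"]) and np.isfinite(res.iloc[2]["hf"])
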