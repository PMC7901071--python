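"""N-state hidden Markov model with per-feature Weibull emissions.

The observation model treats each 30-s feature window as one time step.
Given hidden state ``i``, features are conditionally independent, each
following a Weibull distribution with state- and feature-specific shape
``k`` and scale ``lam``.  Transition probabilities follow a row-wise
multinomial logit with the diagonal as reference (eta_ii = 0); a categorical
covariate (e.g. species) can shift the off-diagonal logits additively.
Individuals are independent realizations of a common model.

Estimation maximizes the scaled forward likelihood over an unconstrained
parameterization (log shapes/scales, transition logits, additive-log-ratio
initial distribution) with a quasi-Newton routine (L-BFGS-B).  Gradients
are exact: by the Fisher identity the score is the posterior expectation of
the complete-data score, which one forward-backward pass provides.  A
simplex (Nelder-Mead) fallback handles quasi-Newton failures.  The best of
``n_restarts`` random starts is returned, together with a numerical
stability report (how many restarts reached the same maximum).

Missing windows contribute an all-ones emission factor, so parameters are
informed by non-missing observations only while the transition structure
still bridges short gaps; runs of missingness longer than a configurable
threshold split an individual's chain into separate segments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

try:  # optional JIT acceleration of the forward-backward recursions
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]

FEATURE_FLOOR = 1e-6
_EXP_CLIP = 600.0  # cap on (x/scale)^shape exponents to keep log-densities finite


# ---------------------------------------------------------------------------
# Weibull primitives
# ---------------------------------------------------------------------------

def weibull_logpdf(x, shape, scale):
    """Log-density of the Weibull distribution, elementwise.

    ``f(x) = (k/lam) (x/lam)^(k-1) exp(-(x/lam)^k)`` for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Weibull log-density requires x > 0 (pre-floor features)")
    if np.any(np.asarray(shape) <= 0) or np.any(np.asarray(scale) <= 0):
        raise ValueError("shape and scale must be positive")
    u = np.log(x) - np.log(scale)
    return np.log(shape) - np.log(scale) + (shape - 1.0) * u - np.exp(shape * u)


def weibull_cdf(x, shape, scale):
    x = np.asarray(x, dtype=float)
    return -np.expm1(-np.power(np.maximum(x, 0.0) / scale, shape))


def weibull_mean(shape, scale):
    return scale * special.gamma(1.0 + 1.0 / shape)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Row-wise multinomial-logit transition model with a categorical covariate.

    ``eta_ij(level) = beta0_ij + beta_level_ij`` for i != j (``beta_level`` is
    zero for the reference level, the first in ``levels``), ``eta_ii = 0``,
    and ``gamma_ij = exp(eta_ij) / sum_j exp(eta_ij)``.
    """

    n_states: int
    levels: tuple = ("A",)
    beta0: np.ndarray = None  # type: ignore[assignment]
    beta_level: dict = field(default_factory=dict)  # level -> (S, S) offsets

    def __post_init__(self) -> None:
        if self.beta0 is None:
            self.beta0 = np.zeros((self.n_states, self.n_states))
        self.beta0 = np.asarray(self.beta0, dtype=float)

    def gamma(self, level: str) -> np.ndarray:
        """Transition probability matrix for one covariate level."""
        if level not in self.levels:
            raise ValueError(f"unknown covariate level {level!r}")
        eta = self.beta0.copy()
        if level != self.levels[0]:
            eta = eta + self.beta_level.get(level, 0.0)
        np.fill_diagonal(eta, 0.0)
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    @staticmethod
    def from_matrix(gamma: np.ndarray, levels: tuple = ("A",)) -> "TransitionModel":
        """Invert the logit link for a single positive row-stochastic matrix."""
        gamma = np.asarray(gamma, dtype=float)
        with np.errstate(divide="ignore"):
            beta0 = np.log(gamma / np.diag(gamma)[:, None])
        np.fill_diagonal(beta0, 0.0)
        return TransitionModel(n_states=gamma.shape[0], levels=levels, beta0=beta0)


def transition_matrices(model: TransitionModel, covariate_level: str) -> np.ndarray:
    return model.gamma(covariate_level)


@dataclass
class EmissionParams:
    """Per-state, per-feature Weibull shape/scale parameters."""

    feature_names: tuple
    shapes: np.ndarray  # (S, F)
    scales: np.ndarray  # (S, F)

    def __post_init__(self) -> None:
        self.shapes = np.atleast_2d(np.asarray(self.shapes, dtype=float))
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=float))
        if self.shapes.shape != self.scales.shape:
            raise ValueError("shapes and scales must have matching dimensions")
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("Weibull shapes and scales must be strictly positive")


@dataclass
class HMMParams:
    """Full parameter set: emissions, transition model, initial distribution."""

    n_states: int
    feature_names: tuple
    shapes: np.ndarray  # (S, F)
    scales: np.ndarray  # (S, F)
    transition: TransitionModel
    delta: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        self.shapes = np.atleast_2d(np.asarray(self.shapes, dtype=float))
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=float))
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("Weibull shapes and scales must be strictly positive")
        if abs(self.delta.sum() - 1.0) > 1e-8:
            raise ValueError("initial distribution must sum to 1")

    def to_json_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "feature_names": list(self.feature_names),
            "shapes": self.shapes.tolist(),
            "scales": self.scales.tolist(),
            "delta": self.delta.tolist(),
            "transition": {
                "levels": list(self.transition.levels),
                "reference_level": self.transition.levels[0],
                "link": "multinomial-logit, diagonal reference",
                "beta0": self.transition.beta0.tolist(),
                "beta_level": {k: np.asarray(v).tolist()
                               for k, v in self.transition.beta_level.items()},
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "HMMParams":
        tr = d["transition"]
        tm = TransitionModel(
            n_states=d["n_states"],
            levels=tuple(tr["levels"]),
            beta0=np.asarray(tr["beta0"], dtype=float),
            beta_level={k: np.asarray(v, dtype=float)
                        for k, v in tr["beta_level"].items()},
        )
        return cls(
            n_states=d["n_states"],
            feature_names=tuple(d["feature_names"]),
            shapes=np.asarray(d["shapes"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            transition=tm,
            delta=np.asarray(d["delta"], dtype=float),
        )


@dataclass
class FitResult:
    params: HMMParams
    loglik: float
    aic: float
    n_free_params: int
    restart_logliks: list
    converged: list
    n_stable: int
    data_hash: str
    feature_set: tuple
    covariate: bool


def n_free_parameters(n_states: int, n_features: int, n_levels: int) -> int:
    return (n_states * n_features * 2
            + n_states * (n_states - 1) * n_levels
            + (n_states - 1))


# ---------------------------------------------------------------------------
# chain preparation
# ---------------------------------------------------------------------------

def prepare_chains(table: pd.DataFrame, feature_set, floor: float = FEATURE_FLOOR,
                   missing_split_run: int = 10, return_index: bool = False):
    """FeatureTable -> list of (X, missing, level) chains in time order.

    Features are floored into the Weibull support.  NaN features in a
    non-missing row are rejected; runs of missingness longer than
    ``missing_split_run`` split the chain (the long run itself is dropped).
    With ``return_index`` each chain additionally carries
    ``(individual_id, window_index array)``.
    """
    chains = []
    for ind, g in table.groupby("individual_id", sort=True):
        g = g.sort_values("window_index")
        X = g[list(feature_set)].to_numpy(dtype=float)
        missing = g["missing"].to_numpy(dtype=bool) if "missing" in g else np.zeros(len(g), bool)
        widx = g["window_index"].to_numpy()
        bad = ~missing & ~np.all(np.isfinite(X), axis=1)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"individual {ind}: NaN feature in non-missing row {idx}"
            )
        X = np.where(missing[:, None], 1.0, np.maximum(X, floor))
        level = str(g["covariate"].iloc[0]) if "covariate" in g else "A"
        # split on long missing runs
        start = 0
        run = 0
        segments = []
        for t in range(len(g) + 1):
            m = missing[t] if t < len(g) else False
            if m:
                run += 1
            else:
                if run > missing_split_run:
                    cut_end = t - run
                    if cut_end > start:
                        segments.append((start, cut_end))
                    start = t
                run = 0
        segments.append((start, len(g)))
        for a, b in segments:
            if b - a >= 1:
                chain = (X[a:b], missing[a:b], level)
                if return_index:
                    chain = chain + (ind, widx[a:b])
                chains.append(chain)
    if not chains:
        raise ValueError("no non-empty chains")
    return chains


def _pack_chains(chains, levels):
    C = len(chains)
    Tmax = max(len(x) for x, _, _ in chains)
    F = chains[0][0].shape[1]
    X = np.ones((C, Tmax, F))
    obs = np.zeros((C, Tmax), dtype=bool)      # real, non-missing steps
    inchain = np.zeros((C, Tmax), dtype=bool)  # real steps
    lv = np.zeros(C, dtype=int)
    level_index = {l: i for i, l in enumerate(levels)}
    for c, (x, miss, level) in enumerate(chains):
        T = len(x)
        X[c, :T] = x
        inchain[c, :T] = True
        obs[c, :T] = ~miss
        lv[c] = level_index[level]
    trans = inchain[:, :-1] & inchain[:, 1:]
    return X, obs, inchain, trans, lv


# ---------------------------------------------------------------------------
# emission factors
# ---------------------------------------------------------------------------

def emission_matrix(X: np.ndarray, missing: np.ndarray, shapes: np.ndarray,
                    scales: np.ndarray) -> np.ndarray:
    """Per-window per-state likelihood factors (linear scale).

    Row ``t``, state ``i`` holds the product over features of the Weibull
    density; a missing window contributes an all-ones row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    missing = np.asarray(missing, dtype=bool)
    bad = ~missing & ~np.all(np.isfinite(X), axis=1)
    if bad.any():
        raise ValueError(f"NaN feature in non-missing row {int(np.flatnonzero(bad)[0])}")
    logE = _log_emissions(X[None, ...], (~missing)[None, ...], shapes, scales)[0]
    return np.exp(logE)


def _log_emissions(X, obs, shapes, scales, logx=None):
    """(C, T, S) log emission factors; 0 where not observed.

    Exponents are capped so that an observation far outside a state's
    support yields a finite (astronomically negative) log-density instead
    of propagating infinities through the scaled recursions.
    """
    S, F = shapes.shape
    C, T, _ = X.shape
    logE = np.zeros((C, T, S))
    if logx is None:
        logx = np.log(np.where(obs[..., None], X, 1.0))
    for s in range(S):
        acc = np.zeros((C, T))
        for f in range(F):
            k, lam = shapes[s, f], scales[s, f]
            u = logx[..., f] - np.log(lam)
            acc += (np.log(k) - np.log(lam) + (k - 1.0) * u
                    - np.exp(np.minimum(k * u, _EXP_CLIP)))
        logE[..., s] = np.where(obs, acc, 0.0)
    return logE


# ---------------------------------------------------------------------------
# JIT-compiled recursions (pure-python fallback when numba is unavailable)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _forward_kernel(El, G, delta, A, c_scale):  # pragma: no cover - compiled
    C, T, S = El.shape
    for c in range(C):
        tot = 0.0
        for s in range(S):
            A[c, 0, s] = delta[s] * El[c, 0, s]
            tot += A[c, 0, s]
        c_scale[c, 0] = tot
        for s in range(S):
            A[c, 0, s] /= tot
        for t in range(1, T):
            tot = 0.0
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += A[c, t - 1, i] * G[c, i, j]
                acc *= El[c, t, j]
                A[c, t, j] = acc
                tot += acc
            c_scale[c, t] = tot
            for j in range(S):
                A[c, t, j] /= tot


@njit(cache=False)
def _backward_kernel(El, G, c_scale, B):  # pragma: no cover - compiled
    C, T, S = El.shape
    for c in range(C):
        for s in range(S):
            B[c, T - 1, s] = 1.0
        for t in range(T - 2, -1, -1):
            for i in range(S):
                acc = 0.0
                for j in range(S):
                    acc += G[c, i, j] * El[c, t + 1, j] * B[c, t + 1, j]
                B[c, t, i] = acc / c_scale[c, t + 1]


@njit(cache=False)
def _xi_kernel(A, B, El, G, c_scale, trans, lv, n_levels):  # pragma: no cover
    C, T, S = El.shape
    out = np.zeros((n_levels, S, S))
    for c in range(C):
        li = lv[c]
        for t in range(T - 1):
            if not trans[c, t]:
                continue
            inv_c = 1.0 / c_scale[c, t + 1]
            for i in range(S):
                ai = A[c, t, i]
                for j in range(S):
                    out[li, i, j] += (ai * G[c, i, j] * El[c, t + 1, j]
                                      * B[c, t + 1, j] * inv_c)
    return out


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward_backward(X, obs, trans, lv, gammas, delta, shapes, scales,
                      want_grad=False, logx=None):
    """Scaled forward(-backward) pass over the padded chain batch.

    Padded steps carry all-ones emissions; because the transition matrices
    are row-stochastic they are transparent to both the likelihood and the
    backward recursion, so only the posterior accumulations need masks.
    """
    C, T, _ = X.shape
    S = delta.shape[0]
    logE = _log_emissions(X, obs, shapes, scales, logx=logx)
    m = logE.max(axis=2)
    El = np.exp(logE - m[..., None])
    G = np.ascontiguousarray(gammas[lv])  # (C, S, S)

    A = np.empty((C, T, S))
    c_scale = np.empty((C, T))
    _forward_kernel(El, G, np.asarray(delta, dtype=float), A, c_scale)
    loglik = float(np.log(c_scale).sum() + m.sum())
    if not want_grad:
        return loglik, A, c_scale, El, m, None

    B = np.empty((C, T, S))
    _backward_kernel(El, G, c_scale, B)
    W = A * B
    W = W / np.maximum(W.sum(axis=2, keepdims=True), 1e-300)
    return loglik, A, c_scale, El, m, (B, W, G, logE)


def forward_loglik(table_or_chains, params: HMMParams,
                   floor: float = FEATURE_FLOOR,
                   missing_split_run: int = 10) -> float:
    """Total log-likelihood over individuals (scaled forward algorithm)."""
    chains = _as_chains(table_or_chains, params, floor, missing_split_run)
    levels = params.transition.levels
    X, obs, inchain, trans, lv = _pack_chains(chains, levels)
    gammas = np.stack([params.transition.gamma(l) for l in levels])
    ll, *_ = _forward_backward(X, obs, trans, lv, gammas, params.delta,
                               params.shapes, params.scales)
    return ll


def _as_chains(table_or_chains, params, floor, missing_split_run):
    if isinstance(table_or_chains, pd.DataFrame):
        return prepare_chains(table_or_chains, params.feature_names, floor,
                              missing_split_run)
    chains = table_or_chains
    if not chains or any(len(x) == 0 for x, _, _ in chains):
        raise ValueError("empty chain")
    return chains


# ---------------------------------------------------------------------------
# packed objective with analytic gradient
# ---------------------------------------------------------------------------

class _Objective:
    def __init__(self, chains, feature_set, levels, n_states, delta_mode="estimate"):
        self.S = n_states
        self.F = len(feature_set)
        self.levels = tuple(levels)
        self.L = len(self.levels)
        self.delta_mode = delta_mode
        self.X, self.obs, self.inchain, self.trans, self.lv = _pack_chains(
            chains, self.levels)
        self.logx = np.log(np.where(self.obs[..., None], self.X, 1.0))
        self.off = ~np.eye(self.S, dtype=bool)
        self.n_off = self.S * (self.S - 1)

    # packing: [log k (S*F), log lam (S*F), beta0 (S(S-1)),
    #           beta_level per non-reference level (S(S-1)), alr (S-1)]
    def pack(self, shapes, scales, beta0, beta_level, alr):
        parts = [np.log(shapes).ravel(), np.log(scales).ravel(),
                 beta0[self.off]]
        for l in self.levels[1:]:
            parts.append(np.asarray(beta_level[l])[self.off])
        parts.append(alr)
        return np.concatenate(parts)

    def unpack(self, theta):
        S, F = self.S, self.F
        i = 0
        shapes = np.exp(theta[i:i + S * F]).reshape(S, F); i += S * F
        scales = np.exp(theta[i:i + S * F]).reshape(S, F); i += S * F
        beta0 = np.zeros((S, S))
        beta0[self.off] = theta[i:i + self.n_off]; i += self.n_off
        beta_level = {}
        for l in self.levels[1:]:
            b = np.zeros((S, S))
            b[self.off] = theta[i:i + self.n_off]; i += self.n_off
            beta_level[l] = b
        alr = theta[i:i + S - 1]
        tm = TransitionModel(n_states=S, levels=self.levels, beta0=beta0,
                             beta_level=beta_level)
        e = np.exp(np.concatenate([[0.0], alr]))
        delta = e / e.sum()
        return shapes, scales, tm, delta

    def bounds(self):
        S, F = self.S, self.F
        b = ([(np.log(0.05), np.log(200.0))] * (S * F)
             + [(np.log(1e-7), np.log(1e4))] * (S * F)
             + [(-15.0, 15.0)] * (self.n_off * self.L)
             + [(-15.0, 15.0)] * (S - 1))
        return b

    def __call__(self, theta):
        shapes, scales, tm, delta = self.unpack(theta)
        gammas = np.stack([tm.gamma(l) for l in self.levels])
        if self.delta_mode == "stationary":
            delta = stationary_distribution(gammas[0])
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll, A, c_scale, El, m, extra = _forward_backward(
                self.X, self.obs, self.trans, self.lv, gammas, delta,
                shapes, scales, want_grad=True, logx=self.logx)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        B, W, G, logE = extra
        S, F = self.S, self.F

        # emission gradients (exponents capped: states far from an
        # observation carry vanishing posterior weight anyway)
        g_logk = np.zeros((S, F))
        g_loglam = np.zeros((S, F))
        for s in range(S):
            ws = np.where(self.obs, W[..., s], 0.0)
            for f in range(F):
                k, lam = shapes[s, f], scales[s, f]
                u = self.logx[..., f] - np.log(lam)
                eku = np.exp(np.minimum(k * u, 80.0))
                g_logk[s, f] = np.sum(ws * (1.0 + k * u * (1.0 - eku)))
                g_loglam[s, f] = np.sum(ws * (k * (eku - 1.0)))

        # expected transition counts per covariate level
        xi_level = _xi_kernel(A, B, El, G, c_scale, self.trans, self.lv,
                              self.L)
        g_eta = np.zeros((self.L, S, S))
        for li in range(self.L):
            xs = xi_level[li]
            g = xs - gammas[li] * xs.sum(axis=1, keepdims=True)
            np.fill_diagonal(g, 0.0)
            g_eta[li] = g
        g_beta0 = g_eta.sum(axis=0)
        g_beta_level = {l: g_eta[li] for li, l in enumerate(self.levels) if li > 0}

        # initial distribution (additive log ratio); zero in stationary mode
        first = W[:, 0, :]
        if self.delta_mode == "stationary":
            g_alr = np.zeros(S - 1)
        else:
            g_full = first.sum(axis=0) - len(first) * delta
            g_alr = g_full[1:]

        grad = np.concatenate(
            [g_logk.ravel(), g_loglam.ravel(), g_beta0[self.off]]
            + [g_beta_level[l][self.off] for l in self.levels[1:]]
            + [g_alr])
        if not np.all(np.isfinite(grad)):
            return 1e12, np.zeros_like(theta)
        return -ll, -grad


def stationary_distribution(gamma: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix by power iteration."""
    v = np.full(gamma.shape[0], 1.0 / gamma.shape[0])
    for _ in range(n_iter):
        v = v @ gamma
        v = v / v.sum()
    return v


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _draw_start(obj: _Objective, rng: np.random.Generator):
    S, F = obj.S, obj.F
    Xobs = obj.X[obj.obs]
    q = np.linspace(0.5 / S, 1.0 - 0.5 / S, S)
    scales = np.empty((S, F))
    for f in range(F):
        anchors = np.quantile(Xobs[:, f], q)
        anchors = np.maximum(anchors, FEATURE_FLOOR * 10)
        perm = rng.permutation(S)
        scales[:, f] = anchors[perm] * np.exp(rng.normal(0.0, 0.25, size=S))
    shapes = np.exp(rng.uniform(np.log(0.7), np.log(6.0), size=(S, F)))
    beta0 = rng.normal(-2.2, 0.5, size=(S, S))
    beta_level = {l: rng.normal(0.0, 0.3, size=(S, S)) for l in obj.levels[1:]}
    alr = rng.normal(0.0, 0.5, size=S - 1)
    return obj.pack(shapes, scales, beta0, beta_level, alr)


def _kmeans_start(obj: _Objective, seed: int):
    """Informed start: Weibull moment-matching within a k-means partition.

    Plays the role of starting values anticipated per state; the remaining
    restarts explore randomly around the data quantiles.
    """
    from scipy.cluster.vq import kmeans2
    from scipy.optimize import brentq

    S, F = obj.S, obj.F
    Xobs = obj.X[obj.obs]
    Z = np.log(np.maximum(Xobs, FEATURE_FLOOR))
    Z = (Z - Z.mean(axis=0)) / np.maximum(Z.std(axis=0), 1e-12)
    _, labels = kmeans2(Z, S, minit="++", seed=seed)
    shapes = np.full((S, F), 2.0)
    scales = np.empty((S, F))
    for s in range(S):
        grp = Xobs[labels == s] if (labels == s).sum() >= 5 else Xobs
        for f in range(F):
            m = float(grp[:, f].mean())
            cv = float(grp[:, f].std() / max(m, 1e-12))
            cv = min(max(cv, 0.02), 5.0)

            def _cv_gap(k):
                g1 = special.gammaln(1 + 1.0 / k)
                g2 = special.gammaln(1 + 2.0 / k)
                return np.sqrt(max(np.exp(g2 - 2 * g1) - 1.0, 1e-300)) - cv

            try:
                k = brentq(_cv_gap, 0.08, 150.0)
            except ValueError:
                k = 2.0
            shapes[s, f] = k
            scales[s, f] = max(m / special.gamma(1 + 1.0 / k), FEATURE_FLOOR)
    beta0 = np.full((obj.S, obj.S), -2.2)
    beta_level = {l: np.zeros((S, S)) for l in obj.levels[1:]}
    return obj.pack(shapes, scales, beta0, beta_level, np.zeros(S - 1))


def _data_hash(table: pd.DataFrame, feature_set) -> str:
    arr = table[list(feature_set)].to_numpy(dtype=float)
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.nan_to_num(arr, nan=-1.0)).tobytes())
    h.update(",".join(feature_set).encode())
    return h.hexdigest()[:16]


def fit_hmm(table: pd.DataFrame, feature_set=("hf", "p5", "sh"),
            covariate: bool = True, n_states: int = 3, n_restarts: int = 25,
            seed: int = 0, floor: float = FEATURE_FLOOR,
            missing_split_run: int = 10, stability_tol: float = 1e-3,
            delta_mode: str = "estimate", maxiter: int = 500) -> FitResult:
    """Maximum-likelihood fit from ``n_restarts`` random starting values.

    Each restart draws Weibull scales near data quantiles (randomly assigned
    to states), log-uniform shapes, and transition intercepts near a
    diagonally dominant matrix, then minimizes the negative log-likelihood
    on the unconstrained scale.  The restart with the largest converged
    log-likelihood wins; ``n_stable`` counts restarts within
    ``stability_tol`` of the best.
    """
    feature_set = tuple(feature_set)
    chains = prepare_chains(table, feature_set, floor, missing_split_run)
    if covariate:
        levels = tuple(sorted({lvl for _, _, lvl in chains}))
    else:
        levels = ("_all",)
        chains = [(x, m, "_all") for x, m, _ in chains]
    obj = _Objective(chains, feature_set, levels, n_states, delta_mode)
    bounds = obj.bounds()
    rng = np.random.default_rng(seed)
    results = []
    for restart in range(n_restarts):
        if restart == 0:
            try:  # informed start from the anticipated state partition
                x0 = _kmeans_start(obj, seed)
            except Exception:
                x0 = _draw_start(obj, rng)
        else:
            x0 = _draw_start(obj, rng)
        for _retry in range(10):  # redraw starts that land outside support
            if np.isfinite(obj(x0)[0]) and obj(x0)[0] < 1e11:
                break
            x0 = _draw_start(obj, rng)
        try:
            res = optimize.minimize(obj, x0, jac=True, method="L-BFGS-B",
                                    bounds=bounds,
                                    options=dict(maxiter=maxiter, maxfun=4 * maxiter,
                                                 ftol=1e-11, gtol=1e-7))
            ok = np.isfinite(res.fun) and res.fun < 1e11
        except Exception:
            res, ok = None, False
        if not ok:
            try:  # simplex fallback
                res = optimize.minimize(lambda th: obj(th)[0], x0,
                                        method="Nelder-Mead",
                                        options=dict(maxiter=2000, fatol=1e-8))
                ok = np.isfinite(res.fun) and res.fun < 1e11
            except Exception:
                res, ok = None, False
        results.append((res, ok))
    logliks = [(-res.fun if ok else -np.inf) for res, ok in results]
    if not any(ok for _, ok in results):
        raise RuntimeError(
            "all restarts failed; per-restart diagnostics: "
            + "; ".join(str(r) for r, _ in results))
    best_idx = int(np.argmax(logliks))
    best = results[best_idx][0]
    # polish the winning restart: the quasi-Newton tail along the flat
    # likelihood ridge converges slowly, so give the winner extra budget
    try:
        polished = optimize.minimize(obj, best.x, jac=True, method="L-BFGS-B",
                                     bounds=bounds,
                                     options=dict(maxiter=8 * maxiter,
                                                  maxfun=16 * maxiter,
                                                  ftol=1e-12, gtol=1e-7))
        if np.isfinite(polished.fun) and polished.fun <= best.fun:
            best = polished
            logliks[best_idx] = -polished.fun
    except Exception:
        pass
    shapes, scales, tm, delta = obj.unpack(best.x)
    if delta_mode == "stationary":
        delta = stationary_distribution(tm.gamma(levels[0]))
    params = HMMParams(n_states=n_states, feature_names=feature_set,
                       shapes=shapes, scales=scales, transition=tm, delta=delta)
    loglik = float(logliks[best_idx])
    n_free = n_free_parameters(n_states, len(feature_set), len(levels))
    n_stable = int(sum(1 for ll in logliks
                       if np.isfinite(ll) and loglik - ll <= stability_tol))
    return FitResult(
        params=params, loglik=loglik, aic=-2.0 * loglik + 2.0 * n_free,
        n_free_params=n_free, restart_logliks=[float(l) for l in logliks],
        converged=[bool(ok) for _, ok in results], n_stable=n_stable,
        data_hash=_data_hash(table, feature_set), feature_set=feature_set,
        covariate=covariate)


def compare_aic(fit_a: FitResult, fit_b: FitResult):
    """Return (preferred fit, AIC_a - AIC_b); rejects fits on different data."""
    if fit_a.data_hash != fit_b.data_hash:
        raise ValueError("fits were computed on different data (hash mismatch)")
    d = fit_a.aic - fit_b.aic
    return (fit_a if d <= 0 else fit_b), float(d)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def viterbi(table_or_chains, params: HMMParams, floor: float = FEATURE_FLOOR,
            missing_split_run: int = 10):
    """Most likely state path per chain (log-space dynamic program).

    Ties break toward the lower state index.  Returns a list of integer
    state arrays, one per chain, in the order of ``prepare_chains``.
    """
    chains = _as_chains(table_or_chains, params, floor, missing_split_run)
    out = []
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.delta)
    for X, miss, level in chains:
        G = params.transition.gamma(level)
        with np.errstate(divide="ignore"):
            logG = np.log(G)  # -inf marks a genuinely impossible transition
        logE = _log_emissions(X[None], (~miss)[None], params.shapes,
                              params.scales)[0]
        T, S = logE.shape
        score = log_delta + logE[0]
        ptr = np.zeros((T, S), dtype=int)
        for t in range(1, T):
            cand = score[:, None] + logG
            ptr[t] = np.argmax(cand, axis=0)  # first max = lowest index
            score = cand[ptr[t], np.arange(S)] + logE[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(score))
        for t in range(T - 1, 0, -1):
            path[t - 1] = ptr[t, path[t]]
        out.append(path)
    return out


def decode_states(table: pd.DataFrame, params: HMMParams,
                  label_map: dict | None = None,
                  floor: float = FEATURE_FLOOR,
                  missing_split_run: int = 10) -> pd.DataFrame:
    """Viterbi-decode a FeatureTable into a tidy state table."""
    chains = prepare_chains(table, params.feature_names, floor,
                            missing_split_run, return_index=True)
    paths = viterbi([c[:3] for c in chains], params)
    rows = []
    for (X, miss, level, ind, widx), path in zip(chains, paths):
        for w, s in zip(widx, path):
            rows.append({"individual_id": ind, "window_index": int(w),
                         "state_index": int(s),
                         "behavior_label": (label_map or {}).get(int(s), str(s))})
    return pd.DataFrame(rows)


def label_states(fit: FitResult) -> dict:
    """Map state indices to behavior labels, resolving label switching.

    The state with the largest Weibull mean of ``hf`` is flapping; of the
    rest, the one with the larger mean ``sh`` (or ``p5`` if ``sh`` is not in
    the feature set) is soaring; the remainder is on-water.  Exact ties
    break toward the lower state index.
    """
    params = fit.params
    names = list(params.feature_names)
    if "hf" not in names:
        raise ValueError("state labeling requires 'hf' in the feature set")
    means = {f: weibull_mean(params.shapes[:, names.index(f)],
                             params.scales[:, names.index(f)])
             for f in names}
    order = np.argsort(-means["hf"], kind="stable")
    flap = int(order[0])
    rest = [int(i) for i in order[1:]]
    second = "sh" if "sh" in names else "p5"
    rest.sort(key=lambda i: (-means[second][i], i))
    mapping = {flap: "flap"}
    labels = ["soar", "water"]
    for i, s in enumerate(rest):
        mapping[s] = labels[i] if i < 2 else f"state{s}"
    return mapping


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def pseudo_residuals(table_or_chains, params: HMMParams,
                     floor: float = FEATURE_FLOOR,
                     missing_split_run: int = 10) -> pd.DataFrame:
    """Forecast (one-step-ahead) pseudo-residuals per feature.

    For each window the observation is pushed through its model-implied
    conditional CDF given the chain's past, then through the standard normal
    quantile; under a correctly specified model the residuals are iid
    standard normal.  Missing windows yield missing residuals.
    """
    chains = _as_chains(table_or_chains, params, floor, missing_split_run)
    levels = params.transition.levels
    names = list(params.feature_names)
    rows = []
    for ci, (X, miss, level) in enumerate(chains):
        G = params.transition.gamma(level)
        logE = _log_emissions(X[None], (~miss)[None], params.shapes,
                              params.scales)[0]
        mshift = logE.max(axis=1)
        El = np.exp(logE - mshift[:, None])
        T, S = logE.shape
        w_pred = params.delta.copy()
        a = None
        for t in range(T):
            rec = {"chain": ci, "window_index": t}
            for f, name in enumerate(names):
                if miss[t]:
                    rec[name] = np.nan
                else:
                    u = float(np.sum(w_pred * weibull_cdf(
                        X[t, f], params.shapes[:, f], params.scales[:, f])))
                    rec[name] = float(stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12)))
            rows.append(rec)
            a = w_pred * El[t]
            a = a / a.sum()
            w_pred = a @ G
    return pd.DataFrame(rows)
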