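"""Latent class model for polytomous indicators, fitted by multi-start EM.

The model: each individual belongs to one of C latent classes with
prevalences gamma_c; conditional on class, the J categorical indicators
are independent, with item-response probabilities rho_{j,k|c}.  The
observed-data log-likelihood is

    sum_i log sum_c gamma_c prod_{j in obs(i)} rho_{j, y_ij | c},

products running over observed items only, so item-level missingness is
handled under the missing-at-random assumption without imputation.

EM is run from many random starting values (Dirichlet(1) draws) and the
best converged chain is kept; all chains are iterated as one batched
computation for speed, and classes are relabelled into a canonical
order (descending gamma) so replicate fits are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LCAParams",
    "FitResult",
    "LatentClassModel",
    "log_likelihood",
    "e_step",
    "m_step",
    "fit_em",
    "count_parameters",
    "degrees_of_freedom",
    "canonical_order",
]


class DegenerateClassError(RuntimeError):
    """A class lost essentially all posterior mass during the M-step."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


@dataclass
class LCAParams:
    """Class prevalences and item-response probabilities.

    rho is stored as an array of shape (C, J, K_max); for items with
    fewer than K_max levels the trailing entries are zero and ignored.
    """

    gamma: np.ndarray
    rho: np.ndarray
    K: list  # K_j per item

    @property
    def C(self) -> int:
        return len(self.gamma)

    @property
    def J(self) -> int:
        return self.rho.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if not np.all(self.gamma >= 0) or abs(self.gamma.sum() - 1) > atol:
            raise ValueError("gamma is not on the simplex")
        for j, k in enumerate(self.K):
            rows = self.rho[:, j, :k]
            if not np.allclose(rows.sum(axis=1), 1.0, atol=atol) or np.any(rows < 0):
                raise ValueError(f"rho rows for item {j} are not on the simplex")


@dataclass
class FitResult:
    params: LCAParams
    posteriors: np.ndarray
    loglik: float
    n_params: int
    df: int
    converged: bool
    n_iter: int
    start_logliks: np.ndarray
    start_converged: np.ndarray | None = None
    seed: int | None = None
    n_obs: int = 0
    column_names: list = field(default_factory=list)

    @property
    def C(self) -> int:
        return self.params.C


def _prepare(data) -> tuple[np.ndarray, list, list]:
    """Coerce an indicator matrix to an int array with -1 for missing."""
    cols = []
    if isinstance(data, pd.DataFrame):
        cols = list(data.columns)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("indicator matrix must be 2-dimensional")
    X = np.where(np.isnan(arr), -1, arr).astype(np.int64)
    if np.any(X < -1):
        raise ValueError("indicator levels must be non-negative integers or missing")
    K = [int(max(X[:, j].max(), 1)) + 1 for j in range(X.shape[1])]
    return X, K, cols


def _check_levels(X: np.ndarray, K: list) -> None:
    for j, k in enumerate(K):
        if X[:, j].max() >= k:
            raise ValueError(f"item {j} has level {X[:, j].max()} outside 0..{k - 1}")


def _onehot(X: np.ndarray, K: list) -> tuple[np.ndarray, np.ndarray]:
    """(n, J*Kmax) one-hot with missing rows zeroed, plus (n, J) observed mask."""
    n, J = X.shape
    Kmax = max(K)
    oh = np.zeros((n, J, Kmax))
    obs = X >= 0
    ii, jj = np.nonzero(obs)
    oh[ii, jj, X[ii, jj]] = 1.0
    return oh.reshape(n, J * Kmax), obs.astype(float)


def _safe_log_rho(rho: np.ndarray, K: list) -> np.ndarray:
    """log(rho) with out-of-range level slots set to 0 (never indexed)."""
    lr = np.zeros_like(rho)
    for j, k in enumerate(K):
        lr[..., j, :k] = np.log(np.clip(rho[..., j, :k], 1e-300, None))
    return lr


def _log_joint(params: LCAParams, X: np.ndarray) -> np.ndarray:
    """(n, C) matrix of log gamma_c + sum_j log rho_{j, y_ij | c}."""
    oh, _ = _onehot(X, params.K)
    lr = _safe_log_rho(params.rho, params.K)  # (C, J, Kmax)
    return oh @ lr.reshape(params.C, -1).T + np.log(np.clip(params.gamma, 1e-300, None))


def log_likelihood(params: LCAParams, data) -> float:
    """Observed-data log-likelihood under MAR (empty product for all-missing rows)."""
    X, _, _ = _prepare(data)
    if X.shape[1] != params.J:
        raise ValueError("data/params item count mismatch")
    for j in range(X.shape[1]):
        if X[:, j].max() >= params.K[j]:
            raise ValueError(f"item {j} level out of range for params")
    return float(logsumexp(_log_joint(params, X), axis=1).sum())


def e_step(params: LCAParams, data) -> np.ndarray:
    """Posterior class-membership probabilities, computed in log space."""
    X, _, _ = _prepare(data)
    lj = _log_joint(params, X)
    lse = logsumexp(lj, axis=1, keepdims=True)
    if not np.all(np.isfinite(lse)):
        raise FloatingPointError("zero posterior normalizer")
    return np.exp(lj - lse)


def m_step(posteriors: np.ndarray, data, eps: float = 1e-6, K: list | None = None) -> LCAParams:
    """Closed-form maximizer of the EM Q-function, with boundary clipping."""
    X, K_data, _ = _prepare(data)
    K = K or K_data
    post = np.asarray(posteriors, dtype=float)
    n, C = post.shape
    mass = post.sum(axis=0)
    if np.any(mass < 1e-8 * n):
        bad = int(np.argmin(mass))
        raise DegenerateClassError(f"class {bad} has vanishing posterior mass {mass[bad]:.3g}")
    gamma = mass / n
    oh, obs = _onehot(X, K)
    Kmax = max(K)
    num = (post.T @ oh).reshape(C, -1, Kmax)  # (C, J, Kmax)
    den = post.T @ obs  # (C, J)
    rho = np.zeros_like(num)
    for j, k in enumerate(K):
        r = num[:, j, :k] / np.clip(den[:, j, None], 1e-300, None)
        r = np.clip(r, eps, 1 - eps)
        rho[:, j, :k] = r / r.sum(axis=1, keepdims=True)
    gamma = np.clip(gamma, eps, 1 - eps)
    gamma = gamma / gamma.sum()
    return LCAParams(gamma=gamma, rho=rho, K=list(K))


def count_parameters(J: int, K_list, C: int) -> int:
    """Free parameters: (C-1) prevalences + C*(K_j-1) response probabilities per item."""
    if isinstance(K_list, int):
        K_list = [K_list] * J
    if J < 1 or C < 1 or any(k < 2 for k in K_list):
        raise ValueError("need J>=1, C>=1 and K_j>=2")
    return (C - 1) + sum(C * (k - 1) for k in K_list)


def degrees_of_freedom(J: int, K_list, C: int) -> int:
    """Residual df of the contingency table: prod_j K_j - P - 1 (exact integers)."""
    if isinstance(K_list, int):
        K_list = [K_list] * J
    cells = 1
    for k in K_list:
        cells *= int(k)
    return cells - count_parameters(J, K_list, C) - 1


def canonical_order(params: LCAParams, posteriors: np.ndarray | None = None):
    """Relabel classes by descending gamma (ties: descending rho of item 0's last level)."""
    tie = params.rho[:, 0, params.K[0] - 1]
    order = np.lexsort((-tie, -params.gamma))
    new = LCAParams(gamma=params.gamma[order], rho=params.rho[order], K=list(params.K))
    if posteriors is not None:
        return new, posteriors[:, order]
    return new


def _random_start(rng: np.random.Generator, C: int, K: list, J: int):
    gamma = rng.dirichlet(np.ones(C))
    Kmax = max(K)
    rho = np.zeros((C, J, Kmax))
    for j, k in enumerate(K):
        rho[:, j, :k] = rng.dirichlet(np.ones(k), size=C)
    return gamma, rho


def fit_em(
    data,
    C: int,
    n_starts: int = 100,
    seed: int | None = 0,
    tol: float = 1e-6,
    ll_tol: float = 1e-9,
    max_iter: int = 5000,
    eps: float = 1e-6,
) -> FitResult:
    """Fit a C-class model by EM from ``n_starts`` random starting values.

    All chains are advanced together as one batched array computation;
    each chain stops updating once converged (max absolute parameter
    change < ``tol`` and relative log-likelihood change < ``ll_tol``).
    The best converged chain is returned with classes in canonical
    order.  Within every chain the log-likelihood is checked to be
    non-decreasing (to 1e-8), the EM ascent guarantee.
    """
    X, K, cols = _prepare(data)
    n, J = X.shape
    if C < 1:
        raise ValueError("C must be >= 1")
    if n < C:
        raise ValueError("need at least C rows")

    if C == 1:
        # Closed form: gamma = 1, rho = observed marginal proportions.
        post = np.ones((n, 1))
        params = m_step(post, X, eps=eps, K=K)
        ll = log_likelihood(params, X)
        P = count_parameters(J, K, 1)
        return FitResult(params, post, ll, P, degrees_of_freedom(J, K, 1), True, 1,
                         np.array([ll]), np.array([True]), seed, n, cols)

    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n_starts)]
    S, Kmax = n_starts, max(K)
    gam = np.empty((S, C))
    rho = np.zeros((S, C, J, Kmax))
    for s, rng in enumerate(child_rngs):
        gam[s], rho[s] = _random_start(rng, C, K, J)

    oh, obs = _onehot(X, K)  # (n, J*Kmax), (n, J)
    active = np.ones(S, dtype=bool)
    converged = np.zeros(S, dtype=bool)
    ll = np.full(S, -np.inf)
    n_iter = np.zeros(S, dtype=int)
    failed = np.zeros(S, dtype=bool)

    for it in range(1, max_iter + 1):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        lr = _safe_log_rho(rho[idx], K)  # (s, C, J, Kmax)
        lg = np.log(np.clip(gam[idx], 1e-300, None))
        # E-step for all active chains in one matmul.
        logp = oh @ lr.reshape(idx.size * C, -1).T  # (n, s*C)
        logp = logp.reshape(n, idx.size, C) + lg[None, :, :]
        lse = logsumexp(logp, axis=2)
        ll_new = lse.sum(axis=0)
        post = np.exp(logp - lse[:, :, None])  # (n, s, C)

        drop = ll_new < ll[idx] - 1e-8
        if np.any(drop):  # EM ascent violated: numerical failure of those chains
            failed[idx[drop]] = True
            active[idx[drop]] = False

        # M-step (batched)
        mass = post.sum(axis=0)  # (s, C)
        dead = np.any(mass < 1e-8 * n, axis=1)
        gam_new = np.clip(mass / n, eps, None)
        gam_new /= gam_new.sum(axis=1, keepdims=True)
        pm = post.reshape(n, -1)  # (n, s*C)
        num = (pm.T @ oh).reshape(idx.size, C, J, Kmax)
        den = (pm.T @ obs).reshape(idx.size, C, J)
        rho_new = np.zeros_like(num)
        for j, k in enumerate(K):
            r = num[:, :, j, :k] / np.clip(den[:, :, j, None], 1e-300, None)
            r = np.clip(r, eps, 1 - eps)
            rho_new[:, :, j, :k] = r / r.sum(axis=2, keepdims=True)

        delta = np.maximum(
            np.abs(gam_new - gam[idx]).max(axis=1),
            np.abs(rho_new - rho[idx]).reshape(idx.size, -1).max(axis=1),
        )
        rel_ll = np.abs(ll_new - ll[idx]) / (np.abs(ll_new) + 1.0)

        still = active[idx]  # chains not dropped this iteration
        gam[idx[still]] = gam_new[still]
        rho[idx[still]] = rho_new[still]
        ll[idx[still]] = ll_new[still]
        n_iter[idx[still]] = it

        done = still & (delta < tol) & (rel_ll < ll_tol)
        conv_idx = idx[done]
        converged[conv_idx] = True
        active[conv_idx] = False
        died = still & dead & ~done
        failed[idx[died]] = True
        active[idx[died]] = False

    if not converged.any():
        raise ConvergenceError(
            f"no EM chain converged in {max_iter} iterations",
            diagnostics={"loglik": ll, "n_iter": n_iter, "failed": failed},
        )

    lls = np.where(converged, ll, -np.inf)
    best = int(np.argmax(lls))
    params = LCAParams(gamma=gam[best], rho=rho[best], K=list(K))
    params, post = canonical_order(params, e_step(params, X))
    final_ll = log_likelihood(params, X)
    P = count_parameters(J, K, C)
    start_lls = np.where(failed, -np.inf, ll)
    # the returned chain's recorded value is its fully-converged log-likelihood
    start_lls[best] = max(start_lls[best], final_ll)
    return FitResult(
        params=params,
        posteriors=post,
        loglik=final_ll,
        n_params=P,
        df=degrees_of_freedom(J, K, C),
        converged=True,
        n_iter=int(n_iter[best]),
        start_logliks=start_lls,
        start_converged=converged.copy(),
        seed=seed,
        n_obs=n,
        column_names=cols,
    )


class LatentClassModel(DensityMixin, BaseEstimator):
    """Latent class model for categorical indicators (finite mixture).

    scikit-learn style estimator: ``fit(X)`` on an n x J matrix of
    integer-coded categorical indicators (NaN = missing), then
    ``predict_proba`` gives posterior class memberships and ``predict``
    the modal class.

    Parameters
    ----------
    n_classes : number of latent classes C.
    n_starts : number of random starting values for EM.
    tol, ll_tol, max_iter : EM convergence controls.
    eps : boundary clip for probabilities.
    random_state : master seed; every chain draws from a spawned
        substream, so fits are reproducible.

    Attributes
    ----------
    gamma_ : (C,) class prevalences, descending.
    rho_ : (C, J, K_max) item-response probabilities.
    loglik_ : maximised observed-data log-likelihood.
    posteriors_ : (n, C) training-data posterior memberships.
    n_parameters_, df_, n_iter_, start_logliks_ : fit diagnostics.
    """

    def __init__(
        self,
        n_classes: int = 2,
        n_starts: int = 100,
        tol: float = 1e-6,
        ll_tol: float = 1e-9,
        max_iter: int = 5000,
        eps: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.ll_tol = ll_tol
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y=None):
        res = fit_em(
            X,
            C=self.n_classes,
            n_starts=self.n_starts,
            seed=self.random_state,
            tol=self.tol,
            ll_tol=self.ll_tol,
            max_iter=self.max_iter,
            eps=self.eps,
        )
        self.result_ = res
        self.gamma_ = res.params.gamma
        self.rho_ = res.params.rho
        self.item_levels_ = list(res.params.K)
        self.loglik_ = res.loglik
        self.posteriors_ = res.posteriors
        self.n_parameters_ = res.n_params
        self.df_ = res.df
        self.n_iter_ = res.n_iter
        self.start_logliks_ = res.start_logliks
        self.feature_names_in_ = np.asarray(res.column_names) if res.column_names else None
        return self

    @property
    def params_(self) -> LCAParams:
        check_is_fitted(self, "gamma_")
        return LCAParams(gamma=self.gamma_, rho=self.rho_, K=self.item_levels_)

    def predict_proba(self, X) -> np.ndarray:
        return e_step(self.params_, X)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X) -> np.ndarray:
        Xp, _, _ = _prepare(X)
        return logsumexp(_log_joint(self.params_, Xp), axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-sample log-likelihood (sklearn mixture convention)."""
        return float(np.mean(self.score_samples(X)))
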