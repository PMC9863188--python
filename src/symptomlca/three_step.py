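"""Classification-error-corrected (BCH) association and distal-outcome estimation.

Assigning individuals to their modal latent class and then regressing
on the assignment ignores classification error and attenuates
associations.  The BCH correction estimates the error matrix
D_{cj} = P(modal class j | true class c) from the posteriors and
weights each individual's C pseudo-records by the row of D^-1 indexed
by their modal class.  Those (possibly negative) weights are then used
in a weighted multinomial logistic regression of class on covariates,
and in weighted cross-tabulations of class against distal
health-service outcomes.  Inverse-propensity (IP) weights built from
the fitted covariate model additionally balance covariates across
classes; standardized mean differences (SMD) diagnose the balance.

The weighted multinomial logit is fitted by direct optimisation of the
weighted log-likelihood: BCH weights can be negative, which rules out
the usual GLM fitters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "modal_assignment",
    "classification_matrix",
    "bch_weights",
    "bch_distal",
    "BCHMultinomialLogit",
    "bch_multinomial_regression",
    "ip_weights",
    "IPWeightSet",
]


class SeparationError(RuntimeError):
    """A covariate perfectly separates classes; the MLE is unbounded."""


def modal_assignment(posteriors) -> np.ndarray:
    """Highest-posterior class per individual; ties go to the lower index."""
    return np.argmax(np.asarray(posteriors, dtype=float), axis=1)


def classification_matrix(posteriors, modal=None) -> np.ndarray:
    """D_{cj} = sum_i p_ic 1(m_i = j) / sum_i p_ic (rows: true class, cols: modal)."""
    p = np.asarray(posteriors, dtype=float)
    if modal is None:
        modal = modal_assignment(p)
    n, C = p.shape
    mass = p.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError(f"class {int(np.argmin(mass))} has zero posterior mass")
    D = np.zeros((C, C))
    for j in range(C):
        D[:, j] = p[modal == j].sum(axis=0)
    return D / mass[:, None]


def bch_weights(D: np.ndarray, modal) -> np.ndarray:
    """Per-individual BCH weights u_ic = (D^-1)_{m_i, c}.

    Rows of D sum to 1, so rows of D^-1 do too and every individual's
    weights sum to exactly 1; individual weights may be negative.
    """
    D = np.asarray(D, dtype=float)
    cond = np.linalg.cond(D)
    if cond > 1e8:
        raise np.linalg.LinAlgError(
            f"classification matrix is near-singular (condition {cond:.3g}); "
            "class separation (entropy) is too low for the BCH correction"
        )
    Dinv = np.linalg.inv(D)
    return Dinv[np.asarray(modal, dtype=int)]


def _distal_percents(u: np.ndarray, y_codes: np.ndarray, n_cat: int, warn: bool = True):
    """Class-conditional category percents from signed weights; negatives clipped."""
    C = u.shape[1]
    totals = u.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError(f"class {int(np.argmin(totals))} has non-positive total BCH weight")
    cells = np.zeros((C, n_cat))
    for q in range(n_cat):
        cells[:, q] = u[y_codes == q].sum(axis=0)
    if np.any(cells < 0):
        if warn:
            logger.warning(
                "negative BCH cell estimates clipped to 0 (%d cells)", int((cells < 0).sum())
            )
        cells = np.clip(cells, 0.0, None)
    return 100.0 * cells / cells.sum(axis=1, keepdims=True)


def bch_distal(
    u,
    outcome,
    extra_weights=None,
    n_bootstrap: int = 500,
    seed: int | None = 0,
    categories=None,
) -> pd.DataFrame:
    """BCH-weighted class-conditional distribution of a categorical outcome.

    The class-c share of category q is sum_i u_ic 1(Y_i = q) / sum_i
    u_ic, expressed in percent.  Negative cell estimates are clipped to
    zero and the class renormalised (logged).  ``extra_weights`` (e.g.
    stabilized IP weights, n x C) multiply the BCH weights.  95%
    percentile confidence intervals come from a nonparametric bootstrap
    over individuals, reusing the fixed classification matrix.

    Returns a long DataFrame (class, category, percent, ci_low, ci_high).
    """
    u = np.asarray(u, dtype=float)
    y = pd.Categorical(outcome, categories=categories)
    if y.isna().any():
        raise ValueError("outcome contains values outside the declared categories")
    codes = np.asarray(y.codes)
    cats = list(y.categories)
    w = u if extra_weights is None else u * np.asarray(extra_weights, dtype=float)
    pct = _distal_percents(w, codes, len(cats))
    n, C = u.shape
    ci_low = ci_high = np.full_like(pct, np.nan)
    if n_bootstrap and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_bootstrap, C, len(cats)))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            boot[b] = _distal_percents(w[idx], codes[idx], len(cats), warn=False)
        ci_low = np.percentile(boot, 2.5, axis=0)
        ci_high = np.percentile(boot, 97.5, axis=0)
    rows = []
    for c in range(C):
        for q, cat in enumerate(cats):
            rows.append(
                {
                    "class": c,
                    "category": cat,
                    "percent": pct[c, q],
                    "ci_low": ci_low[c, q],
                    "ci_high": ci_high[c, q],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weighted multinomial logistic regression
# ---------------------------------------------------------------------------


def _design(covariates: pd.DataFrame):
    """Dummy-code categoricals (first level = reference), pass numerics through."""
    X_parts, names = [np.ones((len(covariates), 1))], ["intercept"]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            X_parts.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            cat = s.astype("category")
            for lev in cat.cat.categories[1:]:
                X_parts.append((cat == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{col}[{lev}]")
    return np.hstack(X_parts), names


def _wmn_negll_grad(beta_flat, X, U, nonref, C):
    """Negative weighted multinomial log-likelihood and gradient.

    U is the n x C matrix of (signed) class weights; the reference
    class logit is fixed at 0.
    """
    n, p = X.shape
    B = beta_flat.reshape(len(nonref), p)
    eta = np.zeros((n, C))
    eta[:, nonref] = X @ B.T
    lse = logsumexp(eta, axis=1, keepdims=True)
    logpi = eta - lse
    f = -np.sum(U * logpi)
    rowsum = U.sum(axis=1, keepdims=True)
    resid = U - rowsum * np.exp(logpi)  # n x C
    grad = -(resid[:, nonref].T @ X)
    return f, grad.ravel()


class BCHMultinomialLogit(BaseEstimator):
    """Multinomial logistic regression of latent class on covariates, BCH-weighted.

    Each individual contributes C pseudo-records (one per class) with
    signed weight u_ic; the weighted log-likelihood
    sum_i sum_c u_ic log P(class = c | x_i; beta) is maximised by
    L-BFGS with analytic gradients (multi-start fallback when negative
    weights make the surface non-concave).

    Parameters
    ----------
    reference : "largest" (class with the largest total weight) or a
        class index; its coefficients are fixed at zero so odds ratios
        contrast each class against it.

    Attributes
    ----------
    coef_ : (C-1, p) log-odds coefficients for the non-reference classes.
    feature_names_ : design column names ("intercept" first).
    reference_class_ : resolved reference class index.
    odds_ratios_ : tidy DataFrame of exp(coef) per covariate term and class.
    """

    def __init__(self, reference="largest", max_restarts: int = 3, random_state: int = 0):
        self.reference = reference
        self.max_restarts = max_restarts
        self.random_state = random_state

    def fit(self, covariates: pd.DataFrame, u):
        U = np.asarray(u, dtype=float)
        n, C = U.shape
        if len(covariates) != n:
            raise ValueError("covariates and weights have different lengths")
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values; analysis is complete-case")
        X, names = _design(covariates)
        ref = int(np.argmax(U.sum(axis=0))) if self.reference == "largest" else int(self.reference)
        nonref = [c for c in range(C) if c != ref]
        p = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        best = None
        x0 = np.zeros(len(nonref) * p)
        for attempt in range(self.max_restarts):
            res = minimize(
                _wmn_negll_grad,
                x0,
                args=(X, U, nonref, C),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
            x0 = rng.normal(scale=0.1, size=len(nonref) * p)
        coef = best.x.reshape(len(nonref), p)
        if np.any(np.abs(coef) > 15):
            j = int(np.argmax(np.abs(coef).max(axis=0)))
            raise SeparationError(
                f"unbounded coefficient for covariate term {names[j]!r}: "
                "a covariate (quasi-)separates the classes"
            )
        self.coef_ = coef
        self.feature_names_ = names
        self.reference_class_ = ref
        self.nonref_classes_ = nonref
        self.n_classes_ = C
        self.converged_ = bool(best.success)
        rows = []
        for ci, c in enumerate(nonref):
            for j, name in enumerate(names):
                if name == "intercept":
                    continue
                rows.append({"term": name, "class": c, "OR": float(np.exp(coef[ci, j]))})
        self.odds_ratios_ = pd.DataFrame(rows)
        return self

    def predict_proba(self, covariates: pd.DataFrame) -> np.ndarray:
        X, _ = _design(covariates)
        eta = np.zeros((X.shape[0], self.n_classes_))
        eta[:, self.nonref_classes_] = X @ self.coef_.T
        return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))


def bch_multinomial_regression(
    covariates: pd.DataFrame,
    u,
    reference="largest",
    n_bootstrap: int = 500,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, BCHMultinomialLogit]:
    """Odds ratios (with bootstrap 95% CIs) for class membership vs covariates.

    Returns the association table — one row per covariate term and
    non-reference class, with OR and percentile CI — plus the fitted
    model (reused downstream for IP weights).  Reference rows are
    implicit (OR = 1).  The bootstrap resamples individuals and refits,
    holding the design and reference class fixed.
    """
    u = np.asarray(u, dtype=float)
    model = BCHMultinomialLogit(reference=reference, random_state=0).fit(covariates, u)
    table = model.odds_ratios_.copy()
    if n_bootstrap and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(covariates)
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                m = BCHMultinomialLogit(
                    reference=model.reference_class_, random_state=0
                ).fit(covariates.iloc[idx].reset_index(drop=True), u[idx])
                boot.append(m.odds_ratios_["OR"].to_numpy())
            except (SeparationError, np.linalg.LinAlgError):
                continue
        if boot:
            B = np.vstack(boot)
            table["ci_low"] = np.percentile(B, 2.5, axis=0)
            table["ci_high"] = np.percentile(B, 97.5, axis=0)
    else:
        table["ci_low"] = np.nan
        table["ci_high"] = np.nan
    table["reference_class"] = model.reference_class_
    return table, model


# ---------------------------------------------------------------------------
# Inverse-propensity weighting and balance diagnostics
# ---------------------------------------------------------------------------


@dataclass
class IPWeightSet:
    """Stabilized IP weights and covariate-balance diagnostics."""

    weights: np.ndarray  # n x C stabilized weights w_ic
    combined: np.ndarray  # n x C analysis weights u_ic * w_ic
    smd_before: pd.DataFrame  # |SMD| per covariate term x class contrast, BCH only
    smd_after: pd.DataFrame  # same, after IP weighting


def _weighted_smd(x: np.ndarray, w: np.ndarray, ref: int) -> np.ndarray:
    """|SMD| of one covariate column between each class and the reference.

    Means and variances are weight-normalised within each class's
    pseudo-population; the denominator pools the two variances.
    """
    C = w.shape[1]
    tot = w.sum(axis=0)
    means = (w * x[:, None]).sum(axis=0) / tot
    var = (w * (x[:, None] - means) ** 2).sum(axis=0) / tot
    out = np.zeros(C)
    for c in range(C):
        denom = np.sqrt(max((var[c] + var[ref]) / 2.0, 1e-12))
        out[c] = abs(means[c] - means[ref]) / denom
    return out


def ip_weights(class_model: BCHMultinomialLogit, covariates: pd.DataFrame, u) -> IPWeightSet:
    """Stabilized inverse-propensity weights balancing covariates across classes.

    w_ic = P(class = c) / P(class = c | x_i), with the marginal from
    the BCH-weighted class shares; combined analysis weight u_ic * w_ic.
    SMDs for every dummy-coded covariate term and every class contrast
    (vs the model's reference class) are reported before (BCH only) and
    after (BCH x IP) weighting; |SMD| < 0.1 conventionally indicates
    balance.
    """
    u = np.asarray(u, dtype=float)
    n, C = u.shape
    cond = class_model.predict_proba(covariates)
    if np.any(cond < 1e-6):
        bad = np.nonzero((cond < 1e-6).any(axis=1))[0][:10]
        raise ValueError(
            f"predicted class probabilities below 1e-6 for individuals {bad.tolist()}; "
            "IP weights would be extreme"
        )
    marginal = u.sum(axis=0) / u.sum()
    w = marginal[None, :] / cond
    combined = u * w
    X, names = _design(covariates)
    ref = class_model.reference_class_
    # Clip signed BCH weights at 0 for the balance diagnostics: SMDs are
    # descriptive moments of pseudo-populations and need non-negative mass.
    ub = np.clip(u, 0.0, None)
    cb = np.clip(combined, 0.0, None)
    rows_b, rows_a = [], []
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        sb = _weighted_smd(X[:, j], ub, ref)
        sa = _weighted_smd(X[:, j], cb, ref)
        for c in range(C):
            if c == ref:
                continue
            rows_b.append({"term": name, "class": c, "smd": sb[c]})
            rows_a.append({"term": name, "class": c, "smd": sa[c]})
    return IPWeightSet(
        weights=w,
        combined=combined,
        smd_before=pd.DataFrame(rows_b),
        smd_after=pd.DataFrame(rows_a),
    )
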