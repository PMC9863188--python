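"""Model-comparison statistics and class-separation diagnostics.

For each candidate class count the sweep reports the likelihood-ratio
statistic G^2 against the saturated multinomial over observed response
patterns, AIC and BIC on both the G^2 and the -2LL basis, the relative
entropy of the posterior memberships, the smallest class prevalence,
and the share of random starts that reached the best log-likelihood
(model stability).  The average-posterior-probability (AvePP) matrix
summarises classification accuracy for a chosen model: diagonal
entries above 0.7 conventionally indicate well-separated classes.

Model choice itself is left to the analyst: the sweep emits a report
restating the criteria (lower AIC/BIC, higher entropy, class sizes,
stability, AvePP diagonal) without auto-selecting.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .lca import FitResult, LatentClassModel, _prepare, degrees_of_freedom

__all__ = [
    "g_squared",
    "saturated_loglik",
    "information_criteria",
    "relative_entropy",
    "avepp_matrix",
    "replicate_stability",
    "fit_sweep",
    "selection_report",
]

SWEEP_COLUMNS = [
    "C",
    "df",
    "AIC_G2",
    "BIC_G2",
    "AIC_LL",
    "BIC_LL",
    "loglik",
    "smallest_class_prob",
    "entropy",
    "pct_best_replicates",
]


def saturated_loglik(data) -> float:
    """Log-likelihood of the saturated multinomial over distinct observed patterns.

    The pattern key includes the missingness pattern, so G^2 stays
    well-defined with partial missingness and no imputation.
    """
    X, _, _ = _prepare(data)
    counts = Counter(map(tuple, X))
    n = X.shape[0]
    return sum(c * math.log(c / n) for c in counts.values())


def g_squared(fit: FitResult, data) -> float:
    """Likelihood-ratio statistic 2*(LL_sat - LL_model)."""
    X, _, _ = _prepare(data)
    if X.shape[0] != fit.posteriors.shape[0]:
        raise ValueError("data does not match the fitted model's sample")
    return 2.0 * (saturated_loglik(X) - fit.loglik)


def information_criteria(fit: FitResult, data, basis: str = "G2") -> tuple[float, float]:
    """AIC and BIC on the requested basis.

    basis="G2":      AIC = G^2 + 2P,   BIC = G^2 + P ln n
    basis="minus2LL": AIC = -2LL + 2P, BIC = -2LL + P ln n

    The two bases differ by the constant 2*LL_sat, so differences
    between models on the same data are identical.
    """
    n = fit.posteriors.shape[0]
    P = fit.n_params
    if basis == "G2":
        base = g_squared(fit, data)
    elif basis in ("minus2LL", "-2LL"):
        base = -2.0 * fit.loglik
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return base + 2 * P, base + P * math.log(n)


def relative_entropy(posteriors: np.ndarray) -> float:
    """Scaled relative entropy E = 1 - sum_i H(p_i) / (n ln C), in [0, 1].

    1 means perfectly separated classes (one-hot posteriors), 0 means
    no separation (uniform posteriors).  Undefined for C = 1.
    """
    p = np.asarray(posteriors, dtype=float)
    n, C = p.shape
    if C < 2:
        raise ValueError("relative entropy is undefined for a 1-class model")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log(p), 0.0)
    return 1.0 - float(h.sum()) / (n * math.log(C))


def modal_assignment(posteriors: np.ndarray) -> np.ndarray:
    """Highest-posterior class per row; ties broken toward the lower index."""
    return np.argmax(np.asarray(posteriors), axis=1)


def avepp_matrix(posteriors: np.ndarray) -> np.ndarray:
    """Average posterior probabilities by modal class.

    Entry (k, j) is the mean posterior probability of class j among
    individuals modally assigned to class k; rows sum to 1.
    """
    p = np.asarray(posteriors, dtype=float)
    modal = modal_assignment(p)
    C = p.shape[1]
    out = np.empty((C, C))
    for k in range(C):
        mask = modal == k
        if not mask.any():
            raise ValueError(f"no individuals modally assigned to class {k}")
        out[k] = p[mask].mean(axis=0)
    return out


def replicate_stability(start_logliks, tol: float = 0.01, converged=None) -> float:
    """Percent of starts whose final log-likelihood is within ``tol`` of the best.

    Only converged starts can count as reaching the best model; the
    denominator is the total number of starts.
    """
    ll = np.asarray(start_logliks, dtype=float)
    if converged is None:
        converged = np.isfinite(ll)
    conv_ll = ll[np.asarray(converged, dtype=bool) & np.isfinite(ll)]
    if conv_ll.size == 0:
        raise ValueError("no converged starts")
    best = conv_ll.max()
    return 100.0 * float((conv_ll >= best - tol).sum()) / len(ll)


def fit_sweep(
    data,
    C_range=range(1, 7),
    n_starts: int = 100,
    seed: int | None = 0,
    stability_tol: float = 0.01,
    **em_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit every class count in ``C_range`` and tabulate the fit criteria.

    Returns the sweep table (one row per C, columns as in
    ``SWEEP_COLUMNS``) and a dict of the fitted models keyed by C; a C
    whose fit fails is reported as a row of NaNs and skipped in the
    dict.  Each C draws its seed from a substream of ``seed``.
    """
    rows, fits = [], {}
    seeds = np.random.SeedSequence(seed).spawn(len(list(C_range)))
    for C, ss in zip(C_range, seeds):
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            model = LatentClassModel(
                n_classes=C, n_starts=n_starts, random_state=child_seed, **em_kwargs
            ).fit(data)
        except Exception as exc:  # keep sweeping the other class counts
            rows.append({"C": C, **{c: np.nan for c in SWEEP_COLUMNS[1:]}, "error": str(exc)})
            continue
        fit = model.result_
        aic_g2, bic_g2 = information_criteria(fit, data, basis="G2")
        aic_ll, bic_ll = information_criteria(fit, data, basis="minus2LL")
        rows.append(
            {
                "C": C,
                "df": fit.df,
                "AIC_G2": aic_g2,
                "BIC_G2": bic_g2,
                "AIC_LL": aic_ll,
                "BIC_LL": bic_ll,
                "loglik": fit.loglik,
                "smallest_class_prob": float(fit.params.gamma.min()),
                "entropy": relative_entropy(fit.posteriors) if C >= 2 else np.nan,
                "pct_best_replicates": replicate_stability(
                    fit.start_logliks, tol=stability_tol, converged=fit.start_converged
                ),
            }
        )
        fits[C] = model
    return pd.DataFrame(rows), fits


def selection_report(sweep: pd.DataFrame, avepp: np.ndarray | None = None) -> str:
    """Human-readable restatement of the model-choice criteria.

    Lists, per class count, AIC/BIC (lower is better), entropy (higher
    is better), the smallest class prevalence, and stability; flags
    whether BIC is still decreasing at the edge of the sweep range.
    The choice of C is the analyst's."""
    lines = ["Model comparison (choose C by judgement, not by a single criterion):"]
    for _, r in sweep.iterrows():
        ent = "undefined" if not np.isfinite(r.get("entropy", np.nan)) else f"{r['entropy']:.3f}"
        lines.append(
            f"  C={int(r['C'])}: AIC(G2)={r['AIC_G2']:.2f} BIC(G2)={r['BIC_G2']:.2f} "
            f"entropy={ent} smallest class={r['smallest_class_prob']:.3f} "
            f"stability={r['pct_best_replicates']:.0f}%"
        )
    bic = sweep["BIC_G2"].to_numpy()
    if len(bic) >= 2 and np.isfinite(bic[-1]) and np.isfinite(bic[-2]) and bic[-1] < bic[-2]:
        lines.append(
            "  NOTE: BIC is still decreasing at the upper edge of the class range; "
            "consider extending the sweep."
        )
    if avepp is not None:
        diag = np.diag(avepp)
        ok = "all > 0.7" if (diag > 0.7).all() else "NOT all > 0.7"
        lines.append(f"  AvePP diagonal: {np.round(diag, 3).tolist()} ({ok})")
    return "\n".join(lines)
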