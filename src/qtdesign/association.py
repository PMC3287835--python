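"""Regression engines and Wald tests for single-gene association.

Forward analysis regresses the (residualized) quantitative trait on a genetic
predictor — the common-variant dosage or the rare-variant burden score — by
ordinary or inverse-probability-weighted least squares.  Under unequal
sampling probabilities the weighted fit solves the Horvitz-Thompson
estimating equations and its variance is the design-based sandwich

    (X'WX)^{-1} (sum_i w_i^2 e_i^2 x_i x_i') (X'WX)^{-1},

the with-replacement linearization standard in survey analysis.

Reverse analysis conditions on the trait instead: logistic regression of a
carrier indicator, or Poisson regression of the rare-allele count, on the
trait value.  Conditioning on the phenotype makes these fits insensitive to
trait-dependent ascertainment, so they are run unweighted under every design.
Both GLMs are fit by iteratively reweighted least squares with the canonical
link.

Wald tests use a Student-t reference with n-2 degrees of freedom for linear
models and a standard normal reference for the GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FitResult", "fit_linear", "fit_glm_reverse", "wald_test"]

_GLM_TOL = 1e-8
_GLM_MAX_ITER = 100
_ETA_CLIP = 30.0  # logistic/Poisson linear predictor clip against overflow


@dataclass
class FitResult:
    """Estimate, SE, and Wald test for the genetic term of one model fit."""

    coefficient: float
    se: float
    statistic: float
    p_value: float
    model: str  # linear | ipw_linear | logistic_rev | poisson_rev
    design_id: str = ""
    n_used: int = 0
    converged: bool = True


def wald_test(coefficient: float, se: float, reference: str = "normal",
              df: int | None = None) -> tuple[float, float]:
    """Two-sided Wald test: statistic = coefficient/se.

    ``reference='t'`` uses Student t with ``df`` degrees of freedom (linear
    models, df = n - 2); ``reference='normal'`` the standard normal (GLMs).
    A zero SE yields an infinite statistic with p = 0.
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    if se == 0.0:
        return float(np.sign(coefficient)) * np.inf, 0.0
    stat = coefficient / se
    if reference == "t":
        if df is None or df <= 0:
            raise ValueError("t reference requires positive df")
        p = 2.0 * stats.t.sf(abs(stat), df)
    elif reference == "normal":
        p = 2.0 * stats.norm.sf(abs(stat))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return float(stat), float(p)


def _design_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones(x.size), x])
    if np.linalg.matrix_rank(X) < 2:
        raise np.linalg.LinAlgError("constant predictor: collinear with intercept")
    return X


def fit_linear(
    y: np.ndarray,
    x: np.ndarray,
    weights: np.ndarray | None = None,
    variance_mode: str = "classical",
    design_id: str = "",
) -> FitResult:
    """(Weighted) least-squares regression of y on intercept + x.

    Weights are probability weights: the point estimate solves the weighted
    normal equations, and variances never treat sum(w) as a sample size.
    ``variance_mode='classical'`` gives the model-based sigma^2 (X'WX)^{-1}
    with sigma^2 = sum w_i e_i^2 / (n-2); ``'design_sandwich'`` gives the
    robust design-based variance.  An unweighted classical fit is OLS.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 2:
        raise ValueError("need more than 2 observations")
    X = _design_matrix(x)
    if weights is None:
        w = np.ones(n)
        model = "linear"
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        model = "ipw_linear"
    if variance_mode not in ("classical", "design_sandwich"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    XtW = X.T * w
    A = XtW @ X  # X'WX
    beta = np.linalg.solve(A, XtW @ y)
    e = y - X @ beta
    A_inv = np.linalg.inv(A)
    if variance_mode == "classical":
        sigma2 = float((w * e**2).sum() / (n - 2))
        cov = sigma2 * A_inv
    else:
        meat = (X.T * (w**2 * e**2)) @ X
        cov = A_inv @ meat @ A_inv
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    stat, p = wald_test(float(beta[1]), se, reference="t", df=n - 2)
    return FitResult(coefficient=float(beta[1]), se=se, statistic=stat,
                     p_value=p, model=model, design_id=design_id, n_used=n)


def fit_glm_reverse(
    outcome: np.ndarray,
    y: np.ndarray,
    family: str,
    design_id: str = "",
) -> FitResult:
    """Reverse GLM: genotype outcome regressed on the trait by IRLS.

    ``family='binomial'`` fits logistic regression of a 0/1 carrier indicator;
    ``family='poisson'`` log-linear regression of a nonnegative allele count.
    Convergence requires the maximum coefficient change to fall below 1e-8
    within 100 iterations; complete separation surfaces as ``converged=False``
    (such fits should be excluded from summaries).
    """
    out = np.asarray(outcome, dtype=float)
    X = _design_matrix(y)
    n = out.size
    if family == "binomial":
        if not np.isin(out, (0.0, 1.0)).all():
            raise ValueError("binomial outcome must be 0/1")
        if out.min() == out.max():
            raise ValueError("degenerate outcome: no variation in carrier status")
    elif family == "poisson":
        if (out < 0).any() or not np.allclose(out, np.round(out)):
            raise ValueError("poisson outcome must be nonnegative integers")
        if out.sum() == 0:
            raise ValueError("degenerate outcome: all counts zero")
    else:
        raise ValueError(f"unknown family {family!r}")

    beta = np.zeros(2)
    if family == "poisson":
        beta[0] = np.log(out.mean())
    converged = False
    for _ in range(_GLM_MAX_ITER):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            var = mu * (1.0 - mu)
        else:
            mu = np.exp(eta)
            var = mu
        var = np.maximum(var, 1e-12)
        z = eta + (out - mu) / var
        XtW = X.T * var
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < _GLM_TOL:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    var = (lambda m: m * (1 - m))(1.0 / (1.0 + np.exp(-eta))) \
        if family == "binomial" else np.exp(eta)
    var = np.maximum(var, 1e-12)
    cov = np.linalg.inv((X.T * var) @ X)  # inverse Fisher information
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    stat, p = wald_test(float(beta[1]), se, reference="normal")
    model = "logistic_rev" if family == "binomial" else "poisson_rev"
    return FitResult(coefficient=float(beta[1]), se=se, statistic=stat,
                     p_value=p, model=model, design_id=design_id, n_used=n,
                     converged=converged)
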