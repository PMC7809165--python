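"""Two-equation mediation path model for a marker-mediator-phenotype triple.

The recursive system (Mod4) is

    M = alpha' * G + b1m * CGbm + b2m * D + b3m * Srm + e_m
    P = beta' * M + gamma' * G + b1p * CGbp + b2p * D + b3p * Srp + e_p

where G is a marker dosage, M a CLR microbial abundance and P a standardized
phenotype. The system is triangular with uncorrelated equation errors, so
per-equation OLS is the joint maximum-likelihood solution; classical SEs are
reported per equation. The quantities of interest are

* the direct effect gamma' (marker effect holding the mediator fixed),
* the indirect (mediated) effect alpha' * beta',
* the mediation ratio |alpha' * beta'| / |gamma'| used to screen for
  mediation-dominated markers, and
* the Sobel normal-approximation test of the product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PathFit",
    "fit_mediation",
    "mediation_ratio",
    "sobel_test",
    "MediationModel",
]


@dataclass
class PathFit:
    """Estimates for one G-M-P triple from the two-equation path model."""

    alpha: float
    alpha_se: float
    beta: float
    beta_se: float
    gamma_direct: float
    gamma_direct_se: float
    indirect: float
    ratio: float
    nuisance_m: np.ndarray  # (intercept, b1, b2, b3) of the mediator equation
    nuisance_p: np.ndarray  # (intercept, b1, b2, b3) of the phenotype equation
    resid_var_m: float
    resid_var_p: float
    untestable: bool = False
    marker: str | None = None
    mediator: str | None = None
    response: str | None = None

    @property
    def total_check(self) -> float:
        """gamma' + alpha'*beta' — equals the Mod1 total effect under
        matched covariate sets."""
        return self.gamma_direct + self.indirect


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS coefficients, SEs and residual variance (classical, df = n-p)."""
    n, p = X.shape
    XtX = X.T @ X
    coefs = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coefs
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    return coefs, se, sigma2


def fit_mediation(
    P: np.ndarray,
    M: np.ndarray,
    G: np.ndarray,
    covs_m: np.ndarray,
    covs_p: np.ndarray,
) -> PathFit:
    """Fit the recursive two-equation path model by per-equation OLS.

    ``covs_m`` and ``covs_p`` are n x 3 arrays with columns (CGb, damline,
    Sr) for the mediator and phenotype equations respectively (the two
    equations carry their own collapsed covariates). Constant G or M yields
    an untestable flag rather than an exception.
    """
    P = np.asarray(P, float)
    M = np.asarray(M, float)
    G = np.asarray(G, float)
    covs_m = np.atleast_2d(np.asarray(covs_m, float))
    covs_p = np.atleast_2d(np.asarray(covs_p, float))
    n = len(P)
    if not (len(M) == len(G) == n and len(covs_m) == len(covs_p) == n):
        raise ValueError("all inputs must share the same length")
    if np.ptp(G) == 0 or np.ptp(M) == 0:
        return PathFit(*([np.nan] * 8), np.full(4, np.nan), np.full(4, np.nan),
                       np.nan, np.nan, untestable=True)

    ones = np.ones(n)
    Xm = np.column_stack([ones, G, covs_m])
    cm, sem, s2m = _ols(M, Xm)
    Xp = np.column_stack([ones, M, G, covs_p])
    cp, sep, s2p = _ols(P, Xp)

    alpha, alpha_se = float(cm[1]), float(sem[1])
    beta, beta_se = float(cp[1]), float(sep[1])
    gamma_d, gamma_d_se = float(cp[2]), float(sep[2])
    indirect = alpha * beta
    fit = PathFit(
        alpha=alpha, alpha_se=alpha_se,
        beta=beta, beta_se=beta_se,
        gamma_direct=gamma_d, gamma_direct_se=gamma_d_se,
        indirect=indirect, ratio=np.nan,
        nuisance_m=np.concatenate([[cm[0]], cm[2:]]),
        nuisance_p=np.concatenate([[cp[0]], cp[3:]]),
        resid_var_m=s2m, resid_var_p=s2p,
    )
    fit.ratio = mediation_ratio(fit)
    return fit


def mediation_ratio(fit: PathFit) -> float:
    """Absolute mediated-over-direct ratio |alpha'*beta'| / |gamma'|.

    Infinite when the direct effect is exactly zero but the indirect is not
    (mediation trivially dominates); 0 with an untestable flag when both
    vanish.
    """
    indirect, direct = fit.indirect, fit.gamma_direct
    if direct == 0:
        if indirect == 0:
            fit.untestable = True
            return 0.0
        return math.inf
    return abs(indirect) / abs(direct)


def sobel_test(fit: PathFit) -> tuple[float, float]:
    """Sobel z and two-sided normal p for the indirect effect.

    z = a*b / sqrt(a^2 se_b^2 + b^2 se_a^2). A zero product gives z = 0,
    p = 1; a zero denominator with nonzero product is an error.
    """
    a, b = fit.alpha, fit.beta
    se_a, se_b = fit.alpha_se, fit.beta_se
    if se_a < 0 or se_b < 0 or np.isnan(se_a) or np.isnan(se_b):
        raise ValueError("Sobel test requires non-negative standard errors")
    num = a * b
    denom = math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    if num == 0:
        return 0.0, 1.0
    if denom == 0:
        raise ValueError("zero Sobel denominator with nonzero indirect effect")
    z = num / denom
    return z, 2 * stats.norm.sf(abs(z))


def _fit_arrays(P, M, G, covs_m, covs_p, ones):
    """Lean path-model refit for resampling loops: returns (alpha, beta,
    gamma') only, skipping SEs and the dataclass."""
    Xm = np.column_stack([ones, G, covs_m])
    cm = np.linalg.lstsq(Xm, M, rcond=None)[0]
    Xp = np.column_stack([ones, M, G, covs_p])
    cp = np.linalg.lstsq(Xp, P, rcond=None)[0]
    return cm[1], cp[1], cp[2]


class MediationModel(BaseEstimator):
    """Sklearn-style estimator for the two-equation mediation path model.

    ``fit(X, y)`` takes ``X`` as a DataFrame (or dict of arrays) holding the
    marker ``G``, mediator ``M`` and the six covariate columns ``CGbm``,
    ``Srm``, ``CGbp``, ``Srp``, ``damline``; ``y`` is the standardized
    phenotype.

    Attributes (fitted)
    -------------------
    alpha_, beta_, gamma_direct_ : float
        Path coefficients and, with ``*_se_``, their classical SEs.
    indirect_ : float
        Mediated effect alpha' * beta'.
    ratio_ : float
        |indirect| / |direct| screening ratio.
    path_fit_ : PathFit
        Full record including nuisance coefficients.
    """

    def fit(self, X, y) -> "MediationModel":
        X = {k: np.asarray(v, float) for k, v in dict(X).items()}
        covs_m = np.column_stack([X["CGbm"], X["damline"], X["Srm"]])
        covs_p = np.column_stack([X["CGbp"], X["damline"], X["Srp"]])
        fit = fit_mediation(np.asarray(y, float), X["M"], X["G"], covs_m, covs_p)
        self.path_fit_ = fit
        self.alpha_, self.alpha_se_ = fit.alpha, fit.alpha_se
        self.beta_, self.beta_se_ = fit.beta, fit.beta_se
        self.gamma_direct_, self.gamma_direct_se_ = fit.gamma_direct, fit.gamma_direct_se
        self.indirect_ = fit.indirect
        self.ratio_ = fit.ratio
        return self

    def sobel_(self) -> tuple[float, float]:
        return sobel_test(self.path_fit_)
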