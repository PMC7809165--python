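"""Collapse cross-classified nuisance factors into standardized covariates.

Field trials record animals in a cross-classified design: contemporary group
(CG, same-sex batches entering the trial the same week), dam genetic line,
sire, and physical pen. Path models and SEMs are far easier to fit when these
factors are replaced by linear covariates. The two-step procedure is:

1. Fit, per response variable (a standardized trait or a CLR microbial
   feature), the mixed model

       y = CG + damline + sire + pen + e

   with CG, damline and sire fixed and pen a single random effect, estimating
   the pen and residual variances by REML.

2. Collapse the solutions into two per-individual covariates:

       CGb_i = CG solution of i's group  +  BLUP of i's pen
       Sr_i  = sire solution of i's sire

   each then standardized to mean 0, SD 1.

Because every individual sits in exactly one pen, the marginal covariance
``V = I + lambda * Z Z'`` (with ``lambda = var_pen / var_resid``) is block
diagonal with rank-one blocks, so REML reduces to a 1-D profiled likelihood
over ``log lambda`` with O(n) closed-form algebra per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MixedModelSolution",
    "fit_design_model",
    "collapse_covariates",
    "collapse_all",
    "DesignEffectCollapser",
]

REQUIRED_COLUMNS = ("cg", "damline", "sire", "pen")


@dataclass
class MixedModelSolution:
    """Solutions of the pen mixed model for one response."""

    cg_levels: list
    cg_solutions: np.ndarray  # per CG level, reference level = 0
    damline_coef: float
    sire_levels: list
    sire_solutions: np.ndarray  # per sire level, reference level = 0
    pen_levels: list
    pen_blup: np.ndarray  # shrunken pen predictions
    var_pen: float
    var_resid: float
    intercept: float
    converged: bool
    n_iter: int


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design frame missing columns: {missing}")
    return design


def _profile_reml(y, X, pen_idx, pen_sizes, max_log_lambda=12.0):
    """Profiled REML over the pen-to-residual variance ratio.

    For fixed ratio lambda, V = I + lambda*ZZ' is block diagonal over pens,
    giving closed-form GLS, residual variance and log-determinants. Returns
    the optimizer result plus the GLS pieces at the optimum.
    """
    n, p_full = X.shape
    n_pens = len(pen_sizes)
    # reduce X to an independent column basis (confounded fixed effects are
    # resolved by dropping pivoted-out columns; their solutions are 0)
    from scipy.linalg import qr as _qr

    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag[0] > 0 else 0
    keep = np.sort(piv[:rank])
    X = X[:, keep]

    def gls_pieces(lam):
        # V^-1 = I - (lam/(1+lam*k)) 1 1' within each pen of size k
        shrink = lam / (1.0 + lam * pen_sizes)  # per pen

        def vinv(M):  # M is n x q
            sums = np.zeros((n_pens, M.shape[1]))
            np.add.at(sums, pen_idx, M)
            return M - shrink[pen_idx, None] * sums[pen_idx]

        Xv = vinv(X)
        yv = vinv(y[:, None])[:, 0]
        XtVX = X.T @ Xv
        XtVy = X.T @ yv
        beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
        resid = y - X @ beta
        rv = vinv(resid[:, None])[:, 0]
        quad = resid @ rv
        logdet_v = np.sum(np.log1p(lam * pen_sizes))
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        return beta, resid, quad, logdet_v, logdet_xvx

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        _, _, quad, logdet_v, logdet_xvx = gls_pieces(lam)
        sigma2 = quad / (n - rank)
        return 0.5 * (logdet_v + (n - rank) * np.log(sigma2) + logdet_xvx)

    res = minimize_scalar(
        neg_reml, bounds=(-18.0, max_log_lambda), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    # boundary: ratio indistinguishable from zero
    if neg_reml(-18.0) <= res.fun + 1e-10:
        lam = 0.0
    beta, resid, quad, _, _ = gls_pieces(lam)
    sigma2 = float(quad / (n - rank))
    # BLUP: u_j = lam * sum of V^-1-weighted residuals within pen j
    pen_sums = np.zeros(n_pens)
    np.add.at(pen_sums, pen_idx, resid)
    u = lam * pen_sums / (1.0 + lam * pen_sizes)
    beta_full = np.zeros(p_full)
    beta_full[keep] = beta
    return beta_full, u, lam * sigma2, sigma2, res


def fit_design_model(y: np.ndarray, design: pd.DataFrame) -> MixedModelSolution:
    """REML fit of ``y = CG + damline + sire + pen(random) + e``.

    ``y`` should be the standardized response (mean 0, SD 1). Fixed effects
    use drop-first reference coding for CG and sire; dam line enters as the
    numeric 1/2 code. Returns fixed solutions, BLUP pen predictions and the
    two variance components.
    """
    design = _validate_design(design)
    y = np.asarray(y, dtype=float)
    if len(y) != len(design):
        raise ValueError("response and design frame have different lengths")

    cg_levels = sorted(pd.unique(design["cg"]))
    sire_levels = sorted(pd.unique(design["sire"]))
    pen_levels = sorted(pd.unique(design["pen"]))
    cg_idx = pd.Categorical(design["cg"], categories=cg_levels).codes
    sire_idx = pd.Categorical(design["sire"], categories=sire_levels).codes
    pen_idx = pd.Categorical(design["pen"], categories=pen_levels).codes
    pen_sizes = np.bincount(pen_idx, minlength=len(pen_levels)).astype(float)

    n = len(y)
    # X = [1 | CG dummies (drop first) | damline | sire dummies (drop first)]
    X_cg = np.zeros((n, len(cg_levels) - 1))
    nz = cg_idx > 0
    X_cg[np.where(nz)[0], cg_idx[nz] - 1] = 1.0
    X_s = np.zeros((n, len(sire_levels) - 1))
    nz = sire_idx > 0
    X_s[np.where(nz)[0], sire_idx[nz] - 1] = 1.0
    X = np.column_stack([np.ones(n), X_cg, design["damline"].to_numpy(float), X_s])

    beta, u, var_pen, var_resid, res = _profile_reml(y, X, pen_idx, pen_sizes)

    n_cg = len(cg_levels)
    cg_sol = np.concatenate([[0.0], beta[1 : n_cg]])
    damline_coef = float(beta[n_cg])
    sire_sol = np.concatenate([[0.0], beta[n_cg + 1 :]])

    return MixedModelSolution(
        cg_levels=cg_levels,
        cg_solutions=cg_sol,
        damline_coef=damline_coef,
        sire_levels=sire_levels,
        sire_solutions=sire_sol,
        pen_levels=pen_levels,
        pen_blup=u,
        var_pen=float(var_pen),
        var_resid=float(var_resid),
        intercept=float(beta[0]),
        converged=bool(res.success),
        n_iter=int(res.nfev),
    )


def collapse_covariates(
    solution: MixedModelSolution, design: pd.DataFrame, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Build the collapsed covariates (CGb, Sr) from a fitted solution.

    ``CGb_i`` sums the fixed CG solution and the pen BLUP of individual i;
    ``Sr_i`` is the sire solution. Both are standardized to mean 0, SD 1
    unless ``standardize=False``.
    """
    design = _validate_design(design)
    cg_map = {lvl: s for lvl, s in zip(solution.cg_levels, solution.cg_solutions)}
    sire_map = {lvl: s for lvl, s in zip(solution.sire_levels, solution.sire_solutions)}
    pen_map = {lvl: s for lvl, s in zip(solution.pen_levels, solution.pen_blup)}
    for col, mapping in (("cg", cg_map), ("sire", sire_map), ("pen", pen_map)):
        unseen = set(design[col]) - set(mapping)
        if unseen:
            raise ValueError(f"unseen {col} levels: {sorted(unseen)}")
    cgb = design["cg"].map(cg_map).to_numpy(float) + design["pen"].map(pen_map).to_numpy(float)
    sr = design["sire"].map(sire_map).to_numpy(float)
    if standardize:
        cgb = _standardize(cgb)
        sr = _standardize(sr)
    return cgb, sr


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def collapse_all(responses: pd.DataFrame, design: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Fit + collapse for every column of ``responses``.

    Returns a dict mapping response name to a DataFrame with columns
    ``CGb`` and ``Sr`` (one standardized covariate pair per response, as the
    path models require).
    """
    out = {}
    for name in responses.columns:
        y = responses[name].to_numpy(float)
        y = (y - y.mean()) / y.std()
        est = DesignEffectCollapser().fit(design, y)
        out[name] = est.transform(design)
    return out


class DesignEffectCollapser(BaseEstimator, TransformerMixin):
    """Transformer collapsing the cross-classified design for one response.

    ``fit(design, y)`` runs the REML mixed model on the standardized
    response ``y``; ``transform(design)`` returns the standardized
    ``(CGb, Sr)`` covariate pair as a two-column DataFrame.

    Attributes
    ----------
    solution_ : MixedModelSolution
        Fixed solutions, pen BLUPs and variance components.
    var_pen_, var_resid_ : float
        REML variance components.
    """

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "DesignEffectCollapser":
        self.solution_ = fit_design_model(np.asarray(y, float), X)
        self.var_pen_ = self.solution_.var_pen
        self.var_resid_ = self.solution_.var_resid
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "solution_"):
            raise ValueError("DesignEffectCollapser is not fitted")
        cgb, sr = collapse_covariates(self.solution_, X)
        return pd.DataFrame({"CGb": cgb, "Sr": sr}, index=X.index)
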