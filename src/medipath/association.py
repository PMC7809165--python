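"""Single-feature association scans with collapsed design covariates.

One OLS engine serves three scans:

* GWAS (Mod1): phenotype on marker dosage -> total effect gamma
* MWAS (Mod2): phenotype on CLR microbial feature -> effect beta
* G->M scan (Mod3): CLR microbial feature on marker dosage -> effect alpha

Each fit regresses the response on [intercept, feature, CGb, damline, Sr]
and reports the feature coefficient, its classical SE, the t-test p-value
on n-5 degrees of freedom, multiplicity-adjusted p-values and (for MWAS)
the proportion of response variance absorbed by the fitted feature term.

The scan is vectorized over features via Frisch-Waugh-Lovell: response and
features are residualized on the covariate block, the per-feature slope is
the simple-regression slope of the residuals, and the residual variance uses
the full-model degrees of freedom — numerically identical to the per-feature
normal-equations solve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "scan",
    "variance_absorbed",
    "adjust_pvalues",
    "AssociationScan",
]


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment: ``bonferroni`` (min(1, m*p)) or ``fdr_bh``."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def variance_absorbed(coefficient: float, feature_values: np.ndarray) -> float:
    """Variance of the fitted feature contribution ``coef * feature``.

    With the response standardized to variance 1 this is directly the
    proportion of phenotypic variance absorbed by the feature. Population
    variance convention (divide by n).
    """
    feature_values = np.asarray(feature_values, dtype=float)
    if feature_values.size == 0:
        raise ValueError("empty feature vector")
    return float(coefficient**2 * feature_values.var())


def scan(
    responses: pd.DataFrame,
    features: pd.DataFrame,
    covariates: dict[str, pd.DataFrame],
    damline: np.ndarray,
    model: str = "mod1",
) -> pd.DataFrame:
    """Scan every (response, feature) pair with the covariate-adjusted OLS.

    Parameters
    ----------
    responses : DataFrame, n x r
        Standardized responses (phenotypes for Mod1/Mod2, CLR features for
        Mod3).
    features : DataFrame, n x m
        Marker dosages (Mod1/Mod3) or CLR abundances (Mod2).
    covariates : dict response-name -> DataFrame with columns CGb, Sr
        One collapsed covariate pair per response.
    damline : array
        Dam-line code (1/2), shared across responses.
    model : str
        Label recorded in the output (mod1 | mod2 | mod3).

    Returns a tidy DataFrame with one row per response x feature, including
    ``coef``, ``se``, ``t``, ``p``, ``p_bonferroni``, ``p_fdr``,
    ``var_absorbed`` and the covariate coefficients ``b1`` (CGb), ``b2``
    (damline), ``b3`` (Sr). Zero-variance features are flagged
    ``untestable`` rather than dropped. The Bonferroni/FDR family is the
    set of features tested for each response.
    """
    damline = np.asarray(damline, dtype=float)
    n = len(features)
    F = features.to_numpy(dtype=float)
    rows = []
    for resp_name in responses.columns:
        y = responses[resp_name].to_numpy(dtype=float)
        cov = covariates[resp_name]
        C = np.column_stack([np.ones(n), cov["CGb"], damline, cov["Sr"]])
        res = _fwl_scan(y, F, C)
        res["response"] = resp_name
        res["feature"] = list(features.columns)
        res["model"] = model
        testable = ~res["untestable"]
        for method, col in (("bonferroni", "p_bonferroni"), ("fdr_bh", "p_fdr")):
            adj = np.full(len(res), np.nan)
            if testable.any():
                adj[testable.to_numpy()] = adjust_pvalues(
                    res.loc[testable, "p"].to_numpy(), method
                )
            res[col] = adj
        res["var_absorbed"] = [
            variance_absorbed(c, F[:, j]) if t else np.nan
            for j, (c, t) in enumerate(zip(res["coef"], testable))
        ]
        rows.append(res)
    out = pd.concat(rows, ignore_index=True)
    cols = [
        "model", "response", "feature", "coef", "se", "t", "p",
        "p_bonferroni", "p_fdr", "var_absorbed", "b1", "b2", "b3",
        "untestable",
    ]
    return out[cols]


def _fwl_scan(y: np.ndarray, F: np.ndarray, C: np.ndarray) -> pd.DataFrame:
    """Vectorized per-feature OLS of y on [C, feature] via residualization."""
    n, m = F.shape
    p_cov = C.shape[1]
    df = n - p_cov - 1
    # residualize y and all features on the covariate block
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    F_res = F - Q @ (Q.T @ F)
    sxx = np.einsum("ij,ij->j", F_res, F_res)
    untestable = sxx <= 1e-12 * n
    sxx_safe = np.where(untestable, 1.0, sxx)
    coef = (F_res.T @ y_res) / sxx_safe
    rss = y_res @ y_res - coef**2 * sxx_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    # covariate coefficients from the full per-feature fit (cheap loop only
    # for reporting; slope/SE above are exact already)
    CtC_inv = np.linalg.pinv(C.T @ C)
    base = CtC_inv @ (C.T @ y)
    adj = CtC_inv @ (C.T @ F)  # covariate coefs shift by -adj * slope
    b_full = base[:, None] - adj * coef[None, :]
    coef = np.where(untestable, np.nan, coef)
    se = np.where(untestable, np.nan, se)
    t = np.where(untestable, np.nan, t)
    p = np.where(untestable, np.nan, p)
    return pd.DataFrame(
        {
            "coef": coef, "se": se, "t": t, "p": p,
            "b1": b_full[1], "b2": b_full[2], "b3": b_full[3],
            "untestable": untestable,
        }
    )


class AssociationScan(BaseEstimator):
    """Sklearn-style wrapper around the single-feature scan.

    Parameters
    ----------
    model : str
        Scan label: ``mod1`` (GWAS), ``mod2`` (MWAS) or ``mod3`` (G->M).

    After ``fit(features, responses, covariates=..., damline=...)`` the tidy
    result table is available as ``results_``.
    """

    def __init__(self, model: str = "mod1"):
        self.model = model

    def fit(self, X: pd.DataFrame, y: pd.DataFrame, *, covariates, damline):
        if isinstance(y, pd.Series):
            y = y.to_frame()
        self.results_ = scan(y, X, covariates, damline, model=self.model)
        return self
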