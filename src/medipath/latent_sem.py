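"""Latent-variable structural equation models for mediation genome scans.

A latent phenotype Pi (e.g. overall fat deposition) is measured by three
correlated indicators. Nuisance design effects enter through two latent
adjuster constructs, each built on the three per-trait collapsed covariates
(CGpi on the three CGb variables, Srpi on the three Sr variables). Three
structural layouts are supported:

* ``mod1l``  Pi ~ G + CGpi + D + Srpi              (latent GWAS, total effect)
* ``mod2l``  Pi ~ M + CGpi + D + Srpi              (latent MWAS)
* ``mod4l``  M ~ G (+ covariates);  Pi ~ M + G + CGpi + D + Srpi
             (latent mediation; indirect effect = alpha' * beta'_Pi)
* ``cfa``    measurement model only (no structural predictors)

Estimation minimizes the maximum-likelihood discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - k

over the model-implied covariance Sigma(theta) of all observed variables,
with the mean structure saturated. The model is parameterized in RAM form
(v = A v + u, Sigma = F (I-A)^-1 S0 (I-A)^-T F'). Identification follows the
marker-variable convention: the first loading of every latent construct is
fixed to 1. Variances are optimized on the log scale with an analytic
gradient; standard errors come from the inverse observed information.
Exogenous observed predictors (G, M, D, mediator covariates) have their
covariance block fixed at the sample moments (the conditional-ML, x-fixed
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "LatentSpec",
    "SemFit",
    "fit_sem",
    "indirect_effect_latent",
    "LatentMediationSEM",
]

_LOG_VAR_LB = -18.0  # lower bound on log variances; active bound => Heywood


@dataclass
class LatentSpec:
    """Measurement specification for one latent phenotype.

    ``indicators`` are the measured traits loading on the factor;
    ``cg_adjusters``/``sr_adjusters`` are the per-trait collapsed design
    covariates defining the two latent nuisance constructs (may be empty,
    in which case the corresponding construct is omitted).
    """

    name: str
    indicators: list[str]
    cg_adjusters: list[str] = field(default_factory=list)
    sr_adjusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.indicators) < 3:
            raise ValueError("a latent construct needs at least 3 indicators")
        if self.cg_adjusters and len(self.cg_adjusters) != len(self.indicators):
            raise ValueError("one CG adjuster per indicator expected")
        if self.sr_adjusters and len(self.sr_adjusters) != len(self.indicators):
            raise ValueError("one Sr adjuster per indicator expected")
        overlap = set(self.indicators) & (set(self.cg_adjusters) | set(self.sr_adjusters))
        if overlap:
            raise ValueError(f"indicators and adjusters overlap: {sorted(overlap)}")


@dataclass
class SemFit:
    """Fitted SEM: loadings, uniquenesses, structural coefficients."""

    model: str
    factor: str
    loadings: dict[str, dict[str, tuple[float, float]]]  # construct -> var -> (est, se)
    uniquenesses: dict[str, float]
    heywood: list[str]
    structural: dict[str, tuple[float, float]]  # path name -> (est, se)
    factor_disturbance: float
    m_disturbance: float | None
    discrepancy: float
    n: int
    converged: bool
    n_iter: int
    param_names: list[str]
    theta: np.ndarray
    cov_theta: np.ndarray | None


class _RamModel:
    """RAM-parameterized covariance structure with analytic gradient."""

    def __init__(self, var_names: list[str], obs_names: list[str]):
        self.var_names = var_names
        self.index = {v: i for i, v in enumerate(var_names)}
        self.obs_idx = np.array([self.index[v] for v in obs_names])
        self.T = len(var_names)
        self.param_names: list[str] = []
        self.param_init: list[float] = []
        self.param_is_log: list[bool] = []
        self.A_free: list[tuple[int, int, int]] = []
        self.A_fixed: list[tuple[int, int, float]] = []
        self.S_free: list[tuple[int, int, int]] = []
        self.S_fixed: list[tuple[int, int, float]] = []

    def _new_param(self, name, init, is_log):
        self.param_names.append(name)
        self.param_init.append(math.log(max(init, 1e-8)) if is_log else init)
        self.param_is_log.append(is_log)
        return len(self.param_names) - 1

    def add_path(self, src, dst, name=None, init=0.0, fixed=None):
        i, j = self.index[dst], self.index[src]
        if fixed is not None:
            self.A_fixed.append((i, j, fixed))
        else:
            k = self._new_param(name or f"{dst}~{src}", init, False)
            self.A_free.append((i, j, k))

    def add_variance(self, var, name=None, init=1.0, fixed=None):
        i = self.index[var]
        if fixed is not None:
            self.S_fixed.append((i, i, fixed))
        else:
            k = self._new_param(name or f"var({var})", init, True)
            self.S_free.append((i, i, k))

    def add_covariance(self, a, b, name=None, init=0.0, fixed=None):
        i, j = self.index[a], self.index[b]
        if fixed is not None:
            self.S_fixed.append((i, j, fixed))
        else:
            k = self._new_param(name or f"cov({a},{b})", init, False)
            self.S_free.append((i, j, k))

    # -- matrices ---------------------------------------------------------
    def _natural(self, theta):
        out = np.array(theta, float)
        log_mask = np.array(self.param_is_log)
        out[log_mask] = np.exp(out[log_mask])
        return out

    def matrices(self, theta):
        nat = self._natural(theta)
        A = np.zeros((self.T, self.T))
        for i, j, v in self.A_fixed:
            A[i, j] = v
        for i, j, k in self.A_free:
            A[i, j] = nat[k]
        S0 = np.zeros((self.T, self.T))
        for i, j, v in self.S_fixed:
            S0[i, j] = v
            S0[j, i] = v
        for i, j, k in self.S_free:
            S0[i, j] = nat[k]
            S0[j, i] = nat[k]
        return A, S0

    def implied(self, theta):
        A, S0 = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.T) - A)
        full = B @ S0 @ B.T
        return full[np.ix_(self.obs_idx, self.obs_idx)], B, S0

    def discrepancy(self, theta, S, logdet_S):
        Sig, _, _ = self.implied(theta)
        sign, logdet = np.linalg.slogdet(Sig)
        if sign <= 0:
            return 1e12
        try:
            Sig_inv = np.linalg.inv(Sig)
        except np.linalg.LinAlgError:
            return 1e12
        return float(logdet + np.sum(Sig_inv * S) - logdet_S - S.shape[0])

    def gradient(self, theta, S):
        """Analytic gradient of the ML discrepancy.

        Uses dF = tr[W dSigma] with W = Sigma^-1 (Sigma - S) Sigma^-1,
        chained through the RAM structure:
        dF/dA = 2 B' Wf B S0 B',  dF/dS0 = B' Wf B (off-diagonals doubled),
        where Wf embeds W at the observed rows/columns.
        """
        Sig, B, S0 = self.implied(theta)
        Sig_inv = np.linalg.inv(Sig)
        W = Sig_inv - Sig_inv @ S @ Sig_inv
        Wf = np.zeros((self.T, self.T))
        Wf[np.ix_(self.obs_idx, self.obs_idx)] = W
        BtWfB = B.T @ Wf @ B
        GA = 2.0 * (BtWfB @ S0 @ B.T)
        grad = np.zeros(len(self.param_names))
        for i, j, k in self.A_free:
            grad[k] += GA[i, j]
        for i, j, k in self.S_free:
            grad[k] += BtWfB[i, j] if i == j else 2.0 * BtWfB[i, j]
        nat = self._natural(theta)
        log_mask = np.array(self.param_is_log)
        grad[log_mask] *= nat[log_mask]  # chain rule through log-variances
        return grad

    def fit(self, S, theta0=None, gtol=1e-8, maxiter=500):
        logdet_S = np.linalg.slogdet(S)[1]
        bounds = [
            (_LOG_VAR_LB, 20.0) if is_log else (None, None)
            for is_log in self.param_is_log
        ]
        starts = [np.array(self.param_init, float)]
        if theta0 is not None:
            starts.insert(0, np.asarray(theta0, float))
        best = None
        for start in starts:
            res = minimize(
                self.discrepancy, start, args=(S, logdet_S),
                jac=lambda th, S=S, ld=logdet_S: self.gradient(th, S),
                method="L-BFGS-B", bounds=bounds,
                options={"gtol": gtol, "maxiter": maxiter, "ftol": 1e-14},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if not best.success and best.fun >= 1e11:
            raise RuntimeError(f"SEM optimizer failed: {best.message}")
        return best

    def hessian(self, theta, S, eps=1e-5):
        """Numeric Hessian of F from central differences of the analytic
        gradient (symmetrized)."""
        p = len(theta)
        H = np.zeros((p, p))
        for k in range(p):
            step = eps * max(1.0, abs(theta[k]))
            tp, tm = np.array(theta), np.array(theta)
            tp[k] += step
            tm[k] -= step
            H[:, k] = (self.gradient(tp, S) - self.gradient(tm, S)) / (2 * step)
        return 0.5 * (H + H.T)


def _build_model(spec: LatentSpec, structural: str, g_col, m_col, damline_col,
                 m_cov_cols, data: pd.DataFrame):
    structural = structural.lower()
    if structural not in ("mod1l", "mod2l", "mod4l", "cfa"):
        raise ValueError(f"unknown structural model {structural!r}")
    need_g = structural in ("mod1l", "mod4l")
    need_m = structural in ("mod2l", "mod4l")
    if need_g and g_col is None:
        raise ValueError(f"{structural} requires a marker column")
    if need_m and m_col is None:
        raise ValueError(f"{structural} requires a mediator column")

    obs = list(spec.indicators) + list(spec.cg_adjusters) + list(spec.sr_adjusters)
    exog_obs: list[str] = []
    if need_m and structural == "mod2l":
        exog_obs.append(m_col)
    if need_g:
        exog_obs.append(g_col)
    if damline_col is not None and structural != "cfa":
        exog_obs.append(damline_col)
    m_covs = list(m_cov_cols) if (structural == "mod4l" and m_cov_cols) else []
    exog_obs += m_covs
    endog_m = m_col if structural == "mod4l" else None
    obs_all = obs + ([endog_m] if endog_m else []) + exog_obs

    missing = [c for c in obs_all if c not in data.columns]
    if missing:
        raise ValueError(f"data missing columns: {missing}")

    latents = [spec.name]
    if spec.cg_adjusters:
        latents.append("_CGpi")
    if spec.sr_adjusters:
        latents.append("_Srpi")

    X = data[obs_all].to_numpy(float)
    n = len(X)
    if n <= len(obs_all):
        raise ValueError("need more observations than observed variables")
    S = np.cov(X, rowvar=False, ddof=0)
    if np.linalg.slogdet(S)[0] <= 0:
        raise ValueError("sample covariance is not positive definite")
    sd = np.sqrt(np.diag(S))

    ram = _RamModel(obs_all + latents, obs_all)
    col = {v: obs_all.index(v) for v in obs_all}

    # measurement models; OLS-informed starts via the first indicator
    def add_construct(latent, inds, exogenous):
        ram.add_path(latent, inds[0], fixed=1.0)
        v0 = S[col[inds[0]], col[inds[0]]]
        for ind in inds[1:]:
            init = S[col[ind], col[inds[0]]] / v0
            ram.add_path(latent, ind, name=f"{ind}~{latent}", init=init)
        for ind in inds:
            ram.add_variance(ind, name=f"psi({ind})",
                             init=0.4 * S[col[ind], col[ind]])
        if exogenous:
            ram.add_variance(latent, name=f"var({latent})", init=0.6 * v0)
        else:
            ram.add_variance(latent, name=f"dist({latent})", init=0.6 * v0)

    add_construct(spec.name, spec.indicators, exogenous=False)
    if spec.cg_adjusters:
        add_construct("_CGpi", spec.cg_adjusters, exogenous=True)
    if spec.sr_adjusters:
        add_construct("_Srpi", spec.sr_adjusters, exogenous=True)

    # structural paths into Pi
    if need_m:
        ram.add_path(m_col, spec.name, name="beta_m")
    if need_g:
        ram.add_path(g_col, spec.name, name="gamma_g")
    if structural != "cfa":
        if spec.cg_adjusters:
            ram.add_path("_CGpi", spec.name, name="b_cg")
        if damline_col is not None:
            ram.add_path(damline_col, spec.name, name="b_d")
        if spec.sr_adjusters:
            ram.add_path("_Srpi", spec.name, name="b_sr")

    # mediator equation (mod4l)
    if endog_m:
        ram.add_path(g_col, endog_m, name="alpha",
                     init=S[col[endog_m], col[g_col]] / S[col[g_col], col[g_col]])
        if damline_col is not None:
            ram.add_path(damline_col, endog_m, name="m_b_d")
        for i, c in enumerate(m_covs):
            ram.add_path(c, endog_m, name=f"m_b_{c}")
        ram.add_variance(endog_m, name=f"dist({endog_m})",
                         init=0.8 * S[col[endog_m], col[endog_m]])

    # exogenous observed block fixed at sample moments
    for i, a in enumerate(exog_obs):
        for b in exog_obs[i:]:
            if a == b:
                ram.add_variance(a, fixed=S[col[a], col[a]])
            else:
                ram.add_covariance(a, b, fixed=S[col[a], col[b]])

    # free covariances among exogenous latents and with observed exogenous
    exog_lat = [l for l in ("_CGpi", "_Srpi") if l in latents]
    for i, a in enumerate(exog_lat):
        for b in exog_lat[i + 1:]:
            ram.add_covariance(a, b, name=f"cov({a},{b})")
        for b in exog_obs:
            ram.add_covariance(a, b, name=f"cov({a},{b})")

    return ram, S, obs_all, exog_obs, endog_m, n


def fit_sem(
    data: pd.DataFrame,
    spec: LatentSpec,
    structural: str = "mod4l",
    g_col: str | None = None,
    m_col: str | None = None,
    damline_col: str | None = None,
    m_cov_cols: tuple[str, ...] | None = None,
    compute_se: bool = True,
    theta0: np.ndarray | None = None,
) -> SemFit:
    """ML covariance-structure fit of a latent-phenotype model.

    ``data`` holds all observed variables as columns. ``structural`` picks
    the layout (``mod1l``, ``mod2l``, ``mod4l`` or ``cfa``); ``g_col`` /
    ``m_col`` name the marker and mediator columns where required, and
    ``m_cov_cols`` the mediator-equation covariates (CGbm, Srm) for
    ``mod4l``. ``theta0`` warm-starts the optimizer (used by resampling
    loops together with ``compute_se=False``).
    """
    ram, S, obs_all, exog_obs, endog_m, n = _build_model(
        spec, structural, g_col, m_col, damline_col, m_cov_cols, data
    )
    res = ram.fit(S, theta0=theta0)
    theta = res.x
    nat = ram._natural(theta)

    cov_theta = None
    se_nat = np.full(len(theta), np.nan)
    if compute_se:
        H = ram.hessian(theta, S)
        info = (n / 2.0) * H
        try:
            cov_theta = np.linalg.inv(info)
            se_theta = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
            # delta method back to the natural scale for log-variances
            se_nat = np.where(ram.param_is_log, nat * se_theta, se_theta)
        except np.linalg.LinAlgError:
            pass

    by_name = {nm: (float(nat[k]), float(se_nat[k]))
               for k, nm in enumerate(ram.param_names)}

    loadings: dict[str, dict[str, tuple[float, float]]] = {}
    for construct, inds in (
        (spec.name, spec.indicators),
        ("_CGpi", spec.cg_adjusters),
        ("_Srpi", spec.sr_adjusters),
    ):
        if not inds:
            continue
        entry = {inds[0]: (1.0, 0.0)}
        for ind in inds[1:]:
            entry[ind] = by_name[f"{ind}~{construct}"]
        loadings["CGpi" if construct == "_CGpi" else
                 "Srpi" if construct == "_Srpi" else construct] = entry

    uniq, heywood = {}, []
    for nm, (est, _) in by_name.items():
        if nm.startswith("psi("):
            var = nm[4:-1]
            uniq[var] = est
            if math.log(max(est, 1e-300)) <= _LOG_VAR_LB + 1e-6:
                heywood.append(var)

    structural_paths = {
        nm: val for nm, val in by_name.items()
        if nm in ("beta_m", "gamma_g", "b_cg", "b_d", "b_sr", "alpha", "m_b_d")
        or nm.startswith("m_b_")
    }

    return SemFit(
        model=structural.lower(),
        factor=spec.name,
        loadings=loadings,
        uniquenesses=uniq,
        heywood=heywood,
        structural=structural_paths,
        factor_disturbance=by_name[f"dist({spec.name})"][0],
        m_disturbance=by_name[f"dist({endog_m})"][0] if endog_m else None,
        discrepancy=float(res.fun),
        n=n,
        converged=bool(res.success),
        n_iter=int(res.nit),
        param_names=list(ram.param_names),
        theta=theta,
        cov_theta=cov_theta,
    )


def indirect_effect_latent(fit: SemFit) -> float:
    """Mediated effect on the latent phenotype: alpha' * beta'_Pi.

    Only defined for a ``mod4l`` fit, which carries both the G->M
    regression and the M->Pi structural path.
    """
    if fit.model != "mod4l":
        raise ValueError(
            f"indirect effect requires a mod4l fit, got {fit.model!r}"
        )
    return fit.structural["alpha"][0] * fit.structural["beta_m"][0]


class LatentMediationSEM(BaseEstimator):
    """Sklearn-style estimator wrapping :func:`fit_sem`.

    Parameters mirror the function arguments; ``fit(X)`` takes the observed
    data frame. Fitted attributes: ``fit_`` (the :class:`SemFit`),
    ``loadings_``, ``structural_``, ``indirect_`` (mod4l only) and
    ``discrepancy_``.
    """

    def __init__(
        self,
        spec: LatentSpec = None,
        structural: str = "mod4l",
        g_col: str | None = None,
        m_col: str | None = None,
        damline_col: str | None = None,
        m_cov_cols: tuple[str, ...] | None = None,
        compute_se: bool = True,
    ):
        self.spec = spec
        self.structural = structural
        self.g_col = g_col
        self.m_col = m_col
        self.damline_col = damline_col
        self.m_cov_cols = m_cov_cols
        self.compute_se = compute_se

    def fit(self, X: pd.DataFrame, y=None) -> "LatentMediationSEM":
        if self.spec is None:
            raise ValueError("a LatentSpec is required")
        self.fit_ = fit_sem(
            X, self.spec, self.structural, self.g_col, self.m_col,
            self.damline_col, self.m_cov_cols, compute_se=self.compute_se,
        )
        self.loadings_ = self.fit_.loadings
        self.structural_ = self.fit_.structural
        self.discrepancy_ = self.fit_.discrepancy
        if self.fit_.model == "mod4l":
            self.indirect_ = indirect_effect_latent(self.fit_)
        return self
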