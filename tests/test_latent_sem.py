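import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import FactorAnalysis

from medipath.latent_sem import (
    LatentMediationSEM,
    LatentSpec,
    _build_model,
    fit_sem,
    indirect_effect_latent,
)


def one_factor_data(seed=0, n=2000, loadings=(1.0, 0.8, 0.6), uniq=0.5,
                    factor_var=1.0):
    rng = np.random.default_rng(seed)
    f = rng.normal(0, np.sqrt(factor_var), n)
    Y = np.column_stack([
        lam * f + rng.normal(0, np.sqrt(uniq), n) for lam in loadings
    ])
    return pd.DataFrame(Y, columns=["y1", "y2", "y3"])


def mediated_latent_data(seed=0, n=2000, alpha=0.5, beta=0.4, gamma=0.1,
                         loadings=(1.0, 0.8, 0.6), uniq=0.5):
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, 0.3, n).astype(float)
    D = rng.integers(1, 3, n).astype(float)
    M = alpha * G + rng.normal(size=n)
    cg_core = rng.normal(size=n)
    sr_core = rng.normal(size=n)
    f = beta * M + gamma * G + 0.3 * cg_core + 0.2 * sr_core + rng.normal(size=n)
    Y = np.column_stack([
        lam * f + rng.normal(0, np.sqrt(uniq), n) for lam in loadings
    ])
    cg = np.column_stack([cg_core + 0.4 * rng.normal(size=n) for _ in range(3)])
    sr = np.column_stack([sr_core + 0.4 * rng.normal(size=n) for _ in range(3)])
    return pd.DataFrame(
        np.column_stack([Y, cg, sr, M, G, D]),
        columns=["y1", "y2", "y3", "cg1", "cg2", "cg3",
                 "sr1", "sr2", "sr3", "M", "G", "D"],
    )


SPEC_PLAIN = LatentSpec("F", ["y1", "y2", "y3"])
SPEC_FULL = LatentSpec(
    "F", ["y1", "y2", "y3"], ["cg1", "cg2", "cg3"], ["sr1", "sr2", "sr3"]
)


class TestSpec:
    def test_needs_three_indicators(self):
        with pytest.raises(ValueError, match="3 indicators"):
            LatentSpec("F", ["y1", "y2"])

    def test_overlapping_adjusters_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            LatentSpec("F", ["y1", "y2", "y3"], ["y1", "c2", "c3"])


class TestFit:
    def test_exactly_identified_reproduces_sample_covariance(self):
        # a 3-indicator one-factor model has zero degrees of freedom: the
        # implied covariance reproduces S and the discrepancy vanishes
        data = one_factor_data(seed=1, n=500)
        fit = fit_sem(data, SPEC_PLAIN, "cfa")
        assert fit.discrepancy < 1e-9
        assert fit.converged

    def test_analytic_gradient_matches_finite_differences(self):
        data = one_factor_data(seed=2, n=300)
        ram, S, *_ = _build_model(SPEC_PLAIN, "cfa", None, None, None, None, data)
        theta = np.array(ram.param_init) + 0.13
        logdet_S = np.linalg.slogdet(S)[1]
        grad = ram.gradient(theta, S)
        fd = np.zeros_like(grad)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += 1e-6
            tm[k] -= 1e-6
            fd[k] = (
                ram.discrepancy(tp, S, logdet_S) - ram.discrepancy(tm, S, logdet_S)
            ) / 2e-6
        np.testing.assert_allclose(grad, fd, atol=1e-7)

    def test_loading_recovery_within_three_se(self):
        data = one_factor_data(seed=3, n=2000, loadings=(1.0, 0.8, 0.6), uniq=0.5)
        fit = fit_sem(data, SPEC_PLAIN, "cfa")
        for ind, true in zip(("y2", "y3"), (0.8, 0.6)):
            est, se = fit.loadings["F"][ind]
            assert abs(est - true) < 3 * se

    def test_matches_sklearn_factor_analysis(self):
        # dedicated ML factor-analysis routine as the independent oracle:
        # sklearn parameterizes with unit factor variance, so compare
        # lambda_i * sqrt(var_F)
        data = one_factor_data(seed=4, n=3000)
        fit = fit_sem(data, SPEC_PLAIN, "cfa")
        fa = FactorAnalysis(n_components=1, tol=1e-10, max_iter=10_000)
        fa.fit(data.to_numpy())
        theirs = fa.components_.ravel()
        ours = np.array([
            fit.loadings["F"][c][0] for c in ("y1", "y2", "y3")
        ]) * np.sqrt(fit.factor_disturbance)
        if np.sign(theirs[0]) != np.sign(ours[0]):
            theirs = -theirs
        np.testing.assert_allclose(ours, theirs, atol=1e-4)

    def test_degenerate_factor_equals_ols_on_indicator_mean(self):
        # equal loadings, vanishing uniqueness: the latent regression
        # collapses onto OLS of the indicator mean on G
        rng = np.random.default_rng(5)
        n = 1500
        G = rng.binomial(2, 0.3, n).astype(float)
        f = 0.3 * G + rng.normal(size=n)
        Y = np.column_stack([f + rng.normal(0, 1e-3, n) for _ in range(3)])
        data = pd.DataFrame(Y, columns=["y1", "y2", "y3"]).assign(G=G)
        fit = fit_sem(data, SPEC_PLAIN, "mod1l", g_col="G")
        ybar = Y.mean(axis=1)
        X = np.column_stack([np.ones(n), G])
        slope = np.linalg.lstsq(X, ybar, rcond=None)[0][1]
        assert abs(fit.structural["gamma_g"][0] - slope) < 1e-3

    def test_structural_recovery_mod4l(self):
        data = mediated_latent_data(seed=6, n=2000)
        fit = fit_sem(data, SPEC_FULL, "mod4l", g_col="G", m_col="M",
                      damline_col="D")
        for name, true in (("alpha", 0.5), ("beta_m", 0.4), ("gamma_g", 0.1)):
            est, se = fit.structural[name]
            assert abs(est - true) < 3 * se, name
        ind = indirect_effect_latent(fit)
        assert abs(ind - 0.2) < 0.06

    def test_information_matrix_nonsingular_at_optimum(self):
        data = one_factor_data(seed=7, n=800)
        fit = fit_sem(data, SPEC_PLAIN, "cfa")
        assert fit.cov_theta is not None
        assert np.all(np.isfinite(fit.cov_theta))

    def test_indicator_order_invariance(self):
        # permuting non-marker indicators leaves the standardized solution
        # unchanged; loadings follow the permutation
        data = one_factor_data(seed=8, n=1000)
        fit = fit_sem(data, SPEC_PLAIN, "cfa")
        spec_swapped = LatentSpec("F", ["y1", "y3", "y2"])
        fit2 = fit_sem(data, spec_swapped, "cfa")
        assert fit.loadings["F"]["y2"][0] == pytest.approx(
            fit2.loadings["F"]["y2"][0], abs=1e-6
        )
        assert fit.discrepancy == pytest.approx(fit2.discrepancy, abs=1e-9)

    def test_marker_switch_changes_scale_not_standardized_solution(self):
        data = one_factor_data(seed=9, n=1000)
        fit1 = fit_sem(data, LatentSpec("F", ["y1", "y2", "y3"]), "cfa")
        fit2 = fit_sem(data, LatentSpec("F", ["y2", "y1", "y3"]), "cfa")
        # standardized loadings lambda_i * sd(F) are constraint-invariant
        std1 = {
            k: v[0] * np.sqrt(fit1.factor_disturbance)
            for k, v in fit1.loadings["F"].items()
        }
        std2 = {
            k: v[0] * np.sqrt(fit2.factor_disturbance)
            for k, v in fit2.loadings["F"].items()
        }
        for k in std1:
            assert std1[k] == pytest.approx(std2[k], abs=1e-5)


class TestIndirect:
    def test_requires_mod4l(self):
        data = mediated_latent_data(seed=10, n=600)
        fit = fit_sem(data, SPEC_FULL, "mod1l", g_col="G", damline_col="D")
        with pytest.raises(ValueError, match="mod4l"):
            indirect_effect_latent(fit)

    def test_null_alpha_gives_null_indirect(self):
        data = mediated_latent_data(seed=11, n=1500, alpha=0.0)
        fit = fit_sem(data, SPEC_FULL, "mod4l", g_col="G", m_col="M",
                      damline_col="D")
        assert abs(indirect_effect_latent(fit)) < 0.05

    def test_consistent_with_measured_mediation_in_strong_factor_limit(self):
        # with near-zero uniqueness the latent model and the measured path
        # model on the first indicator agree on the indirect effect
        from medipath.mediation import fit_mediation

        data = mediated_latent_data(seed=12, n=2000, uniq=1e-4,
                                    loadings=(1.0, 1.0, 1.0))
        fit = fit_sem(data, SPEC_FULL, "mod4l", g_col="G", m_col="M",
                      damline_col="D")
        covs = np.column_stack([data["cg1"], data["D"], data["sr1"]])
        med = fit_mediation(
            data["y1"].to_numpy(), data["M"].to_numpy(), data["G"].to_numpy(),
            covs, covs,
        )
        assert abs(indirect_effect_latent(fit) - med.indirect) < 0.02


def test_estimator_wrapper():
    data = mediated_latent_data(seed=13, n=800)
    est = LatentMediationSEM(
        spec=SPEC_FULL, structural="mod4l", g_col="G", m_col="M",
        damline_col="D",
    ).fit(data)
    assert est.indirect_ == pytest.approx(
        est.structural_["alpha"][0] * est.structural_["beta_m"][0]
    )
    params = est.get_params()
    assert params["structural"] == "mod4l"
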