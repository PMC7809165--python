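import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from medipath.design_effects import (
    DesignEffectCollapser,
    collapse_all,
    collapse_covariates,
    fit_design_model,
)


def balanced_one_way(k=6, r=8, var_pen=0.4, var_e=1.0, seed=5):
    """Balanced pens-only design (single CG/sire/damline level)."""
    rng = np.random.default_rng(seed)
    pen = np.repeat(np.arange(1, k + 1), r)
    y = rng.normal(0, np.sqrt(var_pen), k)[pen - 1] + rng.normal(0, np.sqrt(var_e), k * r)
    design = pd.DataFrame({"cg": 1, "damline": 1, "sire": 1, "pen": pen})
    return y, design, pen


class TestReml:
    def test_balanced_anova_closed_form(self):
        # on a balanced one-way layout REML equals the ANOVA estimators
        # ((MSB - MSW)/r, MSW)
        k, r = 6, 8
        y, design, pen = balanced_one_way(k, r)
        sol = fit_design_model(y, design)
        groups = [y[pen == j] for j in range(1, k + 1)]
        means = np.array([g.mean() for g in groups])
        msb = r * ((means - y.mean()) ** 2).sum() / (k - 1)
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (k * (r - 1))
        np.testing.assert_allclose(sol.var_resid, msw, rtol=1e-5)
        np.testing.assert_allclose(sol.var_pen, (msb - msw) / r, rtol=1e-5)

    def test_zero_pen_variance_matches_ols(self):
        # no pen signal: variance ratio collapses to ~0 and fixed solutions
        # match plain OLS on CG + damline + sire
        rng = np.random.default_rng(11)
        n = 300
        design = pd.DataFrame({
            "cg": rng.integers(1, 5, n),
            "damline": rng.integers(1, 3, n),
            "sire": rng.integers(1, 7, n),
            "pen": rng.integers(1, 30, n),
        })
        y = (
            0.5 * (design["cg"] == 2)
            + 0.3 * design["damline"]
            - 0.4 * (design["sire"] == 3)
            + rng.normal(size=n)
        ).to_numpy()
        sol = fit_design_model(y, design)
        assert sol.var_pen < 0.02 * sol.var_resid
        df = design.assign(y=y)
        ols = smf.ols("y ~ C(cg) + damline + C(sire)", df).fit()
        np.testing.assert_allclose(
            sol.cg_solutions[1:],
            [ols.params[f"C(cg)[T.{lv}]"] for lv in sol.cg_levels[1:]],
            atol=5e-3,
        )
        np.testing.assert_allclose(sol.damline_coef, ols.params["damline"], atol=5e-3)

    def test_blup_shrinkage_between_extremes(self):
        # BLUPs sit between 0 (ratio -> 0) and the within-pen residual
        # means (ratio -> infinity), shrinking monotonically
        y, design, pen = balanced_one_way(k=3, r=10, var_pen=1.0, seed=2)
        sol = fit_design_model(y, design)
        resid_means = np.array([
            (y - y.mean())[pen == j].mean() for j in (1, 2, 3)
        ])
        assert np.all(np.abs(sol.pen_blup) <= np.abs(resid_means) + 1e-9)
        assert np.all(np.sign(sol.pen_blup) == np.sign(resid_means))
        # shrinkage factor lambda*r/(1+lambda*r) is shared on a balanced design
        factors = sol.pen_blup / resid_means
        np.testing.assert_allclose(factors, factors[0], rtol=1e-6)
        assert 0 < factors[0] < 1

    def test_matches_statsmodels_mixedlm(self):
        # independent mixed-model oracle on a crossed design with real
        # pen signal
        rng = np.random.default_rng(21)
        n = 400
        design = pd.DataFrame({
            "cg": rng.integers(1, 6, n),
            "damline": rng.integers(1, 3, n),
            "sire": rng.integers(1, 9, n),
            "pen": rng.integers(1, 25, n),
        })
        pen_eff = rng.normal(0, 0.5, 24)
        y = (
            0.4 * (design["cg"] == 3)
            + 0.2 * design["damline"]
            + pen_eff[design["pen"] - 1]
            + rng.normal(size=n)
        ).to_numpy()
        y = (y - y.mean()) / y.std()
        sol = fit_design_model(y, design)
        df = design.assign(y=y)
        mlm = smf.mixedlm(
            "y ~ C(cg) + damline + C(sire)", df, groups=df["pen"]
        ).fit(reml=True, method="bfgs")
        np.testing.assert_allclose(sol.var_resid, mlm.scale, rtol=1e-3)
        np.testing.assert_allclose(
            sol.var_pen, float(mlm.cov_re.iloc[0, 0]), rtol=2e-2, atol=1e-4
        )
        np.testing.assert_allclose(
            sol.damline_coef, mlm.params["damline"], atol=1e-3
        )


class TestCollapse:
    def test_shared_level_and_pen_share_cgb(self):
        design = pd.DataFrame({
            "cg": [1, 1, 2, 2, 1, 2],
            "damline": [1, 2, 1, 2, 1, 2],
            "sire": [1, 2, 1, 2, 2, 1],
            "pen": [1, 1, 2, 2, 3, 4],
        })
        y = np.array([0.1, -0.2, 1.3, 0.9, 0.0, 1.1])
        sol = fit_design_model(y, design)
        cgb, sr = collapse_covariates(sol, design, standardize=False)
        assert cgb[0] == cgb[1]  # same CG and same pen
        # matrix-product oracle: X_cg @ b_cg + Z @ u, X_s @ b_s
        cg_idx = design["cg"].map({1: 0, 2: 1})
        pen_idx = design["pen"] - 1
        sire_idx = design["sire"] - 1
        np.testing.assert_allclose(
            cgb, sol.cg_solutions[cg_idx] + sol.pen_blup[pen_idx], atol=1e-12
        )
        np.testing.assert_allclose(sr, sol.sire_solutions[sire_idx], atol=1e-12)

    def test_standardized_outputs(self, tiny_cohort):
        y = tiny_cohort.phenotypes["BF2"].to_numpy()
        est = DesignEffectCollapser().fit(
            tiny_cohort.design, (y - y.mean()) / y.std()
        )
        covs = est.transform(tiny_cohort.design)
        for col in ("CGb", "Sr"):
            assert abs(covs[col].mean()) < 1e-9
            assert abs(covs[col].std(ddof=0) - 1) < 1e-9

    def test_unseen_level_errors(self):
        design = pd.DataFrame({
            "cg": [1, 1, 2, 2], "damline": [1, 2, 1, 2],
            "sire": [1, 2, 1, 2], "pen": [1, 2, 3, 4],
        })
        sol = fit_design_model(np.array([0.1, 0.4, -0.3, 0.2]), design)
        other = design.copy()
        other.loc[0, "sire"] = 99
        with pytest.raises(ValueError, match="unseen sire"):
            collapse_covariates(sol, other)

    def test_row_order_invariance(self, tiny_cohort):
        design = tiny_cohort.design.reset_index(drop=True)
        y = tiny_cohort.phenotypes["BF3"].to_numpy()
        y = (y - y.mean()) / y.std()
        sol = fit_design_model(y, design)
        cgb, sr = collapse_covariates(sol, design)
        perm = np.random.default_rng(0).permutation(len(y))
        sol_p = fit_design_model(y[perm], design.iloc[perm].reset_index(drop=True))
        cgb_p, sr_p = collapse_covariates(sol_p, design.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(cgb[perm], cgb_p, atol=1e-7)
        np.testing.assert_allclose(sr[perm], sr_p, atol=1e-7)


def test_collapse_all_one_pair_per_response(tiny_cohort):
    responses = tiny_cohort.phenotypes[["BF1", "BF4"]]
    covs = collapse_all(responses, tiny_cohort.design)
    assert set(covs) == {"BF1", "BF4"}
    for frame in covs.values():
        assert list(frame.columns) == ["CGb", "Sr"]
        assert len(frame) == len(responses)
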