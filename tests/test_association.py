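import numpy as np
import pandas as pd
import pytest

from medipath.association import AssociationScan, adjust_pvalues, scan, variance_absorbed


def make_inputs(n, features, responses, seed=0):
    rng = np.random.default_rng(seed)
    covs = {
        name: pd.DataFrame({"CGb": rng.normal(size=n), "Sr": rng.normal(size=n)})
        for name in responses.columns
    }
    damline = rng.integers(1, 3, n).astype(float)
    return covs, damline


class TestScan:
    def test_exact_linear_response(self):
        n = 50
        rng = np.random.default_rng(1)
        f = rng.normal(size=n)
        responses = pd.DataFrame({"y": 2.0 * f})
        features = pd.DataFrame({"x": f})
        covs = {"y": pd.DataFrame({"CGb": np.zeros(n), "Sr": np.zeros(n)})}
        res = scan(responses, features, covs, np.ones(n))
        row = res.iloc[0]
        np.testing.assert_allclose(row["coef"], 2.0, atol=1e-10)
        assert row["p"] < 1e-30

    def test_matches_normal_equations_oracle(self):
        # n=30, single feature: coefficient and SE from the brute-force
        # (X'X)^-1 X'y solve with classical sigma^2 (X'X)^-1
        n = 30
        rng = np.random.default_rng(2)
        y = rng.normal(size=n)
        f = rng.normal(size=n)
        cgb, sr = rng.normal(size=n), rng.normal(size=n)
        damline = rng.integers(1, 3, n).astype(float)
        res = scan(
            pd.DataFrame({"y": y}), pd.DataFrame({"x": f}),
            {"y": pd.DataFrame({"CGb": cgb, "Sr": sr})}, damline,
        ).iloc[0]
        X = np.column_stack([np.ones(n), f, cgb, damline, sr])
        bhat = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ bhat
        sigma2 = resid @ resid / (n - 5)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(res["coef"], bhat[1], rtol=1e-10)
        np.testing.assert_allclose(res["se"], se[1], rtol=1e-10)
        np.testing.assert_allclose(res["b1"], bhat[2], rtol=1e-8)
        np.testing.assert_allclose(res["b2"], bhat[3], rtol=1e-8)
        np.testing.assert_allclose(res["b3"], bhat[4], rtol=1e-8)

    def test_null_type_one_error_calibrated(self):
        # 2000 independent features, null response: rejection fraction at
        # alpha=0.05 stays in [0.04, 0.06]
        n, m = 500, 2000
        rng = np.random.default_rng(3)
        responses = pd.DataFrame({"y": rng.normal(size=n)})
        features = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, m)).astype(float),
            columns=[f"x{j}" for j in range(m)],
        )
        covs, damline = make_inputs(n, features, responses, seed=4)
        res = scan(responses, features, covs, damline)
        rate = (res["p"] < 0.05).mean()
        assert 0.04 <= rate <= 0.06

    def test_monomorphic_feature_flagged_untestable(self):
        n = 40
        rng = np.random.default_rng(5)
        responses = pd.DataFrame({"y": rng.normal(size=n)})
        features = pd.DataFrame({"mono": np.zeros(n), "ok": rng.normal(size=n)})
        covs, damline = make_inputs(n, features, responses)
        res = scan(responses, features, covs, damline)
        assert res.set_index("feature").loc["mono", "untestable"]
        assert not res.set_index("feature").loc["ok", "untestable"]
        assert len(res) == 2  # flagged, not dropped

    def test_coef_invariant_to_covariate_scaling(self):
        n = 200
        rng = np.random.default_rng(6)
        responses = pd.DataFrame({"y": rng.normal(size=n)})
        features = pd.DataFrame({"x": rng.normal(size=n)})
        covs, damline = make_inputs(n, features, responses, seed=7)
        res1 = scan(responses, features, covs, damline)
        covs2 = {"y": covs["y"] * 3.5 + 1.2}
        res2 = scan(responses, features, covs2, damline)
        np.testing.assert_allclose(res1["coef"], res2["coef"], rtol=1e-10)
        np.testing.assert_allclose(res1["p"], res2["p"], rtol=1e-8)

    def test_mod3_same_engine_with_roles_swapped(self):
        # the G->M scan is the same code path with the CLR feature as the
        # response; assert numerically identical output
        n = 100
        rng = np.random.default_rng(8)
        clr_feature = pd.DataFrame({"m1": rng.normal(size=n)})
        dosage = pd.DataFrame({"g1": rng.binomial(2, 0.4, n).astype(float)})
        covs, damline = make_inputs(n, dosage, clr_feature, seed=9)
        as_mod3 = scan(clr_feature, dosage, covs, damline, model="mod3")
        as_plain = scan(clr_feature, dosage, covs, damline, model="mod1")
        pd.testing.assert_frame_equal(
            as_mod3.drop(columns="model"), as_plain.drop(columns="model")
        )


class TestAdjustment:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.01], "bonferroni"), [0.01])

    @pytest.mark.parametrize(
        "method,expected",
        [
            ("bonferroni", [0.03, 0.06, 0.09]),
            ("fdr_bh", [0.03, 0.03, 0.03]),
        ],
    )
    def test_hand_computed_adjustments(self, method, expected):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], method), expected
        )

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=50)
        for method in ("bonferroni", "fdr_bh"):
            assert (adjust_pvalues(p, method) >= p - 1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            adjust_pvalues([0.1, np.nan])

    def test_fdr_significant_bonferroni_not(self):
        # a feature can clear FDR while failing Bonferroni
        p = np.array([0.004, 0.005, 0.006] + [0.8] * 17)
        bonf = adjust_pvalues(p, "bonferroni")
        fdr = adjust_pvalues(p, "fdr_bh")
        assert ((fdr < 0.05) & (bonf >= 0.05)).any()


class TestVarianceAbsorbed:
    def test_zero_coefficient(self):
        assert variance_absorbed(0.0, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_standardized_feature_unit(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=1000)
        f = (f - f.mean()) / f.std()
        np.testing.assert_allclose(variance_absorbed(1.0, f), 1.0, atol=1e-12)

    def test_arithmetic(self):
        f = np.array([0.0, 1.0])  # population variance 0.25
        np.testing.assert_allclose(variance_absorbed(0.3, f * np.sqrt(2)), 0.045)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            variance_absorbed(1.0, np.array([]))


def test_estimator_wrapper_matches_function():
    n = 60
    rng = np.random.default_rng(12)
    y = pd.DataFrame({"y": rng.normal(size=n)})
    X = pd.DataFrame({"x": rng.normal(size=n)})
    covs, damline = make_inputs(n, X, y, seed=13)
    est = AssociationScan(model="mod2").fit(X, y, covariates=covs, damline=damline)
    pd.testing.assert_frame_equal(
        est.results_, scan(y, X, covs, damline, model="mod2")
    )
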