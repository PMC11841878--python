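import numpy as np
import pytest

from canopyhsm.maxent import (FeatureExpansion, FeatureSpec, FitConfig,
                              aic, aic_from_parts, bootstrap_fit, fit_maxent,
                              gain, penalized_objective)

LQ = FeatureSpec(classes=("linear", "quadratic"))


class TestFeatureExpansion:
    def test_linear_only_is_standardization(self, rng):
        X = rng.normal(5, 3, (200, 1))
        exp = FeatureExpansion(X, ["a"], FeatureSpec(classes=("linear",)))
        f = exp.transform(X)
        assert f.shape == (200, 1)
        np.testing.assert_allclose(f[:, 0], (X[:, 0] - X.mean()) / X.std())

    def test_three_covariates_three_products(self, rng):
        X = rng.normal(0, 1, (100, 3))
        exp = FeatureExpansion(X, list("abc"), FeatureSpec(classes=("product",)))
        assert exp.n_features == 3      # C(3, 2)
        assert exp.feature_names == ["prod(a,b)", "prod(a,c)", "prod(b,c)"]

    def test_forward_hinge_formula(self):
        # range [0, 1], knot at 0.5: forward hinge maps 0.75 -> 0.5
        X = np.linspace(0, 1, 101)[:, None]
        exp = FeatureExpansion(X, ["x"], FeatureSpec(classes=("hinge",),
                                                     hinge_knots=9))
        j = exp.feature_names.index("hingef(x,0.5)")
        val = exp.transform(np.array([[0.75]]))[0, j]
        assert val == pytest.approx(0.5)

    def test_zero_variance_covariate_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(0, 1, 50), np.full(50, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            exp = FeatureExpansion(X, ["a", "const"], FeatureSpec(classes=("linear",)))
        assert exp.names == ["a"]


class TestFit:
    def test_used_identical_to_available_gives_exact_zeros(self, rng):
        X = rng.normal(0, 1, (300, 2))
        m = fit_maxent(X, X, ["a", "b"], FitConfig(rm=2.0), LQ)
        assert (m.beta == 0).all()

    def test_gaussian_shift_matches_log_density_ratio(self):
        # used ~ N(1,1), available ~ N(0,1): log ratio is linear with unit
        # slope in x and no quadratic term
        rng = np.random.default_rng(11)
        avail = rng.normal(0, 1, (10_000, 1))
        used = rng.normal(1, 1, (10_000, 1))
        m = fit_maxent(used, avail, ["x"], FitConfig(rm=0.01), LQ)
        # coefficients on standardized scale; sd(avail) ~ 1
        assert m.beta[0] == pytest.approx(1.0, abs=0.1)
        assert m.beta[1] == pytest.approx(0.0, abs=0.1)

    def test_huge_rm_forces_null_model(self, rng):
        A = rng.normal(0, 1, (400, 2))
        U = A[:80] + 1.0
        m = fit_maxent(U, A, ["a", "b"], FitConfig(rm=1e6))
        assert (m.beta == 0).all()
        np.testing.assert_allclose(m.predict_logistic(A), 0.5)

    def test_objective_path_is_monotone(self, rng):
        A = rng.normal(0, 1, (500, 3))
        U = A[:100] + np.array([1.0, -0.5, 0.0])
        m = fit_maxent(U, A, list("abc"), FitConfig(rm=1.0))
        assert (np.diff(m.objective_path) >= -1e-12).all()

    def test_solver_matches_grid_search_oracle(self, rng):
        # <= 3 features, <= 200 points: nested dense grid search over beta
        A = rng.normal(0, 1, (200, 2))
        U = A[:50] + np.array([0.8, -0.6])
        spec = FeatureSpec(classes=("linear",))
        m = fit_maxent(U, A, ["a", "b"], FitConfig(rm=2.0), spec)
        f_u, f_a = m.expansion.transform(U), m.expansion.transform(A)
        lam = m.penalties
        center = np.zeros(2)
        width = 5.0
        best = -np.inf
        for _ in range(4):  # nested refinement to ~0.005 spacing
            g0 = np.linspace(center[0] - width, center[0] + width, 21)
            g1 = np.linspace(center[1] - width, center[1] + width, 21)
            vals = np.array([[penalized_objective(np.array([b0, b1]), f_u, f_a, lam)
                              for b1 in g1] for b0 in g0])
            i, j = np.unravel_index(vals.argmax(), vals.shape)
            best = vals[i, j]
            center = np.array([g0[i], g1[j]])
            width /= 10.0
        assert m.objective == pytest.approx(best, abs=1e-3)
        assert m.objective >= best - 1e-3

    def test_soft_threshold_keeps_weak_feature_at_zero(self):
        # single linear feature whose unpenalized gradient at 0 is below
        # lambda: coefficient must stay exactly 0
        rng = np.random.default_rng(5)
        A = rng.normal(0, 1, (1000, 1))
        U = A[:100]  # no shift: gradient ~ sampling noise
        m = fit_maxent(U + 0.01, A, ["x"], FitConfig(rm=100.0),
                       FeatureSpec(classes=("linear",)))
        f_u = m.expansion.transform(U + 0.01)
        f_a = m.expansion.transform(A)
        grad0 = abs(f_u.mean() - f_a.mean())
        assert grad0 < m.penalties[0]
        assert m.beta[0] == 0.0

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        A = rng.normal(0, 1, (500, 2))
        U = A[:100] + 2.0
        with pytest.raises(RuntimeError, match="did not converge"):
            fit_maxent(U, A, ["a", "b"], FitConfig(rm=0.1, max_iterations=1,
                                                   tolerance=1e-12))

    def test_too_few_used_points(self, rng):
        A = rng.normal(0, 1, (10, 1))
        with pytest.raises(ValueError):
            fit_maxent(A[:1], A, ["x"])


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(2)
    A = rng.normal(0, 1, (400, 2))
    U = A[:80] + np.array([1.0, 0.5])
    return U, A, fit_maxent(U, A, ["a", "b"], FitConfig(rm=1.0), LQ)


class TestPredict:
    def test_raw_sums_to_one_over_background(self, fitted):
        _, A, m = fitted
        assert m.predict_raw(A).sum() == pytest.approx(1.0)

    def test_entropy_nonnegative_and_null_identity(self, rng):
        A = rng.normal(0, 1, (256, 1))
        m = fit_maxent(A[:50], A, ["x"], FitConfig(rm=1e9))
        assert m.entropy == pytest.approx(np.log(256))
        np.testing.assert_allclose(m.predict_raw(A), 1 / 256)

    def test_logistic_in_unit_interval_and_rank_agreement(self, fitted, rng):
        _, A, m = fitted
        probe = rng.normal(0, 2, (100, 2))
        r = m.predict_raw(probe)
        h = m.predict_logistic(probe)
        assert (h >= 0).all() and (h <= 1).all()
        np.testing.assert_array_equal(np.argsort(r), np.argsort(h))


class TestGainAndAic:
    def test_null_model_gain_zero(self, rng):
        A = rng.normal(0, 1, (300, 1))
        m = fit_maxent(A[:60], A, ["x"], FitConfig(rm=1e9))
        assert gain(m, A[:60]) == pytest.approx(0.0, abs=1e-12)

    def test_gain_to_likelihood_ratio(self):
        assert np.exp(2.5) == pytest.approx(12.2, abs=0.02)

    def test_informative_feature_never_decreases_gain(self, rng):
        # nested models with near-zero penalty: more features, >= gain
        A = rng.normal(0, 1, (2000, 1))
        U = A[:400] + 1.0
        cfg = FitConfig(rm=1e-4)
        g_lin = gain(fit_maxent(U, A, ["x"], cfg, FeatureSpec(classes=("linear",))), U)
        g_lq = gain(fit_maxent(U, A, ["x"], cfg, LQ), U)
        assert g_lq >= g_lin - 1e-4

    def test_aic_arithmetic(self):
        assert aic_from_parts(0, 0.0) == 0.0
        assert aic_from_parts(2, -10.0) == 24.0

    def test_aic_uses_nonzero_count(self, rng):
        A = rng.normal(0, 1, (300, 2))
        U = A[:60] + np.array([1.0, 0.0])
        m = fit_maxent(U, A, ["a", "b"], FitConfig(rm=2.0), LQ)
        k = int(np.count_nonzero(m.beta))
        lnl = float(np.log(m.predict_raw(U)).sum())
        assert aic(m, U) == pytest.approx(2 * k - 2 * lnl)


class TestBootstrap:
    def test_replicate_count_and_determinism(self, rng):
        A = rng.normal(0, 1, (300, 1))
        U = A[:50] + 1.5
        cfg = FitConfig(rm=2.0, replicates=10, seed=3)
        r1 = bootstrap_fit(U, A, ["x"], cfg)
        r2 = bootstrap_fit(U, A, ["x"], cfg)
        assert len(r1.models) == 10 and len(r1.test_auc) == 10
        for a, b in zip(r1.train_indices, r2.train_indices):
            np.testing.assert_array_equal(a, b)

    def test_separable_scenario_high_test_auc(self, rng):
        # used points form their own well-separated mode and are a small
        # fraction of the background (the background contains them, so the
        # used share bounds the attainable AUC)
        A = np.vstack([rng.normal(0, 1, (1960, 1)), rng.normal(6, 1, (40, 1))])
        U = A[1960:]
        r = bootstrap_fit(U, A, ["x"], FitConfig(rm=2.0, replicates=10, seed=0), LQ)
        assert r.median_test_auc > 0.95

    def test_model_json_roundtrip_fields(self, tmp_path, rng):
        A = rng.normal(0, 1, (200, 1))
        m = fit_maxent(A[:40] + 1, A, ["x"], FitConfig(rm=2.0), LQ)
        m.to_json(tmp_path / "m.json")
        import json

        d = json.loads((tmp_path / "m.json").read_text())
        assert d["covariates"] == ["x"]
        np.testing.assert_allclose(d["beta"], m.beta)
        assert d["rm"] == 2.0
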