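"""Model parsing, implied covariance, ML estimation and standardization."""

import numpy as np
import pytest
from scipy import linalg, optimize

from screensem.sem import (
    FitResult,
    ModelError,
    ModelSpec,
    ParameterSet,
    count_free_parameters,
    expected_information,
    fit,
    implied_covariance,
    ml_discrepancy,
    model_df,
    param_names,
    parse_model,
    render_model,
    standardized_solution,
)
from screensem.study_models import available_keys, load_model

ONE_FACTOR = "F =~ a + b + c"


class TestParse:
    def test_single_latent(self):
        spec = parse_model("R =~ phn + phe + gr")
        assert spec.latents == (("R", ("phn", "phe", "gr")),)
        assert spec.observed == ("phn", "phe", "gr")
        # marker fixed, two free loadings
        assert sum(1 for k in param_names(spec) if k[0] == "loading") == 2

    def test_comments_and_blank_lines(self):
        spec = parse_model("# hello\n\ny ~ x  # trailing\n")
        assert spec.regressions == (("y", "x"),)

    def test_unknown_operator(self):
        with pytest.raises(ModelError, match="operator"):
            parse_model("a -> b")

    def test_duplicate_latent(self):
        with pytest.raises(ModelError, match="twice"):
            parse_model("F =~ a + b\nF =~ c + d")

    def test_single_indicator_latent(self):
        with pytest.raises(ModelError, match="indicator"):
            parse_model("F =~ a\ny ~ F\nz ~ F")

    def test_cycle_detected(self):
        with pytest.raises(ModelError, match="cycle"):
            parse_model("a ~ b\nb ~ c\nc ~ a")

    def test_catalog_round_trips(self):
        for key in available_keys():
            spec = load_model(key)
            assert parse_model(render_model(spec)) == spec


class TestCounting:
    def test_single_factor_hand_count(self):
        # 2 free loadings + 3 residual variances + 1 factor variance
        assert count_free_parameters(parse_model(ONE_FACTOR)) == 6

    def test_gastric_final_hand_enumeration(self):
        # 4 loadings + 4 paths + 3 residual covs + 11 variances + 1 exo cov
        spec = load_model("gastric_male_final")
        assert count_free_parameters(spec) == 23

    def test_count_equals_vector_length(self):
        for key in available_keys():
            spec = load_model(key)
            ps = ParameterSet()
            for k in param_names(spec):
                ps.set(k, 0.1)
            vec = ps.to_vector(spec)
            assert len(vec) == count_free_parameters(spec)
            back = ParameterSet.from_vector(spec, vec)
            assert back.to_vector(spec) == pytest.approx(vec)

    def test_saturated_df_zero(self):
        assert model_df(parse_model("y ~ x")) == 0

    def test_df_invariant_under_renaming(self):
        a = parse_model("F =~ a + b + c\ny ~ F")
        b = parse_model("G =~ p + q + r\nz ~ G")
        assert model_df(a) == model_df(b)

    def test_df_invariant_to_nonmarker_reordering(self):
        a = parse_model("F =~ a + b + c + d")
        b = parse_model("F =~ a + d + c + b")
        assert model_df(a) == model_df(b)


def one_factor_params():
    ps = ParameterSet()
    ps.loadings[("F", "b")] = 0.8
    ps.loadings[("F", "c")] = 0.6
    for v, val in (("a", 0.5), ("b", 0.5), ("c", 0.5), ("F", 1.0)):
        ps.variances[v] = val
    return ps


class TestImpliedCovariance:
    def test_zero_coefficients_give_diagonal(self):
        spec = parse_model(ONE_FACTOR)
        ps = one_factor_params()
        ps.loadings[("F", "b")] = 0.0
        ps.loadings[("F", "c")] = 0.0
        ps.variances["F"] = 0.0
        sigma = implied_covariance(spec, ps)
        np.testing.assert_allclose(sigma, np.diag([0.5, 0.5, 0.5]))

    def test_hand_algebra_one_factor(self):
        # lambda = (1, .8, .6), psi = 1, theta = .5:
        # cov(a,b) = 1*.8*1 = .8 ; var(a) = 1 + .5 = 1.5
        sigma = implied_covariance(parse_model(ONE_FACTOR), one_factor_params())
        assert sigma[0, 1] == pytest.approx(0.8)
        assert sigma[0, 0] == pytest.approx(1.5)
        assert sigma[1, 2] == pytest.approx(0.48)

    def test_matches_simulation_oracle(self):
        spec = parse_model(ONE_FACTOR)
        ps = one_factor_params()
        sigma = implied_covariance(spec, ps)
        rng = np.random.default_rng(77)
        f = rng.normal(size=1_000_000)
        lam = np.array([1.0, 0.8, 0.6])
        X = np.outer(f, lam) + rng.normal(size=(1_000_000, 3)) * np.sqrt(0.5)
        np.testing.assert_allclose(
            np.cov(X, rowvar=False), sigma, atol=6e-3
        )


class TestMlDiscrepancy:
    def test_zero_at_equality(self, rng):
        A = rng.normal(size=(5, 5))
        S = A @ A.T + 5 * np.eye(5)
        assert ml_discrepancy(S, S) == pytest.approx(0, abs=1e-12)

    def test_hand_value_1d(self):
        # p=1, S=2, Sigma=1: ln1 + 2 - ln2 - 1 = 1 - ln2
        assert ml_discrepancy([[2.0]], [[1.0]]) == pytest.approx(1 - np.log(2))

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            A = rng.normal(size=(4, 4))
            S = A @ A.T + 4 * np.eye(4)
            B = rng.normal(size=(4, 4))
            Sig = B @ B.T + 4 * np.eye(4)
            w = linalg.eigvalsh(S, Sig)  # generalized eigenvalues of (S, Sig)
            oracle = float(np.sum(w - np.log(w) - 1))
            assert ml_discrepancy(S, Sig) == pytest.approx(oracle, abs=1e-10)

    def test_non_pd_rejected(self):
        with pytest.raises(ModelError):
            ml_discrepancy([[1.0, 2.0], [2.0, 1.0]], np.eye(2))


def brute_force_fml(spec, S, n_starts=12):
    """Multi-start Nelder-Mead oracle minimizing the same discrepancy."""
    keys = param_names(spec)

    def objective(theta):
        try:
            ps = ParameterSet.from_vector(spec, theta)
            return ml_discrepancy(S, implied_covariance(spec, ps))
        except ModelError:
            return 1e6

    best = np.inf
    rng = np.random.default_rng(0)
    for i in range(n_starts):
        theta0 = rng.uniform(-1, 1, size=len(keys))
        theta0[[k[0] == "var" for k in keys]] = rng.uniform(0.3, 1.5)
        res = optimize.minimize(
            objective, theta0, method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-10, "fatol": 1e-12},
        )
        res = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-12, "fatol": 1e-14},
        )
        best = min(best, res.fun)
    return best


class TestFit:
    def test_saturated_recovers_sample_cov(self, rng):
        X = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]])
        spec = parse_model("y ~ x")
        res = fit(spec, X, names=["y", "x"])
        assert res.converged
        assert res.discrepancy == pytest.approx(0, abs=1e-6)
        np.testing.assert_allclose(res.implied_cov, res.sample_cov, atol=1e-6)

    def test_regression_slope_matches_least_squares(self, rng):
        x = rng.normal(size=300)
        y = 0.7 * x + 0.5 * rng.normal(size=300)
        res = fit(parse_model("y ~ x"), np.column_stack([y, x]), names=["y", "x"])
        slope = np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.estimates.paths[("y", "x")] == pytest.approx(slope, abs=1e-6)

    def test_matches_brute_force_oracle_one_factor(self, rng):
        spec = parse_model(ONE_FACTOR)
        sigma = implied_covariance(spec, one_factor_params())
        X = rng.multivariate_normal(np.zeros(3), sigma, size=150)
        res = fit(spec, X, names=["a", "b", "c"])
        oracle = brute_force_fml(spec, res.sample_cov)
        assert res.converged
        assert res.discrepancy == pytest.approx(oracle, abs=1e-6)

    def test_matches_brute_force_oracle_factor_plus_outcome(self, rng):
        spec = parse_model("F =~ a + b + c\ny ~ F")
        truth = one_factor_params()
        truth.paths[("y", "F")] = 0.5
        truth.variances["y"] = 0.6
        sigma = implied_covariance(spec, truth)
        X = rng.multivariate_normal(np.zeros(4), sigma, size=200)
        res = fit(spec, X, names=["a", "b", "c", "y"])
        oracle = brute_force_fml(spec, res.sample_cov)
        assert res.discrepancy == pytest.approx(oracle, abs=1e-6)

    def test_scale_equivariance(self, rng):
        spec = load_model("gastric_male_final")
        from screensem.synthetic import default_config

        truth = default_config("gastric", "male").true_params
        sigma = implied_covariance(spec, truth, marker_fixed=False)
        X = rng.multivariate_normal(np.zeros(len(spec.observed)), sigma, size=300)
        res1 = fit(spec, X, names=list(spec.observed))
        X2 = X.copy()
        X2[:, 3] *= 7.0  # rescale one observed variable
        res2 = fit(spec, X2, names=list(spec.observed))
        assert res2.discrepancy == pytest.approx(res1.discrepancy, abs=1e-8)
        assert res2.df == res1.df
        for key in param_names(spec):
            if key[0] in ("loading", "path"):
                assert res2.standardized.get(key) == pytest.approx(
                    res1.standardized.get(key), abs=1e-6
                )

    def test_gradient_zero_at_optimum(self, rng):
        from screensem.sem import _discrepancy_and_grad, _start_values

        spec = parse_model(ONE_FACTOR)
        sigma = implied_covariance(spec, one_factor_params())
        X = rng.multivariate_normal(np.zeros(3), sigma, size=120)
        res = fit(spec, X, names=["a", "b", "c"])
        keys = param_names(spec)
        th0 = _start_values(spec, res.sample_cov).to_vector(spec)
        _, g = _discrepancy_and_grad(
            res.estimates.to_vector(spec), spec, res.sample_cov, keys, th0
        )
        assert np.max(np.abs(g)) < 1e-6

    def test_missing_data_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, 1.0], [0.5, 0.3]])
        with pytest.raises(ModelError, match="missing"):
            fit(parse_model("y ~ x"), X, names=["y", "x"])

    def test_negative_df_rejected(self):
        spec = ModelSpec(
            observed=("a", "b"),
            regressions=(("a", "b"), ("b", "a"))[:1],
            residual_covariances=(("a", "b"),),
        )
        with pytest.raises(ModelError, match="degrees of freedom"):
            fit(spec, np.random.default_rng(0).normal(size=(50, 2)),
                names=["a", "b"])


class TestStandardErrors:
    def test_information_matches_finite_difference_hessian(self, rng):
        spec = parse_model(ONE_FACTOR)
        sigma = implied_covariance(spec, one_factor_params())
        X = rng.multivariate_normal(np.zeros(3), sigma, size=500)
        res = fit(spec, X, names=["a", "b", "c"])
        keys = param_names(spec)
        theta = res.estimates.to_vector(spec)
        n = res.n

        def nF_half(th):
            ps = ParameterSet.from_vector(spec, th)
            return n * ml_discrepancy(
                res.sample_cov, implied_covariance(spec, ps)
            ) / 2.0

        q = len(keys)
        H = np.zeros((q, q))
        h = 1e-4
        for i in range(q):
            for j in range(q):
                e_i = np.zeros(q); e_i[i] = h
                e_j = np.zeros(q); e_j[j] = h
                H[i, j] = (
                    nF_half(theta + e_i + e_j) - nF_half(theta + e_i - e_j)
                    - nF_half(theta - e_i + e_j) + nF_half(theta - e_i - e_j)
                ) / (4 * h * h)
        info = expected_information(spec, res.estimates, n)
        # expected vs observed information agree at the (near-perfect) optimum
        np.testing.assert_allclose(info, H, rtol=2e-2, atol=2e-2)

    def test_empirical_sd_matches_reported_se(self):
        spec = parse_model(ONE_FACTOR)
        truth = one_factor_params()
        sigma = implied_covariance(spec, truth)
        L = linalg.cholesky(sigma, lower=True)
        ests, ses = [], []
        key = ("loading", "F", "b")
        for rep in range(150):
            rng = np.random.default_rng(1000 + rep)
            X = rng.standard_normal((400, 3)) @ L.T
            res = fit(spec, X, names=["a", "b", "c"])
            if res.converged:
                ests.append(res.estimates.get(key))
                ses.append(res.standard_errors[key])
        ests, ses = np.array(ests), np.array(ses)
        assert abs(ests.std(ddof=1) - ses.mean()) / ses.mean() < 0.15

    def test_null_path_p_value_uniform(self):
        # p-values of a true-zero regression coefficient are U(0,1)
        spec = parse_model("y ~ x")
        pvals = []
        for rep in range(500):
            rng = np.random.default_rng(2000 + rep)
            X = rng.normal(size=(100, 2))
            res = fit(spec, X, names=["y", "x"])
            pvals.append(res.p_values[("path", "y", "x")])
        pvals = np.sort(pvals)
        ks = np.max(np.abs(pvals - np.arange(1, 501) / 500))
        assert ks < 0.1


class TestStandardizedSolution:
    def test_equals_unstandardized_on_standardized_saturated_data(self, rng):
        x = rng.normal(size=400)
        y = 0.6 * x + 0.8 * rng.normal(size=400)
        from screensem.preprocess import standardize

        X = np.column_stack([standardize(y), standardize(x)])
        res = fit(parse_model("y ~ x"), X, names=["y", "x"])
        key = ("path", "y", "x")
        assert res.standardized.get(key) == pytest.approx(
            res.estimates.get(key), abs=1e-6
        )

    def test_variance_decomposition_identity(self, rng):
        spec = parse_model(ONE_FACTOR)
        sigma = implied_covariance(spec, one_factor_params())
        X = rng.multivariate_normal(np.zeros(3), sigma, size=300)
        res = fit(spec, X, names=["a", "b", "c"])
        std = standardized_solution(res)
        for ind in ("a", "b", "c"):
            lam = std.loadings[("F", ind)]
            assert lam**2 + std.variances[ind] == pytest.approx(1.0, abs=1e-8)

    def test_marker_standardized_loading_not_one(self, rng):
        spec = parse_model(ONE_FACTOR)
        sigma = implied_covariance(spec, one_factor_params())
        X = rng.multivariate_normal(np.zeros(3), sigma, size=300)
        res = fit(spec, X, names=["a", "b", "c"])
        assert res.standardized.loadings[("F", "a")] != pytest.approx(1.0, abs=0.01)
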