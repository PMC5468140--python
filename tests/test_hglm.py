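import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import pellethglm as ph
from pellethglm.frames import ModelSpec, Term, build_model_frame
from pellethglm.hglm import CARParams, HGLMFit, term_pvalue

from conftest import edgeless_units, lattice_units, newton_logistic


def two_node_graph():
    return np.array([[0.0, 1.0], [1.0, 0.0]])


class TestRhoRange:
    def test_two_node_single_edge(self):
        lo, hi = ph.rho_valid_range(two_node_graph())
        assert (lo, hi) == pytest.approx((-1.0, 1.0))

    def test_edgeless_unconstrained(self):
        assert ph.rho_valid_range(np.zeros((3, 3))) == (-np.inf, np.inf)

    def test_three_cycle(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
        lo, hi = ph.rho_valid_range(D)
        # cycle-graph spectrum {2, -1, -1}
        assert (lo, hi) == pytest.approx((-1.0, 0.5))

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError, match="symmetric"):
            ph.rho_valid_range(np.array([[0, 1], [0, 0.0]]))


class TestCarCovariance:
    def test_rho_zero_is_scaled_identity(self):
        S = ph.car_covariance(CARParams(tau=2.5, rho=0.0), two_node_graph())
        assert np.allclose(S, 2.5 * np.eye(2))

    def test_two_node_closed_form(self):
        S = ph.car_covariance(CARParams(tau=2.0, rho=0.5), two_node_graph())
        assert np.allclose(S, [[8 / 3, 4 / 3], [4 / 3, 8 / 3]], atol=1e-12)

    def test_rho_outside_range_raises(self):
        with pytest.raises(ValueError, match="positive-definite"):
            ph.car_covariance(CARParams(tau=1.0, rho=1.5), two_node_graph())

    def test_matches_dense_precision_inverse_up_to_50_nodes(self):
        rng = np.random.default_rng(0)
        for n in (10, 30, 50):
            units = pd.DataFrame({
                "plot_id": [f"p{i}" for i in range(n)],
                "x": rng.uniform(0, 1500, n), "y": rng.uniform(0, 1500, n),
                "year": 2010,
            })
            adj = ph.build_adjacency(units)
            lo, hi = ph.rho_valid_range(adj)
            rho = 0.5 * hi if np.isfinite(hi) else 0.1
            params = CARParams(tau=1.7, rho=rho)
            S = ph.car_covariance(params, adj)
            dense_prec = (np.eye(n) - rho * adj.matrix.toarray()) / 1.7
            assert np.allclose(S, np.linalg.inv(dense_prec), atol=1e-8)
            assert np.allclose(S, S.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(S) > 0)


class TestGLMLimit:
    def test_edgeless_tau_zero_matches_logistic_oracle(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.standard_normal(n)
        y = rng.binomial(1, expit(-0.4 + 0.9 * x)).astype(float)
        units = edgeless_units(n)
        adj = ph.build_adjacency(units)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        fit = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec), adj,
                                           fix_tau=1e-8)
        oracle = newton_logistic(np.column_stack([np.ones(n), x]), y)
        assert np.allclose(fit.beta.to_numpy(), oracle, atol=1e-4)

    def test_degenerate_response_raises(self):
        units = edgeless_units(20)
        df = units.assign(cov=np.arange(20.0), presence=0.0)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        with pytest.raises(ValueError, match="degenerate"):
            ph.fit_spatial_binomial_hglm(build_model_frame(df, spec),
                                         ph.build_adjacency(units))


def _dense_iid_fit(X, y, xatol=1e-8):
    """Independently coded iid-random-intercept logistic fit (dense algebra).

    Same estimation principle as the package fitter at rho = 0 -- joint
    Newton for (beta, u), restricted likelihood of the linearized model for
    tau -- but written against dense matrices with its own scalar search.
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    T = np.hstack([X, np.eye(n)])
    state = {"coef": np.zeros(p + n)}

    def newton(tau):
        coef = state["coef"].copy()
        for _ in range(100):
            eta = T @ coef
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            A = (T * w[:, None]).T @ T
            A[p:, p:] += np.eye(n) / tau
            grad = T.T @ (y - mu)
            grad[p:] -= coef[p:] / tau
            step = np.linalg.solve(A, grad)
            coef = coef + step
            if np.max(np.abs(step)) < 1e-10:
                break
        state["coef"] = coef
        eta = T @ coef
        mu = expit(eta)
        return coef, A, mu

    def objective(log_tau):
        tau = float(np.exp(log_tau))
        coef, A, mu = newton(tau)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        rss = float(np.sum((y - mu) ** 2 / w) + coef[p:] @ coef[p:] / tau)
        sign, logdetA = np.linalg.slogdet(A)
        logdetP = -n * np.log(tau)
        return 0.5 * (logdetA - logdetP + rss)

    res = minimize_scalar(objective, bounds=(-6, 4), method="bounded",
                          options={"xatol": xatol})
    tau = float(np.exp(res.x))
    coef, _, _ = newton(tau)
    return coef[:p], tau


class TestIidLimit:
    def test_rho_zero_matches_independent_iid_fitter(self):
        rng = np.random.default_rng(9)
        n = 150
        x = rng.standard_normal(n)
        u = 0.8 * rng.standard_normal(n)
        y = rng.binomial(1, expit(-0.5 + 0.7 * x + u)).astype(float)
        units = edgeless_units(n)
        adj = ph.build_adjacency(units)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec), adj,
                                               fix_rho=0.0)
        beta_iid, tau_iid = _dense_iid_fit(np.column_stack([np.ones(n), x]), y)
        assert np.allclose(fit.beta.to_numpy(), beta_iid, atol=1e-3)
        assert fit.tau == pytest.approx(tau_iid, rel=2e-2)


@pytest.fixture(scope="module")
def lattice_fit():
    units = lattice_units(20)
    adj = ph.build_adjacency(units)
    rng = np.random.default_rng(2)
    n = len(units)
    x = rng.standard_normal(n)
    u = ph.sample_car_effects(CARParams(1.0, 0.1), adj, seed=rng)
    y = rng.binomial(1, expit(-0.8 + 0.6 * x + u)).astype(float)
    df = units.assign(cov=x, presence=y)
    spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ph.fit_spatial_binomial_hglm(build_model_frame(df, spec), adj)


class TestFitInternals:

    def test_probabilities_strictly_inside_unit_interval(self, lattice_fit):
        assert np.all(lattice_fit.mu > 0) and np.all(lattice_fit.mu < 1)

    def test_linear_predictor_is_logit_of_probabilities(self, lattice_fit):
        assert np.allclose(logit(lattice_fit.mu), lattice_fit.eta, atol=1e-10)

    def test_rho_within_valid_range(self, lattice_fit):
        assert lattice_fit.phi > 0
        assert lattice_fit.tau > 0

    def test_deterministic_given_inputs(self):
        units = lattice_units(12)
        adj = ph.build_adjacency(units)
        rng = np.random.default_rng(3)
        n = len(units)
        x = rng.standard_normal(n)
        y = rng.binomial(1, expit(-0.5 + x)).astype(float)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f1 = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec), adj)
            f2 = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec), adj)
        assert f1.beta.equals(f2.beta)
        assert f1.tau == f2.tau and f1.rho == f2.rho and f1.phi == f2.phi

    def test_separation_warns(self):
        n = 60
        units = edgeless_units(n)
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(float)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        with pytest.warns(RuntimeWarning, match="separation"):
            ph.fit_spatial_binomial_hglm(build_model_frame(df, spec),
                                         ph.build_adjacency(units), fix_tau=1e-8)


class TestDispersion:
    def test_phi_near_one_on_well_specified_binary_data(self):
        rng = np.random.default_rng(6)
        n = 5000
        x = rng.standard_normal(n)
        y = rng.binomial(1, expit(-1.0 + 0.8 * x)).astype(float)
        units = edgeless_units(n)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        fit = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec),
                                           ph.build_adjacency(units), fix_tau=1e-8)
        assert fit.phi == pytest.approx(1.0, abs=0.1)

    def test_underdispersion_detected_for_sub_binomial_variance(self):
        # quasi-binomial responses in [0,1] with variance p(1-p)/2: Beta(p, 1-p)
        rng = np.random.default_rng(7)
        n = 3000
        x = rng.standard_normal(n)
        p = expit(-0.3 + 0.6 * x)
        y = rng.beta(p, 1.0 - p)
        units = edgeless_units(n)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        fit = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec),
                                           ph.build_adjacency(units), fix_tau=1e-8)
        assert fit.phi < 1.0
        assert fit.phi == pytest.approx(0.5, abs=0.1)

    def test_deviance_estimator_below_one_for_rare_presence(self):
        # with rare binary outcomes the mean deviance sits well below 1,
        # matching the published dispersion estimates of 0.16-0.33
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.standard_normal(n)
        y = rng.binomial(1, expit(-3.0 + 0.5 * x)).astype(float)
        units = edgeless_units(n)
        df = units.assign(cov=x, presence=y)
        spec = ModelSpec((Term("intercept", "intercept", forced=True), Term("cov")))
        fit = ph.fit_spatial_binomial_hglm(build_model_frame(df, spec),
                                           ph.build_adjacency(units),
                                           fix_tau=1e-8, dispersion="deviance")
        assert fit.phi < 0.6


class TestWaldAndOdds:
    def _fake_fit(self, beta, se):
        names = list(beta)
        return HGLMFit(
            beta=pd.Series(beta), se_beta=pd.Series(se),
            cov_beta=np.diag(np.array(list(se.values())) ** 2),
            u=np.zeros(1), tau=1.0, rho=0.0, phi=1.0, converged=True,
            n_iter=1, n_obs=10,
            term_columns={k: [i] for i, k in enumerate(names)})

    def test_zero_estimate_gives_p_one(self):
        fit = self._fake_fit({"a": 0.0}, {"a": 1.0})
        est, se, z, p = ph.wald_test(fit, "a")
        assert p == pytest.approx(1.0)

    def test_1_96_gives_p_005(self):
        fit = self._fake_fit({"a": 1.96}, {"a": 1.0})
        assert ph.wald_test(fit, "a")[3] == pytest.approx(0.05, abs=1e-3)

    def test_unknown_term_raises(self):
        fit = self._fake_fit({"a": 1.0}, {"a": 1.0})
        with pytest.raises(KeyError):
            ph.wald_test(fit, "nope")
        with pytest.raises(KeyError):
            term_pvalue(fit, "nope")

    def test_term_pvalue_methods(self):
        fit = self._fake_fit({"a": 2.0, "b": 0.5}, {"a": 1.0, "b": 1.0})
        fit.term_columns = {"f": [0, 1]}
        p_max = term_pvalue(fit, "f", method="max")
        p_joint = term_pvalue(fit, "f", method="joint")
        assert p_max == pytest.approx(ph.wald_test(fit, "b")[3])
        assert 0 < p_joint < 1
        with pytest.raises(ValueError):
            term_pvalue(fit, "f", method="something")

    @pytest.mark.parametrize("b,expected", [(0.0, 0), (0.09, 9), (np.log(2), 50)])
    def test_odds_change_examples(self, b, expected):
        assert ph.odds_change_per_unit(b) == expected

    def test_odds_change_conventions(self):
        assert ph.odds_change_per_unit(0.09, "exp", rounded=False) == \
            pytest.approx(100 * (np.exp(0.09) - 1))
        assert ph.odds_change_per_unit(0.09, "linear") == 9
        with pytest.raises(ValueError):
            ph.odds_change_per_unit(np.nan)
        with pytest.raises(ValueError):
            ph.odds_change_per_unit(0.1, "log")
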