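import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from rtcondep import (Dataset, ItemParams, ModelSpec, bvn_conditional_prob,
                      icc_probability, minus2_loglik, modified_bic)
from rtcondep.models import cd_param_count, log_psi, n_params, psi
from rtcondep.simulate import GeneratingSpec, simulate_dataset


class TestPsi:
    @given(st.floats(-50, 50))
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, a):
        assert psi(a, 1) + psi(a, 0) == pytest.approx(1.0, abs=1e-12)

    def test_log_psi_matches_psi(self):
        # psi computes 1 - Phi by subtraction, so only ~1e-7 relative
        # agreement is expected in the far tail
        a = np.linspace(-6, 6, 25)
        np.testing.assert_allclose(np.exp(log_psi(a, 1)), psi(a, 1), rtol=1e-6)
        np.testing.assert_allclose(np.exp(log_psi(a, 0)), psi(a, 0), rtol=1e-6)


class TestIccProbability:
    @pytest.mark.parametrize("kind", ["ci", "linear", "quadratic", "multicat"])
    def test_phi_zero_is_half(self, kind):
        model = ModelSpec(kind=kind)
        item = ItemParams(alpha0=1.3, beta0=0.0)
        assert icc_probability(model, item, 0.0, 0.0) == pytest.approx(0.5)

    def test_quadratic_nests_linear_on_grid(self):
        lin, quad = ModelSpec(kind="linear"), ModelSpec(kind="quadratic")
        item = ItemParams(alpha0=0.9, alpha1=0.25, beta0=-0.4, beta1=0.6)
        thetas = np.linspace(-3, 3, 20)
        zs = np.linspace(-3, 3, 20)
        for th in thetas:
            pl = icc_probability(lin, item, np.full(20, th), zs)
            pq = icc_probability(quad, item, np.full(20, th), zs)
            np.testing.assert_allclose(pl, pq, atol=1e-12)

    def test_linear_nests_ci(self):
        ci, lin = ModelSpec(kind="ci"), ModelSpec(kind="linear")
        item = ItemParams(alpha0=1.2, beta0=0.3)
        z = np.linspace(-2, 2, 9)
        pl = icc_probability(lin, item, np.zeros(9) + 0.7, z)
        pc = icc_probability(ci, item, np.zeros(9) + 0.7, z)
        np.testing.assert_allclose(pl, pc, atol=1e-12)

    def test_quadratic_peak_by_grid_search(self):
        # with beta2 < 0 the intercept-driven probability over z peaks at
        # -beta1 / (2 beta2); locate it by brute grid search at step 0.001
        model = ModelSpec(kind="quadratic")
        item = ItemParams(alpha0=1.0, beta0=0.2, beta1=0.5, beta2=-0.4)
        zs = np.arange(-3, 3, 0.001)
        p = icc_probability(model, item, np.zeros_like(zs), zs)
        z_star = zs[np.argmax(p)]
        assert z_star == pytest.approx(-0.5 / (2 * -0.4), abs=0.002)

    def test_multicat_categories(self):
        model = ModelSpec(kind="multicat", thresholds=(-1.5, -0.5, 0.5, 1.5),
                          baseline=2)
        cats = model.categories(np.array([-2.0, -1.5, -1.0, 0.0, 0.5, 3.0]))
        np.testing.assert_array_equal(cats, [0, 1, 1, 2, 3, 4])

    def test_multicat_contrasts_shift_probability(self):
        model = ModelSpec(kind="multicat")
        beta_cat = np.array([-0.5, -0.2, 0.0, -0.2, -0.5])
        item = ItemParams(alpha0=1.0, beta0=0.0, beta_cat=beta_cat,
                          alpha_cat=np.zeros(5))
        p_base = icc_probability(model, item, 0.0, 0.0)
        p_fast = icc_probability(model, item, 0.0, -2.0)
        assert p_base == pytest.approx(0.5)
        assert p_fast == pytest.approx(ndtr(-0.5))


class TestBvnConditionalProb:
    def test_rho_zero_equals_ci(self):
        item = ItemParams(alpha0=1.1, beta0=-0.2, xi=0.8, sigma=0.5)
        for t in (0.5, 1.0, 3.0):
            p1 = bvn_conditional_prob(0.4, 0.1, 1.1, -0.2, 0.8, 0.5, 0.0, t)
            p2 = icc_probability(ModelSpec(kind="ci"), item, 0.4, 0.0)
            assert p1 == pytest.approx(p2, abs=1e-15)

    def test_equivalence_with_rescaled_linear_model(self):
        # conditioning the bivariate normal on t gives the linear model with
        # coefficients scaled by 1/sqrt(1 - rho^2)
        rho, alpha, beta, xi, sigma = 0.3, 1.0, 0.0, 1.0, 0.5
        r = 1.0 / math.sqrt(1 - rho ** 2)
        item = ItemParams(alpha0=alpha * r, beta0=beta * r, beta1=rho * r)
        lin = ModelSpec(kind="linear")
        t = math.e
        z = (math.log(t) - xi + 0.0) / sigma
        p1 = bvn_conditional_prob(0.0, 0.0, alpha, beta, xi, sigma, rho, t)
        p2 = icc_probability(lin, item, 0.0, z)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="rho"):
            bvn_conditional_prob(0, 0, 1, 0, 0, 1, 1.0, 1.0)

    def test_against_quadrature_of_joint_density(self):
        # integrate the joint (x*, t) density over {x* > 0} x small
        # t-interval and compare with conditional prob x marginal x width
        theta, tau = 0.3, -0.2
        alpha, beta, xi, sigma, rho = 0.8, 0.1, 0.5, 0.6, 0.4
        t0, dt = 1.7, 1e-4
        mean = np.array([alpha * theta + beta, xi - tau])
        cov = np.array([[1.0, rho * sigma], [rho * sigma, sigma ** 2]])
        mvn = multivariate_normal(mean=mean, cov=cov)
        xs = np.linspace(0, 12, 2001)
        ts = np.linspace(t0, t0 + dt, 5)
        xx, tt = np.meshgrid(xs, ts, indexing="ij")
        dens = mvn.pdf(np.stack([xx, np.log(tt)], axis=-1)) / tt
        inner = np.trapezoid(dens, xs, axis=0)
        integral = np.trapezoid(inner, ts)
        z = (math.log(t0 + dt / 2) - xi + tau) / sigma
        marg = math.exp(-0.5 * z * z) / ((t0 + dt / 2) * sigma
                                         * math.sqrt(2 * math.pi))
        cond = bvn_conditional_prob(theta, tau, alpha, beta, xi, sigma, rho,
                                    t0 + dt / 2)
        assert integral == pytest.approx(cond * marg * dt, rel=1e-6)


def _tiny_dataset(kind="linear", n=1, k=1, seed=31):
    spec = GeneratingSpec(model=ModelSpec(kind=kind), n_persons=max(n, 10),
                          n_items=max(k, 3))
    ds, truth = simulate_dataset(spec, seed)
    ds = Dataset(X=ds.X[:n, :k], T=ds.T[:n, :k])
    return ds, truth


class TestMinus2Loglik:
    def test_single_cell_against_trapezoid(self):
        ds, _ = _tiny_dataset(n=1, k=1)
        model = ModelSpec(kind="linear")
        items = [ItemParams(alpha0=1.0, alpha1=0.2, beta0=-0.3, beta1=0.4,
                            xi=0.5, sigma=0.5)]
        Sigma_P = np.array([[1.0, 0.2], [0.2, 0.3]])
        m2 = minus2_loglik(ds, model, items, Sigma_P, n_quad=31)

        # brute force on a [-8, 8]^2 grid
        g = np.arange(-8, 8.0001, 0.01)
        th, ta = np.meshgrid(g, g, indexing="ij")
        x, t = int(ds.X[0, 0]), float(ds.T[0, 0])
        z = (math.log(t) - items[0].xi + ta) / items[0].sigma
        pred = (items[0].alpha0 + items[0].alpha1 * z) * th \
            + items[0].beta0 + items[0].beta1 * z
        p_acc = ndtr(np.clip(pred, -8, 8))
        acc = p_acc if x == 1 else 1 - p_acc
        f_t = np.exp(-0.5 * ((math.log(t) - items[0].xi + ta)
                             / items[0].sigma) ** 2) \
            / (t * items[0].sigma * math.sqrt(2 * math.pi))
        prior = multivariate_normal(mean=[0, 0], cov=Sigma_P).pdf(
            np.stack([th, ta], axis=-1))
        lik = np.trapezoid(np.trapezoid(acc * f_t * prior, g, axis=1), g)
        assert m2 == pytest.approx(-2 * math.log(lik), rel=1e-6)

    def test_quadratic_with_zero_effects_equals_linear(self):
        ds, _ = _tiny_dataset(n=25, k=3, seed=32)
        lin_items = [ItemParams(alpha0=1.0, alpha1=0.1, beta0=0.2, beta1=-0.3,
                                xi=0.5, sigma=0.5) for _ in range(3)]
        Sigma_P = np.array([[1.0, 0.1], [0.1, 0.25]])
        m_lin = minus2_loglik(ds, ModelSpec(kind="linear"), lin_items, Sigma_P)
        m_quad = minus2_loglik(ds, ModelSpec(kind="quadratic"), lin_items,
                               Sigma_P)
        assert m_lin == pytest.approx(m_quad, rel=1e-12)

    def test_uninformative_item_decomposition(self):
        # an added item with alpha0=beta0=0 contributes exactly ln(1/2) per
        # response on the accuracy side; a huge sigma makes its time term
        # essentially constant over tau so the integral factorizes
        ds, _ = _tiny_dataset(n=30, k=2, seed=33)
        model = ModelSpec(kind="ci")
        items = [ItemParams(alpha0=1.0, beta0=0.1, xi=0.4, sigma=0.5),
                 ItemParams(alpha0=0.8, beta0=-0.2, xi=0.6, sigma=0.4)]
        Sigma_P = np.array([[1.0, 0.15], [0.15, 0.25]])
        base = minus2_loglik(ds, model, items, Sigma_P)

        big_sigma = 1000.0
        extra = ItemParams(alpha0=0.0, beta0=0.0, xi=0.0, sigma=big_sigma)
        ds3 = Dataset(X=np.column_stack([ds.X, np.ones(30, dtype=int)]),
                      T=np.column_stack([ds.T, np.ones(30)]))
        m3 = minus2_loglik(ds3, model, items + [extra], Sigma_P)
        lt = 0.0  # ln t = 0 for the added unit times
        f_t = -lt - math.log(big_sigma) - 0.5 * math.log(2 * math.pi) \
            - 0.5 * (lt / big_sigma) ** 2
        expected = base - 2 * 30 * math.log(0.5) - 2 * 30 * f_t
        assert m3 == pytest.approx(expected, rel=1e-6)


class TestModifiedBic:
    def test_ln_e_case(self):
        assert modified_bic(100.0, 10, math.e) == pytest.approx(110.0)

    def test_incremental_parameter_counts(self):
        k = 38
        ci = cd_param_count(ModelSpec(kind="ci"), k)
        lin = cd_param_count(ModelSpec(kind="linear"), k)
        quad = cd_param_count(ModelSpec(kind="quadratic"), k)
        mc = cd_param_count(ModelSpec(kind="multicat"), k)
        assert (lin - ci, quad - ci, mc - ci) == (76, 152, 304)

    def test_full_count_increments(self):
        k = 20
        full_ci = n_params(ModelSpec(kind="ci"), k, include_hyper=False)
        full_lin = n_params(ModelSpec(kind="linear"), k, include_hyper=False)
        assert full_lin - full_ci == 2 * k

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            modified_bic(1.0, 0, 10)
        with pytest.raises(ValueError):
            modified_bic(1.0, 3, 1)

    def test_ml_nesting_at_desk_scale(self):
        # a quadratic fit started from the linear ML solution can only
        # improve the likelihood (direct optimization, no MCMC)
        from scipy.optimize import minimize

        spec = GeneratingSpec(
            model=ModelSpec(kind="linear"), n_persons=120, n_items=3,
            mu_I=np.array([1.0, 0.0, 0.0, 0.3, 0.5]),
            Sigma_I=np.diag([0.04, 0.04, 0.09, 0.04, 0.04]))
        ds, truth = simulate_dataset(spec, 34)  # 120 persons keep the oracle cheap
        xi = np.array(truth["xi"])
        sig = np.array(truth["sigma"])
        Sigma_P = np.array(truth["Sigma_P"])

        def make_items(kind, vec):
            model = ModelSpec(kind=kind)
            d = model.n_acc_params
            return model, [ItemParams.from_acc_vector(
                model, vec[i * d:(i + 1) * d], xi=xi[i], sigma=sig[i])
                for i in range(3)]

        def obj(kind):
            def f(vec):
                model, items = make_items(kind, vec)
                return minus2_loglik(ds, model, items, Sigma_P, n_quad=11)
            return f

        x0 = np.tile([1.0, 0.0, 0.0, 0.0], 3)
        res_lin = minimize(obj("linear"), x0, method="Nelder-Mead",
                           options={"maxiter": 600, "xatol": 1e-3,
                                    "fatol": 1e-6})
        # embed the linear solution as a quadratic start with zero effects
        x_quad = []
        for i in range(3):
            a0, a1, b0, b1 = res_lin.x[i * 4:(i + 1) * 4]
            x_quad += [a0, a1, 0.0, b0, b1, 0.0]
        res_quad = minimize(obj("quadratic"), np.array(x_quad),
                            method="Nelder-Mead",
                            options={"maxiter": 400, "xatol": 1e-3,
                                     "fatol": 1e-6})
        assert res_quad.fun <= res_lin.fun + 1e-6
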