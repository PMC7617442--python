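import numpy as np
import pytest

import sesindex as si
from conftest import make_toy_dataset
from sesindex.model_core import pointwise_loglik


def _state(spec, n_areas, **kw):
    p = spec.p
    st = si.ParameterState(
        alpha=kw.get("alpha", np.zeros((n_areas, p))),
        alpha_star=kw.get("alpha_star", np.zeros(p)),
        beta=kw.get("beta", np.ones(p)),
        theta=kw.get("theta", np.zeros(n_areas)),
        sigma=kw.get("sigma", np.ones(p)),
        iota=kw.get("iota", np.nan))
    return st


class TestLoglikObservation:
    def test_probit_at_zero_is_half(self):
        spec = si.ModelSpec(variant="M0", is_dichotomous=(True,))
        st = _state(spec, 1, beta=np.zeros(1))
        assert si.loglik_observation(st, spec, 0, 0, 1.0) == pytest.approx(
            np.log(0.5), abs=1e-12)

    def test_continuous_density_at_mean(self):
        spec = si.ModelSpec(variant="M0", is_dichotomous=(False,))
        st = _state(spec, 1, beta=np.array([0.7]), theta=np.array([1.3]),
                    sigma=np.array([2.0]))
        y = 0.7 * 1.3
        assert si.loglik_observation(st, spec, 0, 0, y) == pytest.approx(
            -np.log(2.0 * np.sqrt(2 * np.pi)), abs=1e-12)

    def test_probit_against_quadrature(self):
        # success log-probability log Phi(1.5) for alpha=1.2, beta*theta=0.3
        spec = si.ModelSpec(variant="HS", is_dichotomous=(True,))
        st = _state(spec, 1, alpha=np.array([[1.2]]), beta=np.array([0.3]),
                    theta=np.array([1.0]), iota=0.5)
        # trapezoid quadrature of the standard normal density below 1.5
        g = np.linspace(-12.0, 1.5, 400_001)
        phi = np.trapezoid(np.exp(-g**2 / 2) / np.sqrt(2 * np.pi), g)
        got = si.loglik_observation(st, spec, 0, 0, 1.0)
        assert got == pytest.approx(np.log(phi), abs=1e-8)
        got0 = si.loglik_observation(st, spec, 0, 0, 0.0)
        assert got0 == pytest.approx(np.log1p(-phi), abs=1e-6)

    def test_marginal_matches_augmented_average(self):
        # integrating the truncated-normal augmentation over y* >= 0
        # reproduces Phi(alpha + beta*theta)
        eta = 0.8
        g = np.linspace(0, 14, 200_001)
        mass = np.trapezoid(np.exp(-(g - eta) ** 2 / 2)
                            / np.sqrt(2 * np.pi), g)
        spec = si.ModelSpec(variant="M0", is_dichotomous=(True,))
        st = _state(spec, 1, beta=np.array([eta]), theta=np.array([1.0]))
        assert si.loglik_observation(st, spec, 0, 0, 1.0) == pytest.approx(
            np.log(mass), abs=1e-8)


class TestLogJoint:
    def test_sign_violation_gives_minus_inf(self, toy_hs):
        data, adj, spec, st = toy_hs
        st = st.copy()
        dich = np.nonzero(data.is_dichotomous)[0]
        k = dich[0]
        h = 0
        # force a contradiction between y* and the observed 0/1 value
        st.ystar[h, k] = -1.0 if data.y[h, k] == 1.0 else 1.0
        assert si.log_joint(st, data, spec, adj) == -np.inf

    def test_m0_continuous_equals_hand_sum(self):
        # single continuous variable: joint = sum of normal log-densities
        # for data, theta prior, beta half-normal prior, sigma half-Cauchy
        spec = si.ModelSpec(variant="M0", is_dichotomous=(False,))
        data = make_toy_dataset(spec, n_areas=2, households_per_area=3)
        st = _state(spec, 2, beta=np.array([0.9]), theta=np.array([0.4, -1.1]),
                    sigma=np.array([0.8]))
        st.ystar = data.y.copy()
        got = si.log_joint(st, data, spec, None)

        def logn(x, m, s):
            return (-0.5 * ((x - m) / s) ** 2 - np.log(s)
                    - 0.5 * np.log(2 * np.pi))

        want = 0.0
        for j in range(data.n_households):
            i = data.area_ids[j]
            want += logn(data.y[j, 0], st.beta[0] * st.theta[i], st.sigma[0])
        for i in range(2):
            want += logn(st.theta[i], 0.0, 1.0)
        want += logn(st.beta[0], 0.0, 1.0) + np.log(2.0)  # half-normal
        want += np.log(2 / np.pi) - np.log1p(st.sigma[0] ** 2)  # half-Cauchy
        assert got == pytest.approx(want, abs=1e-10)

    def test_scale_invariance_of_continuous_likelihood(self):
        # (beta, theta) -> (c*beta, theta/c) leaves the likelihood terms
        # unchanged for continuous-only data with alpha = 0
        spec = si.ModelSpec(variant="M0", is_dichotomous=(False, False))
        data = make_toy_dataset(spec, n_areas=3, households_per_area=4)
        rng = np.random.default_rng(2)
        st = _state(spec, 3, beta=np.abs(rng.standard_normal(2)) + 0.1,
                    theta=rng.standard_normal(3),
                    sigma=np.array([0.7, 1.2]))
        st.ystar = data.y.copy()
        for c in (0.5, 2.0, 7.3):
            st2 = st.copy()
            st2.beta = c * st.beta
            st2.theta = st.theta / c
            ll1 = pointwise_loglik(st, data, spec).sum()
            ll2 = pointwise_loglik(st2, data, spec).sum()
            assert ll2 == pytest.approx(ll1, abs=1e-10)

    def test_additive_decomposition_in_theta(self, toy_hs):
        data, adj, spec, st = toy_hs
        st = st.copy()
        base = si.log_joint(st, data, spec, adj)
        st2 = st.copy()
        st2.theta = st.theta.copy()
        st2.theta[0] += 0.37
        moved = si.log_joint(st2, data, spec, adj)

        # independently: delta of the terms containing theta_0 only
        def theta0_terms(s):
            total = 0.0
            a = data.area_ids
            for j in np.nonzero(a == 0)[0]:
                for k in range(spec.p):
                    r = s.ystar[j, k] - s.alpha[0, k] - s.beta[k] * s.theta[0]
                    total += -0.5 * r**2 / s.sigma[k] ** 2
            q = si.build_car_precision(adj, s.iota).dense()
            total += -0.5 * q[0, 0] * s.theta[0] ** 2
            total += -q[0, 1] * s.theta[0] * s.theta[1]
            return total

        assert moved - base == pytest.approx(
            theta0_terms(st2) - theta0_terms(st), abs=1e-9)


class TestLoglikMatrix:
    @pytest.fixture
    def small_fit(self):
        spec = si.ModelSpec(variant="M0", is_dichotomous=(True, False))
        data = make_toy_dataset(spec, n_areas=2, households_per_area=2)
        draws = si.fit(data, None, spec,
                       si.McmcConfig(n_chains=1, n_iter=12, n_warmup=7,
                                     seed=0))
        return spec, data, draws

    def test_matches_nested_loop_oracle(self, small_fit):
        spec, data, draws = small_fit
        ll = si.loglik_matrix(draws, data)
        assert ll.shape == (5, data.n_households * data.n_variables)
        for r, st in enumerate(draws.iter_states()):
            col = 0
            for j in range(data.n_households):
                i = int(data.area_ids[j])
                for k in range(data.n_variables):
                    want = si.loglik_observation(st, spec, i, k, data.y[j, k])
                    assert ll[r, col] == pytest.approx(want, abs=1e-12)
                    col += 1

    def test_identical_states_give_identical_rows(self, small_fit):
        spec, data, draws = small_fit
        st = next(draws.iter_states())
        row1 = pointwise_loglik(st, data, spec).ravel()
        row2 = pointwise_loglik(st.copy(), data, spec).ravel()
        np.testing.assert_array_equal(row1, row2)


def test_model_spec_variant_table():
    for variant, hier, spat in [("HS", True, True), ("H", True, False),
                                ("S", False, True), ("M0", False, False)]:
        s = si.ModelSpec(variant=variant, is_dichotomous=(True,))
        assert s.hierarchical_alpha is hier
        assert s.spatial_theta is spat
    icar = si.ModelSpec(variant="HS_icar", is_dichotomous=(True,))
    assert icar.icar_theta and icar.hierarchical_alpha
    with pytest.raises(ValueError):
        si.ModelSpec(variant="HX", is_dichotomous=(True,))


def test_state_validation_catches_constraint_breaks(toy_hs):
    data, adj, spec, st = toy_hs
    bad = st.copy()
    bad.beta = bad.beta.copy()
    bad.beta[0] = -0.1
    with pytest.raises(ValueError, match="beta"):
        bad.validate(spec)
    bad2 = st.copy()
    bad2.sigma = bad2.sigma.copy()
    bad2.sigma[0] = 2.0  # dichotomous variable
    with pytest.raises(ValueError, match="sigma"):
        bad2.validate(spec)
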