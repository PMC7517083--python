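"""Closed-form model results against independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.stats import gamma as gamma_dist

from stochpop import (
    ModelParams,
    Regime,
    TimeGrid,
    exact_logistic,
    exact_richards,
    linear_model_moments,
    stationary_gamma_moments,
)


def ode_oracle(a, eps, x0, t_eval, beta=2.0):
    """Adaptive integration of dX/dt = a X - eps X^beta (independent oracle)."""
    sol = solve_ivp(
        lambda t, x: a * x - eps * x**beta,
        (0.0, max(t_eval)),
        [x0],
        t_eval=t_eval,
        rtol=1e-11,
        atol=1e-13,
        method="RK45",
    )
    return sol.y[0]


class TestModelParams:
    def test_carrying_capacity_and_regimes(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=50.0, lam=0.01)
        assert p.carrying_capacity == 50.0
        assert p.regime is Regime.PERSISTENT
        assert ModelParams(a0=0.0001, eps=0.01, x0=0.5, lam=0.02).regime is Regime.EXTINCTION
        assert ModelParams(a0=0.125, eps=0.01, x0=0.5, lam=0.5).regime is Regime.TRANSITION
        assert ModelParams(a0=0.5, eps=0.0, x0=1.0).carrying_capacity == np.inf

    @pytest.mark.parametrize(
        "kwargs", [dict(eps=-1e-3), dict(x0=0.0), dict(lam=-0.1), dict(a1=-0.01)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(a0=0.5, eps=0.01, x0=0.5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ModelParams(**base)


class TestTimeGrid:
    def test_times_and_horizon(self):
        g = TimeGrid.from_horizon(0.05, 40.0)
        assert g.n_steps == 800
        assert g.times[0] == 0.0
        assert g.times[-1] == pytest.approx(40.0)
        np.testing.assert_allclose(np.diff(g.times), 0.05)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            TimeGrid(dt=0.0, n_steps=10)
        with pytest.raises(ValueError):
            TimeGrid(dt=0.1, n_steps=0)


class TestExactLogistic:
    def test_fixed_point_at_carrying_capacity(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=50.0)
        assert exact_logistic(p, 10.0) == pytest.approx(50.0, abs=1e-12)

    def test_long_time_limits(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5)
        assert exact_logistic(p, 1e4) == pytest.approx(50.0, rel=1e-12)
        decay = ModelParams(a0=-0.5, eps=0.01, x0=0.5)
        assert exact_logistic(decay, 1e3) == pytest.approx(0.0, abs=1e-12)

    def test_matches_adaptive_ode_integration(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5)
        t = np.array([5.0, 10.0, 20.0])
        np.testing.assert_allclose(exact_logistic(p, t), ode_oracle(0.5, 0.01, 0.5, t), rtol=1e-8)

    def test_ode_residual_by_finite_differences(self):
        # five-point central stencil keeps the differentiation error ~h^4
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5)
        h = 1e-3
        for t in np.linspace(1.0, 30.0, 12):
            x = np.array([exact_logistic(p, t + k * h) for k in (-2, -1, 0, 1, 2)])
            dxdt = (x[0] - 8 * x[1] + 8 * x[3] - x[4]) / (12 * h)
            assert abs(dxdt - p.a0 * x[2] + p.eps * x[2] ** 2) < 1e-8

    @given(
        a0=st.floats(0.1, 2.0),
        eps=st.floats(1e-3, 0.1),
        ratio=st.floats(0.01, 0.99) | st.floats(1.01, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_approach_to_capacity(self, a0, eps, ratio):
        # strictly increasing from below L, strictly decreasing from above
        L = a0 / eps
        p = ModelParams(a0=a0, eps=eps, x0=ratio * L)
        t = np.linspace(0.0, 20.0, 50)
        diffs = np.diff(exact_logistic(p, t))
        # strict until the trajectory saturates at float resolution
        if ratio < 1:
            assert diffs[0] > 0 and np.all(diffs >= 0)
        else:
            assert diffs[0] < 0 and np.all(diffs <= 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_logistic(ModelParams(a0=0.0, eps=0.01, x0=0.5), 1.0)
        with pytest.raises(ValueError):
            exact_logistic(ModelParams(a0=0.5, eps=0.0, x0=0.5), 1.0)
        with pytest.raises(ValueError):
            exact_logistic(ModelParams(a0=0.5, eps=0.01, x0=0.5), -1.0)


class TestExactRichards:
    def test_beta_two_reduces_to_logistic(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5)
        t = np.linspace(0.0, 30.0, 40)
        np.testing.assert_allclose(
            exact_richards(p, 2.0, t), exact_logistic(p, t), rtol=1e-12
        )

    def test_matches_ode_oracle_beta3(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5)
        t = np.array([2.0, 5.0, 10.0])
        np.testing.assert_allclose(
            exact_richards(p, 3.0, t), ode_oracle(0.5, 0.01, 0.5, t, beta=3.0), rtol=1e-8
        )

    @pytest.mark.parametrize("beta", [1.5, 2.0, 3.0, 4.0])
    def test_steady_state_independent_of_beta_at_fixed_capacity(self, beta):
        # the allometric exponent reshapes the transient only when the loss
        # coefficient is tied to a fixed carrying capacity L = 50
        a0, L = 0.5, 50.0
        p = ModelParams(a0=a0, eps=a0 / L ** (beta - 1.0), x0=0.5)
        assert exact_richards(p, beta, 1e4) == pytest.approx(L, rel=1e-10)

    def test_beta_one_rejected(self):
        with pytest.raises(ValueError):
            exact_richards(ModelParams(a0=0.5, eps=0.01, x0=0.5), 1.0, 1.0)


class TestStationaryGamma:
    @pytest.mark.parametrize(
        "lam,mean,var",
        [(0.01, 49.995, 0.249975), (0.02, 49.98, 0.9996)],
    )
    def test_moments_at_reference_parameters(self, lam, mean, var):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5, lam=lam)
        m, v = stationary_gamma_moments(p)
        assert m == pytest.approx(mean, rel=1e-12)
        assert v == pytest.approx(var, rel=1e-12)

    def test_agrees_with_scipy_gamma(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5, lam=0.015)
        shape = 2 * p.a0 / p.lam**2 - 1
        scale = p.lam**2 / (2 * p.eps)
        m_ref, v_ref = gamma_dist.stats(shape, scale=scale, moments="mv")
        m, v = stationary_gamma_moments(p)
        assert m == pytest.approx(float(m_ref), rel=1e-12)
        assert v == pytest.approx(float(v_ref), rel=1e-12)

    @given(a0=st.floats(0.1, 2.0), eps=st.floats(1e-3, 0.1), lam=st.floats(1e-3, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_mean_identity_over_sweep(self, a0, eps, lam):
        # shape*scale simplifies algebraically to a0/eps - lam^2/(2 eps)
        p = ModelParams(a0=a0, eps=eps, x0=1.0, lam=lam)
        if p.regime is not Regime.PERSISTENT:
            return
        m, _ = stationary_gamma_moments(p)
        assert m == pytest.approx(a0 / eps - lam**2 / (2 * eps), rel=1e-10)

    def test_deterministic_limit(self):
        p = ModelParams(a0=0.5, eps=0.01, x0=0.5, lam=0.0)
        assert stationary_gamma_moments(p) == (50.0, 0.0)

    def test_no_stationary_law_in_extinction_regime(self):
        p = ModelParams(a0=0.0001, eps=0.01, x0=0.5, lam=0.02)
        with pytest.raises(ValueError, match="regime"):
            stationary_gamma_moments(p)


class TestLinearModelMoments:
    def test_zero_noise(self):
        mean, var = linear_model_moments(a=0.5, lam=0.0, x0=1.0, t=2.0)
        assert mean == pytest.approx(np.e, rel=1e-14)
        assert var == 0.0

    def test_mean_is_exponential_growth(self):
        mean, _ = linear_model_moments(a=0.5, lam=0.1, x0=1.0, t=1.0)
        assert mean == pytest.approx(np.exp(0.5), rel=1e-14)

    def test_variance_against_gbm_sampling(self):
        # 10^6 exact geometric-Brownian-motion draws as Monte Carlo oracle
        a, lam, x0, t = 0.5, 0.1, 1.0, 1.0
        rng = np.random.default_rng(123)
        X = x0 * np.exp((a - 0.5 * lam**2) * t + lam * np.sqrt(t) * rng.standard_normal(10**6))
        sample_var = X.var(ddof=1)
        m4 = ((X - X.mean()) ** 4).mean()
        se = np.sqrt((m4 - sample_var**2) / X.size)
        _, var = linear_model_moments(a, lam, x0, t)
        assert abs(var - sample_var) < 3 * se

    def test_small_noise_series_limit(self):
        # Var -> lam^2 t x0^2 e^{2at} with relative error < lam^2 t
        for lam, t in [(0.01, 1.0), (0.02, 2.0), (0.005, 10.0)]:
            assert lam**2 * t < 1e-3
            _, var = linear_model_moments(0.3, lam, 2.0, t)
            lead = lam**2 * t * 4.0 * np.exp(2 * 0.3 * t)
            assert abs(var - lead) / lead < lam**2 * t
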