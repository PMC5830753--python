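import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma

from casparks import (DiffusionStepper, StabilityError, apply_operator,
                      build_operator, grunwald_weights, rl_quadrature_oracle)


class TestGrunwaldWeights:
    def test_order_two_gives_laplacian_stencil(self):
        w = grunwald_weights(2.0, 5).weights
        assert np.allclose(w, [1, -2, 1, 0, 0])

    def test_order_1p25_recurrence_values(self):
        w = grunwald_weights(1.25, 3).weights
        assert w[0] == 1.0
        assert w[1] == pytest.approx(-1.25)
        assert w[2] == pytest.approx(0.15625)   # g1 * (1 - 1.25) / 2

    def test_partial_sums_tend_to_zero(self):
        w = grunwald_weights(2.25, 4000).weights
        partial = np.cumsum(w)
        assert abs(partial[-1]) < 1e-3
        assert abs(partial[-1]) < abs(partial[40])

    def test_paper_literal_differs_by_gamma_factor(self):
        a = grunwald_weights(1.25, 6, "normalized").weights
        b = grunwald_weights(1.25, 6, "paper_literal").weights
        assert np.allclose(b, a * gamma(-1.25))

    @pytest.mark.parametrize("order", [0.5, 1.0, 2.5, -1.0])
    def test_order_domain_enforced(self, order):
        with pytest.raises(ValueError):
            grunwald_weights(order, 4)

    @given(st.floats(min_value=1.01, max_value=2.25))
    @settings(max_examples=25, deadline=None)
    def test_recurrence_invariant(self, order):
        w = grunwald_weights(order, 10).weights
        k = np.arange(1, 10)
        assert np.allclose(w[1:], w[:-1] * (k - 1 - order) / k)


class TestApplyOperator:
    def test_constant_field_maps_to_zero(self):
        op = build_operator(60, 0.1, 2.25)
        assert np.abs(apply_operator(np.full(60, 3.7), op)).max() < 1e-10

    def test_power_function_matches_closed_form(self):
        """Left-sided order-a derivative of x^2 is G(3)/G(3-a) x^(2-a)."""
        n, h, a = 1000, 1e-3, 2.25
        x = (np.arange(n) + 0.5) * h
        op = build_operator(n, h, a, side_mode="left", boundary="extend_zero")
        num = apply_operator(x ** 2, op)
        exact = gamma(3) / gamma(3 - a) * x ** (2 - a)
        sl = slice(100, 900)
        rel = np.abs(num[sl] - exact[sl]) / np.abs(exact[sl])
        assert rel.max() < 0.02

    def test_order_two_matches_classical_second_difference(self):
        n, h = 64, 0.05
        g = np.exp(-((np.arange(n) + 0.5) * h - 1.6) ** 2 / 0.1)
        op = build_operator(n, h, 2.0)
        ge = np.concatenate([[g[0]], g, [g[-1]]])   # zero-flux ghost
        classical = (ge[2:] - 2 * ge[1:-1] + ge[:-2]) / h ** 2
        assert np.abs(apply_operator(g, op) - classical).max() < 1e-10

    def test_riesz_mode_preserves_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        f = rng.random(40)
        op = build_operator(40, 0.1, 2.25, side_mode="riesz_symmetric")
        assert np.allclose(apply_operator(f[::-1], op),
                           apply_operator(f, op)[::-1], atol=1e-12)

    def test_shape_mismatch_raises(self):
        op = build_operator(16, 0.1, 2.25)
        with pytest.raises(ValueError):
            apply_operator(np.zeros(17), op)


class TestQuadratureOracle:
    def test_cubic_closed_form(self):
        a = 2.25
        x = np.linspace(0, 1, 1200)
        d = rl_quadrature_oracle(x, x ** 3, a)
        exact = gamma(4) / gamma(4 - a) * x ** (3 - a)
        sl = slice(120, 1080)
        assert np.max(np.abs(d[sl] - exact[sl]) / np.abs(exact[sl])) < 0.01

    def test_constant_follows_power_law_decay(self):
        """The (Riemann-Liouville) derivative of a constant is not zero but
        decays as c x^-a / Gamma(1-a) away from the lower terminal."""
        a = 2.25
        x = np.linspace(0, 1, 600)
        d = rl_quadrature_oracle(x, np.full_like(x, 2.0), a)
        sl = slice(200, -10)
        exact = 2.0 * x[sl] ** (-a) / gamma(1 - a)
        assert np.max(np.abs(d[sl] - exact) / np.abs(exact)) < 0.01

    def test_grunwald_agrees_with_oracle_on_square(self):
        """The discrete scheme and the integral-definition oracle are two
        independent routes to the same derivative."""
        n, h, a = 1000, 1e-3, 2.25
        x = (np.arange(n) + 0.5) * h
        f = x ** 2
        op = build_operator(n, h, a, side_mode="left", boundary="extend_zero")
        num = apply_operator(f, op)
        orc = rl_quadrature_oracle(x, f, a)
        sl = slice(100, 900)
        scale = np.abs(gamma(3) / gamma(3 - a) * x[sl] ** (2 - a))
        assert np.max(np.abs(num[sl] - orc[sl]) / scale) < 0.02


class TestDiffusionStepper:
    def _steppers(self, n=64, h=0.05, order=2.0, Dx=30.0, Dy=15.0):
        opx = build_operator(n, h, order, axis="x")
        opy = build_operator(n, h, order, axis="y")
        return DiffusionStepper(opx, opy, Dx, Dy), h, n

    def test_zero_field_stays_zero(self):
        st_, h, n = self._steppers()
        out = st_.step(np.zeros((n, n)), 1e-4)
        assert np.abs(out).max() == 0.0

    def test_point_release_matches_gaussian_green_function(self):
        st_, h, n = self._steppers(n=128, h=0.05, order=2.0, Dx=30, Dy=15)
        f = np.zeros((n, n))
        f[n // 2, n // 2] = 1.0 / h ** 2
        dt, nsteps = 2e-5, 200
        for _ in range(nsteps):
            f = st_.step(f, dt)
        t = dt * nsteps
        xs = (np.arange(n) + 0.5) * h - (n // 2 + 0.5) * h
        X, Y = np.meshgrid(xs, xs)
        G = np.exp(-(X ** 2 / (4 * 30 * t) + Y ** 2 / (4 * 15 * t))) \
            / (4 * np.pi * t * np.sqrt(30.0 * 15.0))
        assert np.linalg.norm(f - G) / np.linalg.norm(G) < 0.01

    def test_implicit_step_is_bitwise_deterministic(self):
        st_, h, n = self._steppers(order=2.25)
        f = np.random.default_rng(3).random((n, n))
        a = st_.step(f, 1e-4)
        b = st_.step(f, 1e-4)
        assert np.array_equal(a, b)

    def test_explicit_above_bound_raises(self):
        st_, h, n = self._steppers(order=2.25)
        with pytest.raises(StabilityError):
            st_.step(np.zeros((n, n)), 10 * st_.dt_stable_explicit(),
                     mode="explicit")

    def test_implicit_explicit_agree_as_dt_shrinks(self):
        st_, h, n = self._steppers(n=40, h=0.1, order=2.25, Dx=3.0, Dy=1.5)
        f = np.random.default_rng(0).random((40, 40))
        errs = []
        for dt in (2e-4, 1e-4, 5e-5):
            errs.append(np.abs(st_.step(f, dt) - st_.step(f, dt, "explicit")).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] / errs[0] < 0.5   # O(dt) agreement
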