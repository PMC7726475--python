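"""SCAD penalty values, threshold operators, Newton step and SVD zeroing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcgnet import (
    OptimizerState,
    newton_step,
    scad,
    scad_derivative,
    scad_threshold,
    soft_threshold,
    sparsify_by_svd,
)
from dcgnet.optim import (
    GaussNewtonObjective,
    QuadraticObjective,
    StalledStepError,
    solve_penalized_precision,
)


class TestScad:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            (0.0, 0.0),  # origin
            (0.5, 0.5),  # linear piece: lam * |x|
            (10.0, 2.35),  # plateau: lam^2 (a+1) / 2 = 4.7 / 2
        ],
    )
    def test_reference_values(self, theta, expected):
        assert scad(theta, lam=1.0, a=3.7) == pytest.approx(expected, abs=1e-12)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            scad(1.0, lam=1.0, a=2.0)
        with pytest.raises(ValueError):
            scad_derivative(1.0, lam=1.0, a=1.5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        x=st.floats(-20, 20),
        lam=st.floats(0.01, 3.0),
        a=st.floats(2.1, 8.0),
    )
    def test_continuity_and_derivative_consistency(self, x, lam, a):
        # penalty is even, non-decreasing in |x|, and its finite-difference
        # slope matches scad_derivative away from the origin
        assert scad(x, lam, a) == pytest.approx(scad(-x, lam, a))
        h = 1e-6
        if abs(x) > 1e-3:
            fd = (scad(abs(x) + h, lam, a) - scad(abs(x) - h, lam, a)) / (2 * h)
            assert fd == pytest.approx(scad_derivative(x, lam, a), abs=1e-5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        z=st.floats(-10, 10),
        lam=st.floats(0.01, 2.0),
        step=st.floats(0.05, 1.0),
    )
    def test_scad_threshold_minimizes_its_objective(self, z, lam, step):
        # grid oracle: the prox output must beat a dense scan of candidates
        a = 3.7
        x = scad_threshold(z, lam, a, step)

        def obj(v):
            return (v - z) ** 2 / (2 * step) + scad(v, lam, a)

        grid = np.linspace(-12.0, 12.0, 4801)
        grid_best = float(np.min(obj(grid)))
        assert obj(x) <= grid_best + 1e-9


class TestSoftThreshold:
    def test_scalar_lasso_closed_form(self):
        # argmin_x (x - z)^2 / (2 step) + lam |x|  ==  soft(z, step * lam)
        z, lam, step = 0.7, 0.4, 0.5
        grid = np.linspace(-2, 2, 200_001)
        obj = (grid - z) ** 2 / (2 * step) + lam * np.abs(grid)
        assert soft_threshold(z, step * lam) == pytest.approx(
            grid[np.argmin(obj)], abs=1e-4
        )
        assert soft_threshold(0.3, 0.5) == 0.0
        assert soft_threshold(-1.0, 0.25) == pytest.approx(-0.75)


class TestNewtonStep:
    def test_quadratic_objective_solved_in_one_step(self):
        target = np.array([1.0, -2.0, 0.5])
        state = OptimizerState(theta=np.zeros(3))
        new = newton_step(state, QuadraticObjective(target))
        assert new.alpha == 1.0
        assert np.allclose(new.theta, target, atol=1e-12)

    def test_gauss_newton_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        j = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        obj = GaussNewtonObjective(
            residual=lambda th: j @ th - y, jacobian=lambda th: j
        )
        theta = rng.standard_normal(4)
        g = obj.gradient(theta)
        h = 1e-6
        for k in range(4):
            e = np.zeros(4)
            e[k] = h
            fd = (obj.value(theta + e) - obj.value(theta - e)) / (2 * h)
            assert g[k] == pytest.approx(fd, abs=1e-6)

    def test_stationary_point_is_fixed(self):
        target = np.array([0.3, -0.1])
        state = OptimizerState(theta=target.copy())
        new = newton_step(state, QuadraticObjective(target))
        assert np.allclose(new.theta, target)

    def test_stalled_step_raises(self):
        class Flat:
            def value(self, th):
                return 0.0

            def gradient(self, th):
                return np.ones_like(th)

            def hessian(self, th):
                return np.eye(th.size)

        with pytest.raises(StalledStepError):
            # constant objective but nonzero gradient: no decrease possible,
            # and the proposed steps never coincide with the current point
            newton_step(OptimizerState(theta=np.ones(2)), Flat())

    def test_pinned_coordinates_stay_zero(self):
        target = np.array([1.0, -2.0, 0.5])
        state = OptimizerState(theta=np.zeros(3))
        state.pinned[1] = True
        new = newton_step(state, QuadraticObjective(target))
        assert new.theta[1] == 0.0
        assert np.allclose(new.theta[[0, 2]], target[[0, 2]], atol=1e-12)


class TestSparsifyBySvd:
    def test_tau_zero_pins_nothing(self):
        state = OptimizerState(
            theta=np.array([1e-9, 2.0]), jacobian=np.eye(2)
        )
        assert not sparsify_by_svd(state, 0.0).pinned.any()

    def test_tau_inf_pins_all_penalized(self):
        state = OptimizerState(theta=np.array([3.0, 4.0]), jacobian=np.eye(2))
        state.pinnable[:] = [True, False]
        new = sparsify_by_svd(state, np.inf)
        assert list(new.pinned) == [True, False]
        assert new.theta[0] == 0.0 and new.theta[1] == 4.0

    def test_pinned_set_matches_brute_force_and_is_monotone(self):
        rng = np.random.default_rng(3)
        j = rng.standard_normal((20, 6))
        theta = rng.standard_normal(6) * np.array([1e-4, 1, 1e-3, 2, 1e-5, 0.5])
        tau = 1e-3
        state = OptimizerState(theta=theta.copy(), jacobian=j)
        new = sparsify_by_svd(state, tau)
        # independent computation of the rule
        sigma_max = np.linalg.svd(j, compute_uv=False).max()
        col = np.linalg.norm(j, axis=0)
        expected = np.abs(theta) <= tau * sigma_max * col / col.max()
        assert np.array_equal(new.pinned, expected)
        # monotone: a second call at smaller tau cannot unpin
        again = sparsify_by_svd(new, 0.0)
        assert np.array_equal(again.pinned, new.pinned)


class TestPenalizedPrecision:
    def test_two_by_two_closed_form(self):
        # with off-diagonal penalty lam, the covariance estimate keeps the
        # sample diagonal and soft-thresholds the off-diagonal entry
        s = np.array([[1.2, 0.5], [0.5, 0.9]])
        lam = 0.2
        w_expected = np.array(
            [[1.2, soft_threshold(0.5, lam)], [soft_threshold(0.5, lam), 0.9]]
        )
        omega_expected = np.linalg.inv(w_expected)
        omega = solve_penalized_precision(s, np.full((2, 2), lam))
        assert np.allclose(omega, omega_expected, atol=1e-6)

    def test_full_shrinkage_gives_diagonal_precision(self):
        s = np.array([[1.0, 0.8], [0.8, 2.0]])
        omega = solve_penalized_precision(s, np.full((2, 2), 50.0))
        assert omega[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_sklearn_graphical_lasso(self):
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 4))
        x[:, 1] += 0.7 * x[:, 0]
        s = np.cov(x.T)
        lam = 0.1
        _, prec_skl = graphical_lasso(s, alpha=lam)
        omega = solve_penalized_precision(s, np.full((4, 4), lam), tol=1e-12)
        assert np.allclose(omega, prec_skl, atol=1e-4)
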