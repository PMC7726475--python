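"""Connectivity estimators: oracles, collapse to OLS, invariants."""

import numpy as np
import pytest

from dcgnet import (
    ConnectivityEstimate,
    MultichannelRecording,
    PenaltySpec,
    SingularDesignError,
    bic,
    build_design,
    fit_glasso,
    fit_method,
    fit_tscgm,
    fit_tscgm_iterative,
    fit_tscgm_nonlinear,
    fit_var_ols,
    neg_loglik,
    select_lambda,
    simulate_var1,
    sparsity_proportion,
    threshold_weak_links,
)
from dcgnet.estimators import METHOD_TAGS

# 6-sample, 2-channel fixture used for the normal-equations oracle
FIXTURE_62 = np.array(
    [
        [0.2, -1.1, 0.7, 1.3, -0.4, 0.9],
        [1.5, 0.3, -0.8, 0.6, 1.1, -0.2],
    ]
)

PENALIZED_FITS = {
    "glasso": lambda rec, p, **kw: fit_glasso(rec, p, **kw),
    "tscgm": lambda rec, p, **kw: fit_tscgm(rec, p, **kw),
    "tscgm_nl": lambda rec, p, **kw: fit_tscgm_nonlinear(rec, p, tau=0.0, **kw),
    "tscgm_it": lambda rec, p, **kw: fit_tscgm_iterative(rec, p, **kw),
}


class TestBuildDesign:
    def test_lag_alignment_shapes(self):
        rec = MultichannelRecording(
            np.random.default_rng(0).standard_normal((3, 10)), 1.0
        )
        d = build_design(rec)
        assert d.y.shape == (9, 3)
        assert d.x.shape == (9, 4)
        assert np.all(d.x[:, 0] == 1.0)
        assert np.array_equal(d.x[:, 1:], rec.data.T[:-1])
        assert np.array_equal(d.y, rec.data.T[1:])

    def test_constant_recording_flagged_rank_deficient(self):
        rec = MultichannelRecording(np.ones((2, 20)), 1.0)
        assert build_design(rec).is_rank_deficient
        with pytest.raises(SingularDesignError, match="ch0"):
            fit_var_ols(rec)

    def test_channel_permutation_permutes_design_columns(self):
        rng = np.random.default_rng(1)
        rec = MultichannelRecording(rng.standard_normal((3, 15)), 1.0, ["a", "b", "c"])
        perm = rec.select_channels(["c", "a", "b"])
        d0, dp = build_design(rec), build_design(perm)
        order = [2, 0, 1]
        assert np.array_equal(dp.y, d0.y[:, order])
        assert np.array_equal(dp.x[:, 1:], d0.x[:, 1:][:, order])


class TestNegLoglik:
    def test_zero_residual_identity_precision_is_zero(self):
        rec = MultichannelRecording(np.zeros((2, 8)) + [[1.0], [2.0]], 1.0)
        d = build_design(rec)
        gamma = np.zeros((2, 2))
        val = neg_loglik(gamma, np.array([1.0, 2.0]), np.eye(2), d)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_identity_precision_reduces_to_mean_squared_frobenius(self):
        rng = np.random.default_rng(2)
        rec = MultichannelRecording(rng.standard_normal((2, 12)), 1.0)
        d = build_design(rec)
        gamma = rng.standard_normal((2, 2)) * 0.1
        intercept = rng.standard_normal(2) * 0.1
        r = d.y - d.x @ np.vstack([intercept, gamma.T])
        val = neg_loglik(gamma, intercept, np.eye(2), d)
        assert val == pytest.approx(np.sum(r**2) / d.t, abs=1e-12)

    def test_matches_elementwise_summation_oracle(self):
        rng = np.random.default_rng(3)
        rec = MultichannelRecording(rng.standard_normal((3, 20)), 1.0)
        d = build_design(rec)
        gamma = rng.standard_normal((3, 3)) * 0.2
        intercept = rng.standard_normal(3)
        omega = np.eye(3) + 0.3 * np.ones((3, 3))
        r = d.y - d.x @ np.vstack([intercept, gamma.T])
        # naive double loop over the trace
        acc = 0.0
        for t in range(d.t):
            for i in range(3):
                for j in range(3):
                    acc += r[t, i] * omega[i, j] * r[t, j]
        expected = acc / d.t - np.log(np.linalg.det(omega))
        assert neg_loglik(gamma, intercept, omega, d) == pytest.approx(
            expected, abs=1e-10
        )

    def test_non_pd_omega_rejected(self):
        rng = np.random.default_rng(4)
        rec = MultichannelRecording(rng.standard_normal((2, 10)), 1.0)
        d = build_design(rec)
        with pytest.raises(ValueError):
            neg_loglik(np.zeros((2, 2)), np.zeros(2), -np.eye(2), d)


class TestVarOls:
    def test_deterministic_ar_recovered_exactly(self):
        # two decoupled noiseless AR(1) channels with distinct decay rates
        t = 40
        y = np.empty((2, t))
        y[:, 0] = [3.0, -2.0]
        for k in range(1, t):
            y[0, k] = 0.5 * y[0, k - 1]
            y[1, k] = 0.3 * y[1, k - 1]
        est = fit_var_ols(MultichannelRecording(y, 1.0))
        assert np.allclose(est.gamma_hat, np.diag([0.5, 0.3]), atol=1e-10)
        assert np.allclose(est.intercept_hat, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle_on_fixture(self):
        rec = MultichannelRecording(FIXTURE_62, 1.0)
        est = fit_var_ols(rec)
        # explicit normal equations on the raw (unstandardized) data
        y = FIXTURE_62.T[1:]
        x = np.column_stack([np.ones(5), FIXTURE_62.T[:-1]])
        b = np.linalg.inv(x.T @ x) @ (x.T @ y)
        assert np.allclose(est.intercept_hat, b[0], atol=1e-10)
        assert np.allclose(est.gamma_hat, b[1:].T, atol=1e-10)
        r = y - x @ b
        sigma = r.T @ r / (5 - 3)
        assert np.allclose(est.sigma_hat, sigma, atol=1e-10)

    def test_matches_statsmodels_var(self, recording5):
        # independent oracle: statsmodels' VAR(1) with constant trend
        from statsmodels.tsa.api import VAR

        res = VAR(recording5.data.T).fit(maxlags=1, trend="c")
        est = fit_var_ols(recording5)
        assert np.allclose(est.intercept_hat, res.params[0], atol=1e-8)
        assert np.allclose(est.gamma_hat, res.coefs[0], atol=1e-8)

    def test_consistency_on_long_simulation(self, model5):
        rec = simulate_var1(model5, 20_000, seed=12)
        est = fit_var_ols(rec)
        assert np.abs(est.gamma_hat - model5.gamma).max() < 0.05


class TestPenalizedFits:
    @pytest.mark.parametrize("name", list(PENALIZED_FITS))
    def test_zero_penalty_collapses_to_ols(self, name, recording5):
        ols = fit_var_ols(recording5)
        est = PENALIZED_FITS[name](recording5, PenaltySpec("none"))
        tol = 1e-4 if name == "tscgm_nl" else 1e-6
        assert np.abs(est.gamma_hat - ols.gamma_hat).max() < tol
        assert np.abs(est.intercept_hat - ols.intercept_hat).max() < tol
        # precisions agree once the ML vs (t-m-1) denominators are aligned
        t, m = recording5.t - 1, recording5.n_channels
        scale = (t - m - 1) / t
        assert np.abs(est.omega_hat * scale - ols.omega_hat).max() < 1e-3

    @pytest.mark.parametrize("name", ["glasso", "tscgm", "tscgm_it"])
    def test_huge_lambda1_zeroes_all_lag_coefficients(self, name, recording3):
        fam = "scad" if name == "tscgm" else "l1"
        est = PENALIZED_FITS[name](recording3, PenaltySpec(fam, lambda1=1e3))
        assert np.abs(est.gamma_hat).max() <= 1e-8

    def test_huge_lambda1_zeroes_newton_fit_via_pinning(self, recording3):
        # at the default zeroing threshold the pinned coefficients are exact zeros
        est = fit_tscgm_nonlinear(recording3, PenaltySpec("l1", lambda1=1e3))
        assert np.abs(est.gamma_hat).max() == 0.0

    def test_huge_lambda2_gives_diagonal_precision(self, recording3):
        est = fit_glasso(recording3, PenaltySpec("l1", lambda1=1e3, lambda2=1e3))
        off = ~np.eye(3, dtype=bool)
        assert np.abs(est.omega_hat[off]).max() <= 1e-10

    @pytest.mark.parametrize("name", list(PENALIZED_FITS))
    def test_objective_monotone_and_precision_pd(self, name, recording5):
        fam = "scad" if name in ("tscgm",) else "l1"
        est = PENALIZED_FITS[name](recording5, PenaltySpec(fam, 0.05, 0.05))
        hist = np.asarray(est.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)
        assert np.linalg.eigvalsh(est.omega_hat).min() > 0
        assert np.allclose(
            est.sigma_hat @ est.omega_hat, np.eye(est.m), atol=1e-6
        )

    def test_sparsity_increases_with_lambda_on_grid(self, recording5):
        nnz = []
        for lam in (0.01, 0.1, 1.0):
            est = fit_tscgm_iterative(recording5, PenaltySpec("l1", lam, lam))
            nnz.append(np.count_nonzero(np.abs(est.gamma_hat) > 1e-12))
        assert nnz[0] >= nnz[1] >= nnz[2]

    def test_permutation_equivariance(self, recording5):
        order = [3, 1, 4, 0, 2]
        labels = [recording5.labels[i] for i in order]
        perm = recording5.select_channels(labels)
        for fitter, spec in [
            (fit_var_ols, None),
            (lambda r: fit_glasso(r, PenaltySpec("l1", 0.05, 0.05)), None),
        ]:
            e0 = fitter(recording5)
            ep = fitter(perm)
            p = np.array(order)
            tol = 1e-12 if e0.method == "var_ols" else 1e-6
            assert np.allclose(ep.gamma_hat, e0.gamma_hat[np.ix_(p, p)], atol=tol)
            assert np.allclose(ep.omega_hat, e0.omega_hat[np.ix_(p, p)], atol=tol)


class TestSelection:
    def test_singleton_grid_returned(self, recording3):
        spec = PenaltySpec("l1", 0.07, 0.07)
        assert select_lambda(recording3, "glasso", [spec]) == spec

    def test_bic_choice_matches_brute_force(self, recording5):
        grid = [PenaltySpec("l1", lam, lam) for lam in (0.01, 0.05, 0.2)]
        chosen = select_lambda(recording5, "glasso", grid)
        t = recording5.t - 1
        bics = [bic(fit_glasso(recording5, g), t) for g in grid]
        assert chosen == grid[int(np.argmin(bics))]

    def test_bic_choice_sparser_than_unpenalized(self, model5):
        rec = simulate_var1(model5, 2000, seed=33)
        grid = [PenaltySpec("scad", lam, lam) for lam in (0.0, 0.05, 0.1, 0.2)]
        _, est = select_lambda(rec, "tscgm", grid, return_estimate=True)
        ols = fit_var_ols(rec)
        assert est.sparsity_gamma > ols.sparsity_gamma


class TestThresholdAndSparsity:
    def _estimate_with_gamma(self, gamma):
        m = gamma.shape[0]
        return ConnectivityEstimate(
            gamma_hat=gamma,
            intercept_hat=np.zeros(m),
            sigma_hat=np.eye(m),
            omega_hat=np.eye(m),
            method="var_ols",
            penalty=PenaltySpec("none"),
            labels=[f"ch{i}" for i in range(m)],
        )

    def test_q_zero_is_identity(self):
        est = self._estimate_with_gamma(np.array([[0.5, 0.1], [0.0, 0.4]]))
        out = threshold_weak_links(est, 0.0)
        assert np.array_equal(out.gamma_hat, est.gamma_hat)

    def test_equal_magnitudes_survive_median_threshold(self):
        est = self._estimate_with_gamma(np.full((2, 2), 0.3))
        out = threshold_weak_links(est, 0.5)
        assert np.count_nonzero(out.gamma_hat) == 4

    def test_median_keeps_top_half_of_fixture(self):
        gamma = np.array(
            [[0.9, 0.5, 0.0], [0.1, 0.0, 0.05], [0.0, 0.0, 0.0]]
        )
        out = threshold_weak_links(self._estimate_with_gamma(gamma), 0.5)
        kept = np.abs(out.gamma_hat[np.abs(out.gamma_hat) > 0])
        assert sorted(kept.tolist()) == [0.5, 0.9]

    @pytest.mark.parametrize(
        "matrix,kwargs,expected",
        [
            (np.zeros((3, 3)), {}, 1.0),
            (np.eye(3), {}, 6 / 9),
            (np.arange(1, 10).reshape(3, 3), {}, 0.0),
            (np.eye(3), {"exclude_diagonal": True}, 1.0),
        ],
    )
    def test_sparsity_proportion(self, matrix, kwargs, expected):
        assert sparsity_proportion(matrix, **kwargs) == pytest.approx(expected)


class TestDispatch:
    def test_unknown_tag_rejected(self, recording3):
        with pytest.raises(ValueError, match="unknown method"):
            fit_method(recording3, "magic")

    @pytest.mark.parametrize("tag", [t for t in METHOD_TAGS if t != "var_ols"])
    def test_tags_route_to_matching_method(self, tag, recording3):
        est = fit_method(recording3, tag, PenaltySpec("l1", 0.05, 0.05))
        assert est.method == tag
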