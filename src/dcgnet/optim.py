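"""Numerical optimization primitives shared by the sparse estimators.

Three workhorses live here:

* a damped Newton step with backtracking line search (used by the joint
  "non-linear" chain-graph fit),
* SVD-based zeroing: parameters whose magnitude falls below a threshold
  scaled by the Jacobian's largest singular value and per-column norms are
  pinned to exactly zero for the remainder of a fit (the pinned set only
  grows),
* proximal inner solvers: an ISTA loop for (weighted-)l1 multi-response
  regression given a fixed precision, and a G-ISTA loop for the
  (weighted-)l1 penalized precision problem
  ``min tr(S W) - log det W + sum_{k != k'} lam[k,k'] |W[k,k']|``.

The precision solver is the graphical-lasso building block; it is written
in-package (rather than delegated) because the SCAD alternation needs
per-entry penalty weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .penalties import soft_threshold

__all__ = [
    "OptimizerState",
    "QuadraticObjective",
    "GaussNewtonObjective",
    "StalledStepError",
    "newton_step",
    "sparsify_by_svd",
    "solve_lasso_regression",
    "solve_penalized_precision",
]


class StalledStepError(RuntimeError):
    """Raised when backtracking cannot find a decreasing step."""


@dataclass
class OptimizerState:
    """Parameter vector plus the pieces a damped Newton iteration needs.

    ``pinnable`` marks the penalized coordinates eligible for zero-pinning;
    ``pinned`` is the (monotone non-decreasing) set currently fixed at zero.
    ``jacobian`` — the residual Jacobian, or a surrogate whose column norms
    scale the zeroing threshold — may be an explicit matrix, or replaced by
    precomputed ``(sigma_max, col_norms)`` when forming it is wasteful.
    """

    theta: np.ndarray
    objective_value: float = np.nan
    alpha: float = 1.0
    n_step: int = 0
    pinnable: np.ndarray | None = None
    pinned: np.ndarray | None = None
    jacobian: np.ndarray | None = None
    sigma_max: float | None = None
    col_norms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).copy()
        n = self.theta.size
        if self.pinnable is None:
            self.pinnable = np.ones(n, dtype=bool)
        if self.pinned is None:
            self.pinned = np.zeros(n, dtype=bool)
        if not 0 < self.alpha <= 1:
            raise ValueError(f"step alpha must lie in (0, 1], got {self.alpha}")


@dataclass
class GaussNewtonObjective:
    """Least-squares objective ``0.5 * ||e(theta)||^2`` from residual/Jacobian.

    The gradient is ``J(theta)' e(theta)`` and the (Gauss-Newton) Hessian
    ``J(theta)' J(theta)``, matching the damped-Newton search direction
    ``s = -alpha * H^-1 J' e``.
    """

    residual: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]

    def value(self, theta: np.ndarray) -> float:
        e = self.residual(theta)
        return 0.5 * float(e @ e)

    def gradient(self, theta: np.ndarray) -> np.ndarray:
        return self.jacobian(theta).T @ self.residual(theta)

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        j = self.jacobian(theta)
        return j.T @ j


@dataclass
class QuadraticObjective:
    """``||theta - target||^2`` — one exact Newton step reaches the optimum."""

    target: np.ndarray

    def value(self, theta: np.ndarray) -> float:
        d = theta - self.target
        return float(d @ d)

    def gradient(self, theta: np.ndarray) -> np.ndarray:
        return 2.0 * (theta - self.target)

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        return 2.0 * np.eye(self.target.size)


def newton_step(
    state: OptimizerState,
    objective,
    max_halvings: int = 30,
    ridge: float = 1e-8,
) -> OptimizerState:
    """One damped Newton step ``s = -alpha H^-1 g`` with backtracking.

    ``objective`` must expose ``value``, ``gradient`` and ``hessian``
    callables.  The step is projected onto the non-pinned coordinates; alpha
    starts at 1 and is halved until the objective decreases (simple-decrease
    rule).  A singular Hessian is regularized with a small ridge; if no
    decrease is found after ``max_halvings`` halvings a
    :class:`StalledStepError` is raised.
    """
    theta = state.theta
    g = np.asarray(objective.gradient(theta), dtype=float)
    h = np.asarray(objective.hessian(theta), dtype=float)
    free = ~state.pinned
    gf = g[free]
    hf = h[np.ix_(free, free)]
    if np.linalg.norm(gf) == 0.0:  # stationary point: zero step
        return replace(
            state, objective_value=objective.value(theta), n_step=state.n_step + 1
        )
    try:
        direction = -np.linalg.solve(hf, gf)
    except np.linalg.LinAlgError:
        direction = -np.linalg.solve(hf + ridge * np.eye(hf.shape[0]), gf)
    if direction @ gf > 0:  # not a descent direction: fall back to gradient
        direction = -gf
    f0 = objective.value(theta)
    alpha = 1.0
    for _ in range(max_halvings + 1):
        cand = theta.copy()
        cand[free] = theta[free] + alpha * direction
        cand[state.pinned] = 0.0
        if objective.value(cand) < f0:
            return replace(
                state,
                theta=cand,
                objective_value=objective.value(cand),
                alpha=alpha,
                n_step=state.n_step + 1,
            )
        alpha /= 2.0
    raise StalledStepError(
        f"no objective decrease after {max_halvings} step halvings"
    )


def sparsify_by_svd(state: OptimizerState, tau: float) -> OptimizerState:
    """Pin near-zero penalized parameters to exactly zero.

    Coordinate ``j`` is pinned when ``|theta_j| <= tau * sigma_max * c_j``,
    where ``sigma_max`` is the largest singular value of the Jacobian and
    ``c_j = ||J[:, j]|| / max_k ||J[:, k]||`` its normalized column norm
    (from ``state.jacobian``, or the precomputed ``sigma_max``/``col_norms``
    fields).  Already-pinned coordinates stay pinned, so the pinned set is
    monotone non-decreasing over a fit.  Large ``tau`` can distort the fit
    by excluding valid search directions — a caution worth heeding.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    new = replace(state, theta=state.theta.copy(), pinned=state.pinned.copy())
    if tau == 0:
        return new
    if np.isinf(tau):
        new.pinned |= new.pinnable
        new.theta[new.pinned] = 0.0
        return new
    if state.jacobian is not None:
        j = np.asarray(state.jacobian, dtype=float)
        sigma_max = float(np.linalg.svd(j, compute_uv=False)[0])
        col = np.linalg.norm(j, axis=0)
    else:
        if state.sigma_max is None or state.col_norms is None:
            raise ValueError("state needs a jacobian or (sigma_max, col_norms)")
        sigma_max = float(state.sigma_max)
        col = np.asarray(state.col_norms, dtype=float)
    cmax = col.max()
    cn = col / cmax if cmax > 0 else col
    thr = tau * sigma_max * cn
    new.pinned |= new.pinnable & (np.abs(new.theta) <= thr)
    new.theta[new.pinned] = 0.0
    return new


# ---------------------------------------------------------------------------
# Proximal inner solvers
# ---------------------------------------------------------------------------


def solve_lasso_regression(
    xtx: np.ndarray,
    xty: np.ndarray,
    yty: np.ndarray,
    t: int,
    omega: np.ndarray,
    lam_mat: np.ndarray,
    b0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Weighted-l1 multi-response regression given a fixed precision.

    Minimizes ``(1/t) tr((Y - X B) W (Y - X B)') + sum lam_mat * |B|`` over
    the coefficient matrix ``B`` by monotone ISTA with the exact Lipschitz
    constant ``(2/t) eigmax(X'X) eigmax(W)``.  Only sufficient statistics
    (``X'X``, ``X'Y``, ``Y'Y``) are needed, so the cost is independent of
    the sample count.  Rows of ``lam_mat`` equal to zero (the intercept row)
    are never thresholded.
    """
    p, q = xty.shape
    lam_mat = np.asarray(lam_mat, dtype=float)
    if lam_mat.max() == 0.0:
        # Unpenalized: the precision factors out and the exact minimizer is
        # the least-squares solution.
        try:
            return np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            return np.linalg.solve(xtx + 1e-10 * np.eye(p), xty)
    b = np.zeros((p, q)) if b0 is None else np.asarray(b0, dtype=float).copy()
    lip = (
        2.0 / t * float(np.linalg.eigvalsh(xtx).max()) * float(np.linalg.eigvalsh(omega).max())
    )
    step = 1.0 / max(lip, 1e-12)

    def smooth(bm):
        r2 = yty - xty.T @ bm - bm.T @ xty + bm.T @ xtx @ bm
        return float(np.trace(r2 @ omega)) / t

    def grad(bm):
        return 2.0 / t * (xtx @ bm - xty) @ omega

    f = smooth(b) + float((lam_mat * np.abs(b)).sum())
    for _ in range(max_iter):
        b_new = soft_threshold(b - step * grad(b), step * lam_mat)
        f_new = smooth(b_new) + float((lam_mat * np.abs(b_new)).sum())
        if f_new > f + 1e-12:
            step /= 2.0
            continue
        done = abs(f - f_new) <= tol * (abs(f) + 1e-12)
        b, f = b_new, f_new
        if done:
            break
    return b


def solve_penalized_precision(
    s: np.ndarray,
    lam_mat: np.ndarray,
    omega0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
    floor: float = 1e-10,
) -> np.ndarray:
    """Weighted graphical-lasso precision estimate by G-ISTA.

    Minimizes ``tr(S W) - log det W + sum_{k != k'} lam_mat[k,k'] |W[k,k']|``
    (diagonal unpenalized) by proximal gradient on the precision: gradient
    ``S - W^-1``, off-diagonal soft-threshold, backtracking until the
    iterate stays positive definite and the objective decreases.  The step
    is initialized at ``eigmin(W)^2``, the classical G-ISTA choice.
    """
    m = s.shape[0]
    lam = np.asarray(lam_mat, dtype=float).copy()
    np.fill_diagonal(lam, 0.0)
    if lam.max() == 0.0:
        # Unpenalized: the exact maximum-likelihood precision.
        lam_min = float(np.linalg.eigvalsh(s).min())
        if lam_min < 1e-10:
            s = s + (1e-10 - lam_min) * np.eye(m)
        w = np.linalg.inv(s)
        return (w + w.T) / 2.0
    if omega0 is None:
        w = np.linalg.inv(s + max(floor, 1e-3) * np.eye(m))
    else:
        w = np.asarray(omega0, dtype=float).copy()
    w = (w + w.T) / 2.0

    def objective(wm):
        sign, logdet = np.linalg.slogdet(wm)
        if sign <= 0:
            return np.inf
        return float(np.trace(s @ wm)) - logdet + float((lam * np.abs(wm)).sum())

    f = objective(w)
    for _ in range(max_iter):
        w_inv = np.linalg.inv(w)
        g = s - w_inv
        step = float(np.linalg.eigvalsh(w).min()) ** 2
        accepted = False
        for _bt in range(60):
            cand = soft_threshold(w - step * g, step * lam)
            cand = (cand + cand.T) / 2.0
            try:
                np.linalg.cholesky(cand)
            except np.linalg.LinAlgError:
                step /= 2.0
                continue
            f_cand = objective(cand)
            if f_cand <= f + 1e-12:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        done = abs(f - f_cand) <= tol * (abs(f) + 1e-12)
        w, f = cand, f_cand
        if done:
            break
    return _polish_precision_support(s, lam, w, objective)


def _polish_precision_support(s, lam, omega, objective, n_newton: int = 30):
    """Newton refinement on the active set of a penalized precision estimate.

    Proximal gradient identifies the support quickly but crawls to the exact
    optimum; with the zero pattern and signs frozen the remaining problem is
    smooth, so a few Newton steps on the free entries reach stationarity to
    machine precision.  The polished matrix is kept only when it preserves
    the support and decreases the exact objective.
    """
    m = s.shape[0]
    iu = np.triu_indices(m)
    active = (np.abs(omega) > 0)[iu]
    if not active.any():
        return omega
    signs = np.sign(omega)[iu]
    f0 = objective(omega)

    def unpack(v):
        full = np.zeros(iu[0].size)
        full[active] = v
        om = np.zeros((m, m))
        om[iu] = full
        return om + np.triu(om, 1).T

    def grad(om):
        w_inv = np.linalg.inv(om)
        g_full = s - w_inv + lam * np.sign(om)
        g_full = 2.0 * g_full - np.diag(np.diag(g_full))  # off-diag counted twice
        return g_full[iu][active]

    v = omega[iu][active]
    for _ in range(n_newton):
        om = unpack(v)
        try:
            np.linalg.cholesky(om)
        except np.linalg.LinAlgError:
            return omega
        g = grad(om)
        if np.abs(g).max() < 1e-12:
            break
        n = v.size
        h = np.empty((n, n))
        eps = 1e-6
        for j in range(n):
            vp = v.copy()
            vp[j] += eps
            vmn = v.copy()
            vmn[j] -= eps
            try:
                h[:, j] = (grad(unpack(vp)) - grad(unpack(vmn))) / (2 * eps)
            except np.linalg.LinAlgError:
                return omega
        h = (h + h.T) / 2.0
        try:
            step = np.linalg.solve(h + 1e-12 * np.eye(n), g)
        except np.linalg.LinAlgError:
            return omega
        v = v - step
    om = unpack(v)
    # accept only a strict improvement with identical support and signs
    if (
        np.array_equal(np.abs(om[iu]) > 0, active)
        and np.all(np.sign(om)[iu][active] == signs[active])
        and objective(om) <= f0
    ):
        try:
            np.linalg.cholesky(om)
            return om
        except np.linalg.LinAlgError:
            return omega
    return omega
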