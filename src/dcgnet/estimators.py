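"""Sparse effective/functional connectivity estimators.

All methods model a recording as a lag-1 vector autoregression

    y_t = c + G y_{t-1} + u_t,        u_t ~ N(0, S),   O = S^-1,

where the lag matrix ``G`` (entry ``[i, j]`` = influence of channel ``j`` at
``t-1`` on channel ``i`` at ``t``) encodes directed *effective* connectivity
and the off-diagonal error-precision entries of ``O`` encode undirected
contemporaneous *functional* connectivity (partial correlations).  The shared
fit criterion is the scaled Gaussian negative log-likelihood

    (1/t) tr((Y - X B) O (Y - X B)') - log det O

optionally plus l1 / group-l1 / SCAD penalties on the lag coefficients
(weight ``lambda1``) and on the precision off-diagonals (``lambda2``).

Seven method tags are available: ``var_ols`` (unpenalized reference),
``glasso`` (alternating l1), ``tscgm`` (alternating SCAD via local linear
approximation), ``tscgm_nl_l1`` / ``tscgm_nl_scad`` (joint damped-Newton
optimization of a smoothed penalized likelihood with SVD-threshold zeroing)
and ``tscgm_it_l1`` / ``tscgm_it_scad`` (proximal gradient with exact
threshold operators).  With all penalties at zero every method coincides
with the OLS fit.

Channels are mean-centered and variance-standardized before fitting (the
penalties are scale-sensitive) and estimates are mapped back to the original
scale on return; zero patterns are invariant under that diagonal rescaling.
``neg_loglik`` and ``objective_history`` are reported on the standardized
scale, i.e. the objective the optimizer actually saw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .optim import (
    OptimizerState,
    StalledStepError,
    newton_step,
    solve_lasso_regression,
    solve_penalized_precision,
    sparsify_by_svd,
)
from .penalties import PenaltySpec, scad_derivative, scad_threshold, soft_threshold
from .recording import MultichannelRecording

__all__ = [
    "METHOD_TAGS",
    "DesignPair",
    "ConnectivityEstimate",
    "SingularDesignError",
    "build_design",
    "neg_loglik",
    "fit_var_ols",
    "fit_glasso",
    "fit_tscgm",
    "fit_tscgm_nonlinear",
    "fit_tscgm_iterative",
    "fit_method",
    "select_lambda",
    "threshold_weak_links",
    "sparsity_proportion",
    "bic",
]

logger = logging.getLogger(__name__)

METHOD_TAGS = (
    "var_ols",
    "glasso",
    "tscgm",
    "tscgm_nl_l1",
    "tscgm_nl_scad",
    "tscgm_it_l1",
    "tscgm_it_scad",
)

#: Default SVD zeroing threshold for the joint Newton fits.
DEFAULT_TAU = 1e-3
#: Pseudo-Huber smoothing half-width for the Newton fits' |x| terms.
SMOOTH_EPS = 1e-5


class SingularDesignError(ValueError):
    """Raised when the lagged design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignPair:
    """Lag-aligned response/design matrices from one recording.

    ``y`` holds samples ``2..T`` (rows) per channel (columns); ``x`` holds an
    intercept column of ones followed by samples ``1..T-1``.  The regression
    ``Y = X B`` therefore has ``B`` of shape ``(m+1, m)`` with the intercept
    in row 0 and ``B[1+j, i] = G[i, j]`` (lag matrix row = target channel).
    """

    y: np.ndarray
    x: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y.shape[0] != self.x.shape[0]:
            raise ValueError("Y and X row counts differ")
        if not np.all(self.x[:, 0] == 1.0):
            raise ValueError("X column 0 must be all ones")

    @property
    def t(self) -> int:
        return self.y.shape[0]

    @property
    def m(self) -> int:
        return self.y.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.x))

    @property
    def is_rank_deficient(self) -> bool:
        return self.rank < self.x.shape[1]


def build_design(recording: MultichannelRecording) -> DesignPair:
    """One-step lag alignment: responses 2..T against [1, lagged samples]."""
    m, t = recording.n_channels, recording.t
    if t < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {t}")
    y = recording.data.T[1:]
    x = np.column_stack([np.ones(t - 1), recording.data.T[:-1]])
    return DesignPair(y=y, x=x, labels=list(recording.labels))


@dataclass
class _SuffStats:
    """Sufficient statistics; fit cost becomes independent of sample count."""

    xtx: np.ndarray
    xty: np.ndarray
    yty: np.ndarray
    t: int
    m: int

    @classmethod
    def from_design(cls, design: DesignPair) -> "_SuffStats":
        return cls(
            xtx=design.x.T @ design.x,
            xty=design.x.T @ design.y,
            yty=design.y.T @ design.y,
            t=design.t,
            m=design.m,
        )

    def residual_cov(self, b: np.ndarray, ddof: int = 0) -> np.ndarray:
        r2 = self.yty - self.xty.T @ b - b.T @ self.xty + b.T @ self.xtx @ b
        r2 = (r2 + r2.T) / 2.0
        return r2 / (self.t - ddof)

    def nll(self, b: np.ndarray, omega: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            raise ValueError("omega must be positive definite")
        return float(np.trace(self.residual_cov(b) @ omega)) - logdet


# ---------------------------------------------------------------------------
# Estimate container
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityEstimate:
    """Fitted effective (lag) and functional (precision) connectivity."""

    gamma_hat: np.ndarray
    intercept_hat: np.ndarray
    sigma_hat: np.ndarray
    omega_hat: np.ndarray
    method: str
    penalty: PenaltySpec
    labels: list[str]
    neg_loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.omega_hat = np.asarray(self.omega_hat, dtype=float)
        self.sigma_hat = np.asarray(self.sigma_hat, dtype=float)
        m = self.gamma_hat.shape[0]
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not np.allclose(self.omega_hat, self.omega_hat.T, atol=1e-8):
            raise ValueError("omega_hat must be symmetric")
        if np.linalg.eigvalsh(self.omega_hat).min() <= 0:
            raise ValueError("omega_hat must be positive definite")
        if not np.allclose(self.sigma_hat @ self.omega_hat, np.eye(m), atol=1e-6):
            raise ValueError("sigma_hat and omega_hat are not mutual inverses")

    @property
    def m(self) -> int:
        return self.gamma_hat.shape[0]

    @property
    def sparsity_gamma(self) -> float:
        """Proportion of exactly-zero lag coefficients."""
        return sparsity_proportion(self.gamma_hat)

    @property
    def sparsity_omega(self) -> float:
        """Proportion of exactly-zero off-diagonal precision entries."""
        return sparsity_proportion(self.omega_hat, exclude_diagonal=True)

    @property
    def n_nonzero_parameters(self) -> int:
        m = self.m
        nz_gamma = int(np.count_nonzero(np.abs(self.gamma_hat) > 1e-12))
        off = np.abs(self.omega_hat) > 1e-12
        np.fill_diagonal(off, False)
        return nz_gamma + m + m + int(off.sum()) // 2

    def to_dict(self) -> dict:
        return {
            "gamma_hat": self.gamma_hat.tolist(),
            "intercept_hat": np.asarray(self.intercept_hat).tolist(),
            "sigma_hat": self.sigma_hat.tolist(),
            "omega_hat": self.omega_hat.tolist(),
            "method": self.method,
            "penalty": {
                "family": self.penalty.family,
                "lambda1": self.penalty.lambda1,
                "lambda2": self.penalty.lambda2,
                "scad_a": self.penalty.scad_a,
            },
            "labels": list(self.labels),
            "neg_loglik": float(self.neg_loglik),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "sparsity_gamma": self.sparsity_gamma,
            "sparsity_omega": self.sparsity_omega,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityEstimate":
        return cls(
            gamma_hat=np.array(d["gamma_hat"], dtype=float),
            intercept_hat=np.array(d["intercept_hat"], dtype=float),
            sigma_hat=np.array(d["sigma_hat"], dtype=float),
            omega_hat=np.array(d["omega_hat"], dtype=float),
            method=d["method"],
            penalty=PenaltySpec(**d["penalty"]),
            labels=list(d["labels"]),
            neg_loglik=d.get("neg_loglik", np.nan),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
        )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def neg_loglik(
    gamma: np.ndarray,
    intercept: np.ndarray,
    omega: np.ndarray,
    design: DesignPair,
) -> float:
    """Scaled Gaussian negative log-likelihood of a VAR(1) fit.

    Returns ``(1/t) tr(R O R') - log|O|`` with residuals
    ``R = Y - X [intercept; G']``.  Raises for non-PD ``omega``.
    """
    gamma = np.asarray(gamma, dtype=float)
    omega = np.asarray(omega, dtype=float)
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("omega must be positive definite") from exc
    b = np.vstack([np.asarray(intercept, dtype=float), gamma.T])
    r = design.y - design.x @ b
    sign, logdet = np.linalg.slogdet(omega)
    return float(np.einsum("ti,ij,tj->", r, omega, r) / design.t - logdet)


# ---------------------------------------------------------------------------
# Standardization helpers
# ---------------------------------------------------------------------------


@dataclass
class _Scaling:
    mu: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, recording: MultichannelRecording) -> "_Scaling":
        mu = recording.data.mean(axis=1)
        sd = recording.data.std(axis=1)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mu=mu, sd=sd)

    def apply(self, recording: MultichannelRecording) -> MultichannelRecording:
        z = (recording.data - self.mu[:, None]) / self.sd[:, None]
        return recording.with_data(z)

    def restore(
        self, gamma: np.ndarray, intercept: np.ndarray, omega: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Map standardized-scale estimates back to the original units."""
        d = self.sd
        gamma_o = gamma * d[:, None] / d[None, :]
        intercept_o = self.mu + d * intercept - gamma_o @ self.mu
        omega_o = omega / d[:, None] / d[None, :]
        omega_o = (omega_o + omega_o.T) / 2.0
        sigma_o = np.linalg.inv(omega_o)
        sigma_o = (sigma_o + sigma_o.T) / 2.0
        return gamma_o, intercept_o, omega_o, sigma_o


def _check_full_rank(design: DesignPair) -> None:
    if not design.is_rank_deficient:
        return
    variances = design.x[:, 1:].var(axis=0)
    flat = [design.labels[i] for i in np.flatnonzero(variances < 1e-24)]
    detail = f"constant channels: {flat}" if flat else "collinear lag columns"
    raise SingularDesignError(
        f"design matrix is rank deficient (rank {design.rank} < "
        f"{design.x.shape[1]}); {detail}"
    )


def _gamma_of(b: np.ndarray) -> np.ndarray:
    return b[1:].T


def _b_of(gamma: np.ndarray, intercept: np.ndarray) -> np.ndarray:
    return np.vstack([intercept, gamma.T])


def _finish(
    stats: _SuffStats,
    b: np.ndarray,
    omega: np.ndarray,
    scaling: _Scaling,
    method: str,
    penalty: PenaltySpec,
    labels: list[str],
    n_iter: int,
    converged: bool,
    history: list[float],
) -> ConnectivityEstimate:
    nll = stats.nll(b, omega)
    gamma_s, intercept_s = _gamma_of(b), b[0]
    if float(np.abs(np.linalg.eigvals(gamma_s)).max()) > 0.98:
        logger.warning(
            "%s: estimated lag matrix has spectral radius > 0.98 "
            "(near-unit-root fit; the series may be non-stationary)",
            method,
        )
    gamma_o, intercept_o, omega_o, sigma_o = scaling.restore(
        gamma_s, intercept_s, omega
    )
    return ConnectivityEstimate(
        gamma_hat=gamma_o,
        intercept_hat=intercept_o,
        sigma_hat=sigma_o,
        omega_hat=omega_o,
        method=method,
        penalty=penalty,
        labels=labels,
        neg_loglik=nll,
        n_iter=n_iter,
        converged=converged,
        objective_history=history,
    )


def _prepare(recording: MultichannelRecording) -> tuple[_SuffStats, _Scaling, list[str]]:
    scaling = _Scaling.fit(recording)
    design = build_design(scaling.apply(recording))
    return _SuffStats.from_design(design), scaling, design.labels


def _safe_inv(s: np.ndarray, ridge: float = 1e-10) -> np.ndarray:
    m = s.shape[0]
    lam_min = float(np.linalg.eigvalsh(s).min())
    if lam_min < ridge:
        s = s + (ridge - lam_min) * np.eye(m)
    out = np.linalg.inv(s)
    return (out + out.T) / 2.0


# ---------------------------------------------------------------------------
# OLS reference
# ---------------------------------------------------------------------------


def fit_var_ols(recording: MultichannelRecording) -> ConnectivityEstimate:
    """Equation-by-equation OLS: ``B = (X'X)^-1 X'Y``, ``S = R'R/(t-m-1)``."""
    scaling = _Scaling.fit(recording)
    design = build_design(scaling.apply(recording))
    _check_full_rank(design)
    stats = _SuffStats.from_design(design)
    b = np.linalg.solve(stats.xtx, stats.xty)
    sigma = stats.residual_cov(b, ddof=stats.m + 1)
    omega = _safe_inv(sigma)
    return _finish(
        stats,
        b,
        omega,
        scaling,
        "var_ols",
        PenaltySpec("none"),
        design.labels,
        n_iter=1,
        converged=True,
        history=[stats.nll(b, omega)],
    )


# ---------------------------------------------------------------------------
# Alternating fits: glasso (l1) and tscgm (SCAD via LLA)
# ---------------------------------------------------------------------------


def _penalty_value(penalty: PenaltySpec, gamma: np.ndarray, omega: np.ndarray) -> float:
    off = omega.copy()
    np.fill_diagonal(off, 0.0)
    return penalty.value(gamma, penalty.lambda1) + penalty.value(off, penalty.lambda2)


def _weights(
    penalty: PenaltySpec, gamma: np.ndarray, omega: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry l1 weights on B (intercept row free) and on the precision."""
    if penalty.family == "scad":
        wg = scad_derivative(np.abs(gamma), penalty.lambda1, penalty.scad_a)
        wo = scad_derivative(np.abs(omega), penalty.lambda2, penalty.scad_a)
    else:
        wg = np.full((m, m), penalty.lambda1)
        wo = np.full((m, m), penalty.lambda2)
    wb = np.vstack([np.zeros(m), np.asarray(wg).T])
    wo = np.asarray(wo, dtype=float).copy()
    np.fill_diagonal(wo, 0.0)
    return wb, wo


def _fit_alternating(
    recording: MultichannelRecording,
    penalty: PenaltySpec,
    method: str,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ConnectivityEstimate:
    stats, scaling, labels = _prepare(recording)
    m = stats.m
    b = np.linalg.solve(stats.xtx + 1e-8 * np.eye(m + 1), stats.xty)
    omega = _safe_inv(stats.residual_cov(b), ridge=1e-6)

    history: list[float] = []
    f = stats.nll(b, omega) + _penalty_value(penalty, _gamma_of(b), omega)
    history.append(f)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wb, wo = _weights(penalty, _gamma_of(b), omega, m)
        # Functional (precision) half-step first, then effective (lag).
        omega = solve_penalized_precision(stats.residual_cov(b), wo, omega0=omega)
        b = solve_lasso_regression(
            stats.xtx, stats.xty, stats.yty, stats.t, omega, wb, b0=b
        )
        f_new = stats.nll(b, omega) + _penalty_value(penalty, _gamma_of(b), omega)
        history.append(f_new)
        if abs(f - f_new) <= tol * (abs(f) + 1e-12):
            converged = True
            f = f_new
            break
        f = f_new
    if not converged:
        logger.warning("%s did not converge in %d iterations", method, max_iter)
    return _finish(
        stats, b, omega, scaling, method, penalty, labels, it, converged, history
    )


def fit_glasso(
    recording: MultichannelRecording,
    penalty: PenaltySpec,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ConnectivityEstimate:
    """Alternating l1/group fit: weighted graphical lasso on the residual
    precision, (group-)l1 regression on the lag coefficients.

    Singleton coefficient groups are used, under which the group penalty
    coincides with the entrywise l1 norm.
    """
    if penalty.family not in ("l1", "group", "none"):
        raise ValueError("fit_glasso expects an l1/group penalty")
    if penalty.family == "none":
        penalty = replace(penalty, family="l1")
    return _fit_alternating(recording, penalty, "glasso", tol=tol, max_iter=max_iter)


def fit_tscgm(
    recording: MultichannelRecording,
    penalty: PenaltySpec,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ConnectivityEstimate:
    """Alternating SCAD fit (time-series chain graphical model).

    Each outer iteration first re-estimates the sparse functional precision,
    then the sparse lag matrix using the previous estimate as the initial
    value, cycling to convergence.  SCAD is handled by local linear
    approximation: the inner problems are l1 problems re-weighted by the
    SCAD derivative at the current values, so the true SCAD objective is
    non-increasing (majorize-minimize).
    """
    if penalty.family not in ("scad", "none"):
        raise ValueError("fit_tscgm expects a SCAD penalty")
    if penalty.family == "none":
        penalty = replace(penalty, family="scad")
    return _fit_alternating(recording, penalty, "tscgm", tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Joint Newton fit ("non-linear optimization")
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=64)
def _tril_idx(m: int):
    return np.tril_indices(m, -1)


def _pack(b: np.ndarray, lfac: np.ndarray, m: int) -> np.ndarray:
    il = _tril_idx(m)
    return np.concatenate([b.ravel(), np.log(np.diag(lfac)), lfac[il]])


def _unpack(theta: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    nb = (m + 1) * m
    b = theta[:nb].reshape(m + 1, m)
    lfac = np.zeros((m, m))
    np.fill_diagonal(lfac, np.exp(theta[nb : nb + m]))
    lfac[_tril_idx(m)] = theta[nb + m :]
    return b, lfac


def _pseudo_huber(x: np.ndarray, eps: float) -> np.ndarray:
    return np.sqrt(x**2 + eps**2) - eps


def _pseudo_huber_grad(x: np.ndarray, eps: float) -> np.ndarray:
    return x / np.sqrt(x**2 + eps**2)


class _JointObjective:
    """Smoothed penalized likelihood over theta = (B, Cholesky factor of O).

    The precision is parameterized as ``O = L L'`` with a log-diagonal, so
    every iterate is positive definite by construction.  |x| terms are
    smoothed with a pseudo-Huber of half-width ``eps`` so the objective is
    twice differentiable; the Hessian is a central finite difference of the
    analytic gradient.
    """

    def __init__(
        self,
        stats: _SuffStats,
        wb: np.ndarray,
        wo: np.ndarray,
        eps: float = SMOOTH_EPS,
    ) -> None:
        self.stats = stats
        self.wb = wb  # l1 weight per B entry (intercept row zero)
        self.wo = wo  # l1 weight per precision entry (diagonal zero)
        self.eps = eps
        self.m = stats.m

    def value(self, theta: np.ndarray) -> float:
        b, lfac = _unpack(theta, self.m)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            omega = lfac @ lfac.T
            sr = self.stats.residual_cov(b)
            val = float(np.trace(sr @ omega)) - 2.0 * float(np.log(np.diag(lfac)).sum())
            val += float((self.wb * _pseudo_huber(b, self.eps)).sum())
            val += float((self.wo * _pseudo_huber(omega, self.eps)).sum())
        return val if np.isfinite(val) else np.inf

    def gradient(self, theta: np.ndarray) -> np.ndarray:
        st = self.stats
        b, lfac = _unpack(theta, self.m)
        omega = lfac @ lfac.T
        sr = st.residual_cov(b)
        gb = 2.0 / st.t * (st.xtx @ b - st.xty) @ omega
        gb += self.wb * _pseudo_huber_grad(b, self.eps)
        phi = self.wo * _pseudo_huber_grad(omega, self.eps)
        gl = 2.0 * sr @ lfac + 2.0 * phi @ lfac
        gl = np.tril(gl)
        gl[np.diag_indices(self.m)] -= 2.0 / np.diag(lfac)
        # chain rule for the log-diagonal coordinates
        gdiag = np.diag(gl) * np.diag(lfac)
        return np.concatenate([gb.ravel(), gdiag, gl[_tril_idx(self.m)]])

    def hessian(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        n = theta.size
        hess = np.empty((n, n))
        for j in range(n):
            step = h * (1.0 + abs(theta[j]))
            tp = theta.copy()
            tp[j] += step
            tm = theta.copy()
            tm[j] -= step
            hess[:, j] = (self.gradient(tp) - self.gradient(tm)) / (2.0 * step)
        return (hess + hess.T) / 2.0

    # Jacobian surrogate for SVD zeroing: the residual map e = vec(R L)/sqrt(t)

    def jacobian_column_norms(self, theta: np.ndarray) -> np.ndarray:
        st = self.stats
        b, lfac = _unpack(theta, self.m)
        omega = lfac @ lfac.T
        sr = st.residual_cov(b)
        xtxd = np.diag(st.xtx) / st.t
        nb = np.sqrt(np.outer(xtxd, np.diag(omega)))  # (m+1, m) for B entries
        srd = np.sqrt(np.clip(np.diag(sr), 0.0, None))
        ndiag = srd * np.diag(lfac)  # log-diagonal coordinates
        noff = srd[_tril_idx(self.m)[0]]
        return np.concatenate([nb.ravel(), ndiag, noff])

    def jacobian_sigma_max(self, theta: np.ndarray, n_iter: int = 30) -> float:
        """Largest singular value of the residual Jacobian by power iteration
        on J'J, evaluated through sufficient statistics only."""
        st = self.stats
        b, lfac = _unpack(theta, self.m)
        omega = lfac @ lfac.T
        sr = st.residual_cov(b)
        xtr = st.xty - st.xtx @ b
        m = self.m
        il = _tril_idx(m)
        rng = np.random.default_rng(0)
        v = rng.standard_normal(theta.size)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            vb, vl = _unpack_direction(v, m, lfac)
            ab = (st.xtx @ vb @ omega - xtr @ vl @ lfac.T) / st.t
            al = (-xtr.T @ vb @ lfac) / st.t + sr @ vl
            av = _pack_direction(ab, al, m, lfac, il)
            lam = float(np.linalg.norm(av))
            if lam < 1e-30:
                return 0.0
            v = av / lam
        return float(np.sqrt(lam))


def _unpack_direction(v: np.ndarray, m: int, lfac: np.ndarray):
    nb = (m + 1) * m
    vb = v[:nb].reshape(m + 1, m)
    vl = np.zeros((m, m))
    np.fill_diagonal(vl, v[nb : nb + m] * np.diag(lfac))
    vl[_tril_idx(m)] = v[nb + m :]
    return vb, vl


def _pack_direction(ab: np.ndarray, al: np.ndarray, m: int, lfac, il):
    al = np.tril(al)
    adiag = np.diag(al) * np.diag(lfac)
    return np.concatenate([ab.ravel(), adiag, al[il]])


def fit_tscgm_nonlinear(
    recording: MultichannelRecording,
    penalty: PenaltySpec,
    tau: float = DEFAULT_TAU,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ConnectivityEstimate:
    """Joint damped-Newton fit of the penalized likelihood with SVD zeroing.

    Effective and functional connectivity are optimized *simultaneously*
    over the stacked parameter (B, Cholesky factor of the precision) by
    damped Newton steps on a pseudo-Huber-smoothed penalized likelihood.
    After each accepted step, penalized parameters whose magnitude falls
    below ``tau`` times the residual Jacobian's largest singular value
    (scaled per column) are pinned to exactly zero; the pinned set only
    grows.  SCAD is handled by outer local-linear-approximation rounds that
    re-weight the smoothed l1 term.

    Note the precision inherits sparsity only through zeros of its Cholesky
    factor, so its off-diagonal zeros are approximate; lag-matrix zeros are
    exact.
    """
    if penalty.family not in ("l1", "scad", "none"):
        raise ValueError("fit_tscgm_nonlinear expects an l1 or SCAD penalty")
    if penalty.family == "none":
        penalty = replace(penalty, family="l1")
    if tau > 0.1:
        logger.warning(
            "zeroing threshold tau=%g is large; high thresholds can change "
            "the model's behavior, low ones can bound the search space",
            tau,
        )
    method = "tscgm_nl_scad" if penalty.family == "scad" else "tscgm_nl_l1"
    stats, scaling, labels = _prepare(recording)
    m = stats.m

    b = np.linalg.solve(stats.xtx + 1e-8 * np.eye(m + 1), stats.xty)
    omega = _safe_inv(stats.residual_cov(b), ridge=1e-6)
    lfac = np.linalg.cholesky(omega)
    theta = _pack(b, lfac, m)

    nb = (m + 1) * m
    pinnable = np.zeros(theta.size, dtype=bool)
    pinnable[:nb] = np.vstack(
        [np.zeros(m, bool), np.ones((m, m), bool)]
    ).ravel()  # lag rows of B
    pinnable[nb + m :] = True  # off-diagonal Cholesky coordinates

    n_rounds = 3 if penalty.family == "scad" else 1
    state = OptimizerState(theta=theta, pinnable=pinnable)
    converged = False
    history: list[float] = []
    total_steps = 0
    for _round in range(n_rounds):
        b_cur, lfac_cur = _unpack(state.theta, m)
        wb, wo = _weights(penalty, _gamma_of(b_cur), lfac_cur @ lfac_cur.T, m)
        obj = _JointObjective(stats, wb, wo)
        f = obj.value(state.theta)
        history = [f]
        converged = False
        for _it in range(max_iter):
            try:
                state = newton_step(state, obj)
            except StalledStepError:
                g = obj.gradient(state.theta)
                g[state.pinned] = 0.0
                converged = bool(np.linalg.norm(g) <= 1e-5 * (1 + abs(f)))
                break
            total_steps += 1
            history.append(state.objective_value)
            if tau > 0:
                state.sigma_max = obj.jacobian_sigma_max(state.theta)
                state.col_norms = obj.jacobian_column_norms(state.theta)
                state = sparsify_by_svd(state, tau)
                state.objective_value = obj.value(state.theta)
            if abs(f - state.objective_value) <= tol * (abs(f) + 1e-12):
                converged = True
                f = state.objective_value
                break
            f = state.objective_value
    if not converged:
        logger.warning("%s did not converge in %d Newton steps", method, max_iter)

    b_fin, lfac_fin = _unpack(state.theta, m)
    # Re-apply exact zeros on the lag block (log-diag coords never pinned).
    b_fin = b_fin.copy()
    b_fin.ravel()[np.flatnonzero(state.pinned[:nb])] = 0.0
    omega_fin = lfac_fin @ lfac_fin.T
    omega_fin = (omega_fin + omega_fin.T) / 2.0
    return _finish(
        stats,
        b_fin,
        omega_fin,
        scaling,
        method,
        penalty,
        labels,
        total_steps,
        converged,
        history,
    )


# ---------------------------------------------------------------------------
# Proximal-gradient fit ("iterative optimization")
# ---------------------------------------------------------------------------


def fit_tscgm_iterative(
    recording: MultichannelRecording,
    penalty: PenaltySpec,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ConnectivityEstimate:
    """Proximal-gradient (iterative shrinkage) fit of the penalized likelihood.

    Both blocks take a joint gradient step on the smooth likelihood followed
    by the exact threshold operator of the penalty (soft threshold for l1,
    the three-zone SCAD threshold for SCAD) on the lag coefficients and the
    precision off-diagonals.  The step length is found by backtracking until
    the iterate is positive definite and the penalized objective decreases;
    if no positive-definite iterate is found the precision is repaired by
    eigenvalue flooring (logged).
    """
    if penalty.family not in ("l1", "scad", "none"):
        raise ValueError("fit_tscgm_iterative expects an l1 or SCAD penalty")
    if penalty.family == "none":
        penalty = replace(penalty, family="l1")
    method = "tscgm_it_scad" if penalty.family == "scad" else "tscgm_it_l1"
    stats, scaling, labels = _prepare(recording)
    m = stats.m
    lam1, lam2, a = penalty.lambda1, penalty.lambda2, penalty.scad_a

    def prox_b(z: np.ndarray, step: float) -> np.ndarray:
        out = z.copy()
        if lam1 > 0:
            if penalty.family == "scad":
                out[1:] = scad_threshold(z[1:], lam1, a, step)
            else:
                out[1:] = soft_threshold(z[1:], step * lam1)
        return out

    def prox_omega(z: np.ndarray, step: float) -> np.ndarray:
        z = (z + z.T) / 2.0
        if lam2 <= 0:
            return z
        if penalty.family == "scad":
            shrunk = scad_threshold(z, lam2, a, step)
        else:
            shrunk = soft_threshold(z, step * lam2)
        out = np.asarray(shrunk, dtype=float)
        np.fill_diagonal(out, np.diag(z))
        return out

    def objective(bm: np.ndarray, om: np.ndarray) -> float:
        return stats.nll(bm, om) + _penalty_value(penalty, _gamma_of(bm), om)

    b = np.linalg.solve(stats.xtx + 1e-8 * np.eye(m + 1), stats.xty)
    omega = _safe_inv(stats.residual_cov(b), ridge=1e-6)
    f = objective(b, omega)
    history = [f]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gb = 2.0 / stats.t * (stats.xtx @ b - stats.xty) @ omega
        gom = stats.residual_cov(b) - _safe_inv(omega)
        accepted = False
        step = min(step * 2.0, 1.0)
        for _bt in range(40):
            b_new = prox_b(b - step * gb, step)
            om_new = prox_omega(omega - step * gom, step)
            try:
                np.linalg.cholesky(om_new)
            except np.linalg.LinAlgError:
                step /= 2.0
                continue
            f_new = objective(b_new, om_new)
            if f_new <= f + 1e-12:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            # Last resort: eigenvalue-floor the precision and stop.
            w, v = np.linalg.eigh(omega)
            if w.min() < 1e-8:
                logger.warning("%s: repairing precision by eigenvalue flooring", method)
                omega = v @ np.diag(np.maximum(w, 1e-8)) @ v.T
            converged = abs(history[-1] - f) <= tol * (abs(f) + 1e-12)
            break
        history.append(f_new)
        if abs(f - f_new) <= tol * (abs(f) + 1e-12):
            b, omega, f = b_new, om_new, f_new
            converged = True
            break
        b, omega, f = b_new, om_new, f_new
    if not converged:
        logger.warning("%s did not converge in %d iterations", method, max_iter)
    return _finish(
        stats, b, omega, scaling, method, penalty, labels, it, converged, history
    )


# ---------------------------------------------------------------------------
# Dispatch, model selection, post-processing
# ---------------------------------------------------------------------------


def fit_method(
    recording: MultichannelRecording,
    method: str,
    penalty: PenaltySpec | None = None,
    **kwargs,
) -> ConnectivityEstimate:
    """Fit one of the seven methods by tag."""
    if method not in METHOD_TAGS:
        raise ValueError(f"unknown method tag {method!r}; use one of {METHOD_TAGS}")
    if method == "var_ols":
        return fit_var_ols(recording)
    if penalty is None:
        raise ValueError(f"method {method!r} needs a PenaltySpec")
    if method == "glasso":
        if penalty.family not in ("l1", "group"):
            penalty = replace(penalty, family="l1")
        return fit_glasso(recording, penalty, **kwargs)
    if method == "tscgm":
        if penalty.family != "scad":
            penalty = replace(penalty, family="scad")
        return fit_tscgm(recording, penalty, **kwargs)
    family = "scad" if method.endswith("_scad") else "l1"
    penalty = replace(penalty, family=family)
    if method.startswith("tscgm_nl"):
        return fit_tscgm_nonlinear(recording, penalty, **kwargs)
    return fit_tscgm_iterative(recording, penalty, **kwargs)


def bic(estimate: ConnectivityEstimate, t: int) -> float:
    """Bayesian information criterion: ``t * nll + log(t) * #nonzero``."""
    return float(t * estimate.neg_loglik + np.log(t) * estimate.n_nonzero_parameters)


def select_lambda(
    recording: MultichannelRecording,
    method: str,
    grid: list[PenaltySpec],
    return_estimate: bool = False,
    **kwargs,
):
    """Pick the penalty from ``grid`` minimizing the BIC of its fit.

    Ties break toward the sparser model, then toward smaller ``lambda1``.
    Raises if every fit in the grid fails.
    """
    if not grid:
        raise ValueError("penalty grid must be non-empty")
    t = recording.t - 1
    best = None
    failures: list[str] = []
    for spec in grid:
        try:
            est = fit_method(recording, method, spec, **kwargs)
        except (np.linalg.LinAlgError, ValueError) as exc:
            failures.append(f"{spec}: {exc}")
            continue
        key = (
            bic(est, t),
            -(est.sparsity_gamma + est.sparsity_omega),
            spec.lambda1,
        )
        if best is None or key < best[0]:
            best = (key, spec, est)
    if best is None:
        raise RuntimeError(f"all fits in the penalty grid failed: {failures}")
    _, spec, est = best
    return (spec, est) if return_estimate else spec


def threshold_weak_links(
    estimate: ConnectivityEstimate, q: float = 0.5
) -> ConnectivityEstimate:
    """Remove weak links: entries below the q-quantile of nonzero magnitudes.

    Lag-matrix entries (and precision off-diagonals, each with its own
    quantile) whose magnitude is *strictly below* the quantile of the
    nonzero magnitudes are set to exactly zero; the covariance is recomputed
    from the thresholded precision.  ``q = 0`` leaves the estimate unchanged.
    """
    if not 0 <= q < 1:
        raise ValueError(f"quantile q must lie in [0, 1), got {q}")
    if q == 0:
        return estimate
    gamma = estimate.gamma_hat.copy()
    nz = np.abs(gamma[np.abs(gamma) > 1e-12])
    if nz.size:
        cut = np.quantile(nz, q)
        gamma[np.abs(gamma) < cut] = 0.0
    omega = estimate.omega_hat.copy()
    offmask = ~np.eye(omega.shape[0], dtype=bool)
    nz = np.abs(omega[offmask & (np.abs(omega) > 1e-12)])
    if nz.size:
        cut = np.quantile(nz, q)
        omega[offmask & (np.abs(omega) < cut)] = 0.0
    w = np.linalg.eigvalsh(omega)
    if w.min() <= 1e-10:
        ww, v = np.linalg.eigh(omega)
        omega = v @ np.diag(np.maximum(ww, 1e-8)) @ v.T
    sigma = np.linalg.inv(omega)
    return replace(
        estimate,
        gamma_hat=gamma,
        omega_hat=(omega + omega.T) / 2.0,
        sigma_hat=(sigma + sigma.T) / 2.0,
    )


def sparsity_proportion(
    matrix: np.ndarray, zero_tol: float = 1e-12, exclude_diagonal: bool = False
) -> float:
    """Fraction of entries equal to zero (within ``zero_tol``).

    With ``exclude_diagonal`` (used for precision matrices, whose diagonal
    is never a link) only off-diagonal entries are counted.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("matrix must be non-empty")
    if exclude_diagonal:
        mask = ~np.eye(matrix.shape[0], dtype=bool)
        vals = matrix[mask]
    else:
        vals = matrix.ravel()
    if vals.size == 0:
        return 0.0
    return float((np.abs(vals) <= zero_tol).sum() / vals.size)
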