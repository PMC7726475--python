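"""Ground-truth generators for benchmarking connectivity estimators.

The study protocol this emulates records two periods of resting multichannel
EEG (a baseline and a post-stimulation accommodation period), 5 minutes each
at 500 Hz, from a small subset of channels (7 of a dense montage).  The raw
data are not publicly deposited, so every downstream stage is exercised
against synthetic recordings drawn from a *known* sparse dynamic model:

* a stationary sparse VAR(1) background ``y_t = c + G y_{t-1} + u_t`` with
  sparse error precision ``O = S^-1`` — the lag matrix ``G`` is the
  ground-truth effective connectivity, the precision off-diagonals the
  ground-truth functional connectivity;
* additive band-limited sinusoidal components, one per canonical waveband,
  whose amplitudes differ by condition (the post-stimulation period raises
  the gamma- and theta-band amplitudes and injects *shared* oscillators into
  selected channel pairs, creating band-specific contemporaneous coupling).

All randomness flows from explicit integer seeds; identical inputs produce
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import MultichannelRecording

__all__ = [
    "GroundTruthModel",
    "ProtocolConfig",
    "NonStationaryModelError",
    "make_sparse_model",
    "simulate_var1",
    "simulate_protocol",
    "BAND_CENTER_HZ",
]

#: Representative oscillation frequency (Hz) used for each waveband's
#: synthetic sinusoidal component (roughly the band midpoints of the
#: 0.01-4 / 4-8 / 8-16 / 16-32 / 32-49 Hz table used by ``dcgnet.bands``).
BAND_CENTER_HZ: dict[str, float] = {
    "theta": 2.0,
    "delta": 6.0,
    "alpha": 12.0,
    "beta": 24.0,
    "gamma": 40.0,
}


class NonStationaryModelError(ValueError):
    """Raised when a VAR(1) lag matrix has spectral radius >= 1."""


@dataclass
class GroundTruthModel:
    """Known sparse VAR(1) model: effective matrix, intercept and error law.

    ``gamma[i, j]`` is the influence of channel ``j`` at time ``t-1`` on
    channel ``i`` at time ``t``.  ``omega`` is the error precision (inverse
    of the error covariance ``sigma``); its off-diagonal support is the
    ground-truth functional connectivity.
    """

    gamma: np.ndarray
    intercept: np.ndarray
    omega: np.ndarray
    sigma: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = self.gamma.shape[0]
        if self.gamma.shape != (m, m) or self.omega.shape != (m, m):
            raise ValueError("gamma and omega must be square and conformable")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if np.linalg.eigvalsh(self.omega).min() <= 0:
            raise ValueError("omega must be positive definite")
        if not np.allclose(self.sigma @ self.omega, np.eye(m), atol=1e-8):
            raise ValueError("sigma must invert omega (tolerance 1e-8)")
        if self.spectral_radius >= 1.0:
            raise NonStationaryModelError(
                f"spectral radius {self.spectral_radius:.4f} >= 1"
            )

    @property
    def m(self) -> int:
        return self.gamma.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.gamma)).max())

    @property
    def support_gamma(self) -> np.ndarray:
        """Boolean mask of nonzero lag coefficients."""
        return self.gamma != 0.0

    @property
    def support_omega(self) -> np.ndarray:
        """Boolean mask of nonzero off-diagonal precision entries."""
        mask = self.omega != 0.0
        np.fill_diagonal(mask, False)
        return mask

    def stationary_covariance(self, n_iter: int = 10_000, tol: float = 1e-14) -> np.ndarray:
        """Lag-0 covariance ``S`` solving ``S = G S G' + sigma`` (fixed point)."""
        s = self.sigma.copy()
        for _ in range(n_iter):
            s_new = self.gamma @ s @ self.gamma.T + self.sigma
            if np.abs(s_new - s).max() < tol:
                return s_new
            s = s_new
        return s

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma.tolist(),
            "intercept": self.intercept.tolist(),
            "omega": self.omega.tolist(),
            "sigma": self.sigma.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthModel":
        return cls(
            gamma=np.array(d["gamma"], dtype=float),
            intercept=np.array(d["intercept"], dtype=float),
            omega=np.array(d["omega"], dtype=float),
            sigma=np.array(d["sigma"], dtype=float),
            labels=list(d["labels"]),
        )


def _default_amplitudes() -> dict[str, dict[str, float]]:
    # Post-stimulation raises gamma- and theta-band oscillation amplitudes,
    # emulating the band-specific change observed after stimulation.
    return {
        "baseline": {"theta": 1.0, "delta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
        "post_stim": {"theta": 2.0, "delta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 2.0},
    }


def _default_couplings() -> dict[str, dict[str, list[tuple[int, int]]]]:
    # Shared oscillators injected into channel pairs create contemporaneous
    # coupling confined to one band; only the post-stimulation period has them.
    return {
        "baseline": {},
        "post_stim": {"gamma": [(0, 1), (2, 3)], "theta": [(0, 2)]},
    }


@dataclass
class ProtocolConfig:
    """Settings for the two-period recording protocol emulation.

    Defaults reproduce the study conditions: 7 channels, 500 Hz, two 5-minute
    periods (baseline, post-stimulation), for 300,000 samples in total.
    ``band_amplitudes[condition][band]`` scales the per-channel sinusoidal
    component of that band; ``couplings[condition][band]`` lists channel
    pairs that share one oscillator (contemporaneous band-specific coupling).
    """

    n_channels: int = 7
    fs: float = 500.0
    period_minutes: float = 5.0
    conditions: list[str] = field(default_factory=lambda: ["baseline", "post_stim"])
    band_amplitudes: dict[str, dict[str, float]] = field(default_factory=_default_amplitudes)
    couplings: dict[str, dict[str, list[tuple[int, int]]]] = field(
        default_factory=_default_couplings
    )
    edge_density: float = 0.15
    magnitude_range: tuple[float, float] = (0.2, 0.45)
    noise_scale: float = 1.0
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.fs <= 0 or self.period_minutes <= 0:
            raise ValueError("fs and period_minutes must be positive")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in [0, 1]")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")

    @property
    def samples_per_period(self) -> int:
        return int(round(self.period_minutes * 60.0 * self.fs))


def make_sparse_model(
    m: int,
    density: float,
    magnitude_range: tuple[float, float] = (0.2, 0.45),
    seed: int = 0,
    labels: list[str] | None = None,
) -> GroundTruthModel:
    """Draw a stationary sparse VAR(1) model with sparse error precision.

    ``ceil(density * m * (m-1))`` off-diagonal lag coefficients are placed
    uniformly at random with magnitudes in ``magnitude_range`` and random
    sign; the diagonal is drawn in [0.2, 0.6] for realistic within-channel
    autocorrelation.  If the spectral radius reaches 0.95 the lag matrix is
    rescaled to radius 0.9.  The precision is ``I`` plus a sparse symmetric
    perturbation; positive definiteness is enforced by shrinking the
    perturbation (which preserves the declared support) until the smallest
    eigenvalue is at least 0.05.
    """
    if m < 2:
        raise ValueError(f"need at least 2 channels, got {m}")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    lo, hi = magnitude_range
    if not 0 <= lo <= hi:
        raise ValueError(f"invalid magnitude_range {magnitude_range}")
    rng = np.random.default_rng(seed)

    gamma = np.zeros((m, m))
    gamma[np.diag_indices(m)] = rng.uniform(0.2, 0.6, size=m)
    off = [(i, j) for i in range(m) for j in range(m) if i != j]
    k = int(np.ceil(density * m * (m - 1)))
    if k > 0:
        chosen = rng.choice(len(off), size=k, replace=False)
        for idx in chosen:
            i, j = off[idx]
            gamma[i, j] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    rho = float(np.abs(np.linalg.eigvals(gamma)).max())
    if rho >= 0.95:
        gamma *= 0.9 / rho

    # Precision: identity + sparse symmetric perturbation, support-preserving
    # shrinkage to keep the smallest eigenvalue >= 0.05.
    pert = np.zeros((m, m))
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    kp = int(np.ceil(density * len(pairs)))
    if kp > 0:
        chosen = rng.choice(len(pairs), size=kp, replace=False)
        for idx in chosen:
            i, j = pairs[idx]
            v = rng.uniform(0.2, 0.5) * rng.choice([-1.0, 1.0])
            pert[i, j] = pert[j, i] = v
    omega = np.eye(m) + pert
    lam_min = float(np.linalg.eigvalsh(omega).min())
    if lam_min < 0.05:
        # 1 + c * lam_min(pert) = 0.05  =>  c = 0.95 / (-lam_min(pert))
        c = 0.95 / (1.0 - lam_min)
        omega = np.eye(m) + c * pert
    sigma = np.linalg.inv(omega)
    sigma = (sigma + sigma.T) / 2.0

    if labels is None:
        labels = [f"ch{i}" for i in range(m)]
    return GroundTruthModel(
        gamma=gamma,
        intercept=np.zeros(m),
        omega=omega,
        sigma=sigma,
        labels=labels,
    )


def simulate_var1(
    model: GroundTruthModel,
    t: int,
    burn_in: int = 500,
    seed: int = 0,
    condition: str = "",
    fs: float = 500.0,
) -> MultichannelRecording:
    """Simulate ``y_t = c + G y_{t-1} + u_t``, ``u_t ~ N(0, sigma)``.

    The chain starts at its stationary mean and the first ``burn_in`` samples
    are discarded.  Raises :class:`NonStationaryModelError` if the lag matrix
    has spectral radius >= 1 (the recursion would diverge).
    """
    m = model.m
    if t < m + 2:
        raise ValueError(f"need t >= m+2={m + 2}, got {t}")
    rho = model.spectral_radius
    if rho >= 1.0:
        raise NonStationaryModelError(f"spectral radius {rho:.4f} >= 1")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.sigma)
    n = t + burn_in
    u = rng.standard_normal((n, m)) @ chol.T
    y = np.empty((n, m))
    prev = np.linalg.solve(np.eye(m) - model.gamma, model.intercept)
    g, c = model.gamma, model.intercept
    for k in range(n):
        prev = c + g @ prev + u[k]
        y[k] = prev
    return MultichannelRecording(
        data=y[burn_in:].T, fs=fs, labels=list(model.labels), condition=condition
    )


def _oscillations(
    m: int,
    t: int,
    fs: float,
    amplitudes: dict[str, float],
    couplings: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited sinusoidal components: independent per channel, plus
    shared oscillators for coupled channel pairs."""
    time = np.arange(t) / fs
    out = np.zeros((m, t))
    for band, f0 in BAND_CENTER_HZ.items():
        amp = amplitudes.get(band, 0.0)
        # Per-channel independent oscillators (random phase, 2% freq jitter);
        # drawn even when amp == 0 to keep the RNG stream aligned across
        # conditions that differ only in amplitude tables.
        freq = f0 * (1.0 + 0.02 * rng.uniform(-1.0, 1.0, size=m))
        phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
        if amp != 0.0:
            out += amp * np.sin(2.0 * np.pi * freq[:, None] * time[None, :] + phase[:, None])
        for (i, j) in couplings.get(band, []):
            fshared = f0 * (1.0 + 0.02 * rng.uniform(-1.0, 1.0))
            pshared = rng.uniform(0.0, 2.0 * np.pi)
            shared = max(amp, 1.0) * np.sin(2.0 * np.pi * fshared * time + pshared)
            out[i] += shared
            out[j] += shared
    return out


def simulate_protocol(
    config: ProtocolConfig | None = None,
) -> tuple[list[MultichannelRecording], GroundTruthModel]:
    """Simulate one recording per condition from a single ground-truth model.

    Each period is a VAR(1) background plus additive sinusoidal components
    centred in the five wavebands; conditions share the same model *and* the
    same noise realization (a paired design), so they differ only through
    their amplitude tables and coupled-pair oscillators.  With all amplitudes
    zero and no couplings the output equals :func:`simulate_var1` at the
    config seed exactly.
    """
    if config is None:
        config = ProtocolConfig()
    model = make_sparse_model(
        config.n_channels,
        config.edge_density,
        config.magnitude_range,
        seed=config.seed,
    )
    if config.noise_scale != 1.0:
        s2 = config.noise_scale**2
        model = GroundTruthModel(
            gamma=model.gamma,
            intercept=model.intercept,
            omega=model.omega / s2,
            sigma=model.sigma * s2,
            labels=model.labels,
        )
    t = config.samples_per_period
    recordings = []
    for cond in config.conditions:
        rec = simulate_var1(
            model,
            t,
            burn_in=config.burn_in,
            seed=config.seed,
            condition=cond,
            fs=config.fs,
        )
        amps = config.band_amplitudes.get(cond, {})
        coup = config.couplings.get(cond, {})
        if any(a != 0.0 for a in amps.values()) or any(coup.values()):
            osc_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
            rec = rec.with_data(
                rec.data + _oscillations(config.n_channels, t, config.fs, amps, coup, osc_rng)
            )
        recordings.append(rec)
    return recordings, model
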