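"""Penalty families for sparse connectivity estimation.

Two sparsity-inducing penalties are supported on the lag coefficients and on
the off-diagonal precision entries:

* the l1 norm (``lambda * |x|``; with singleton groups the group penalty of
  the group-lasso formulation reduces to this), and
* SCAD (smoothly clipped absolute deviation), the Fan-Li three-piece
  penalty that is linear near zero, blends quadratically, and is constant
  beyond ``a * lambda`` — shrinking weak coefficients like the l1 norm while
  leaving strong ones nearly unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PenaltySpec",
    "scad",
    "scad_derivative",
    "soft_threshold",
    "scad_threshold",
]

_FAMILIES = ("none", "l1", "group", "scad")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family plus its tuning constants.

    ``lambda1`` penalizes lag (effective-connectivity) coefficients,
    ``lambda2`` off-diagonal precision (functional-connectivity) entries.
    ``scad_a`` is the SCAD shape constant (must exceed 2; 3.7 is the
    conventional default).
    """

    family: str = "none"
    lambda1: float = 0.0
    lambda2: float = 0.0
    scad_a: float = 3.7

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}; use one of {_FAMILIES}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty parameters must be non-negative")
        if self.family == "scad" and not self.scad_a > 2:
            raise ValueError(f"SCAD shape a must exceed 2, got {self.scad_a}")

    def value(self, theta: np.ndarray, lam: float) -> float:
        """Total penalty on the entries of ``theta`` at level ``lam``."""
        theta = np.asarray(theta, dtype=float)
        if self.family == "none" or lam == 0.0:
            return 0.0
        if self.family in ("l1", "group"):
            return float(lam * np.abs(theta).sum())
        return float(scad(theta, lam, self.scad_a).sum())


def scad(theta, lam: float, a: float = 3.7):
    """Fan-Li SCAD penalty, elementwise.

    ``lam*|x|`` for ``|x| <= lam``; a quadratic blend on ``(lam, a*lam]``;
    the constant ``lam^2 (a+1)/2`` beyond.  Continuous, with continuous
    derivative everywhere except the origin.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if not a > 2:
        raise ValueError(f"SCAD shape a must exceed 2, got {a}")
    x = np.abs(np.asarray(theta, dtype=float))
    out = np.where(
        x <= lam,
        lam * x,
        np.where(
            x <= a * lam,
            (2 * a * lam * x - x**2 - lam**2) / (2 * (a - 1)),
            lam**2 * (a + 1) / 2.0,
        ),
    )
    return out if out.ndim else float(out)


def scad_derivative(theta, lam: float, a: float = 3.7):
    """d scad(|x|)/d|x|: ``lam`` on [0, lam], decaying linearly to 0 at a*lam.

    This is the weight used by the local linear approximation (LLA): one
    outer iteration replaces the SCAD penalty by a weighted l1 penalty with
    per-entry weight ``scad_derivative(|current value|)``.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if not a > 2:
        raise ValueError(f"SCAD shape a must exceed 2, got {a}")
    x = np.abs(np.asarray(theta, dtype=float))
    out = np.where(x <= lam, lam, np.maximum(a * lam - x, 0.0) / (a - 1))
    return out if out.ndim else float(out)


def soft_threshold(z, thr):
    """Elementwise soft threshold: the proximal operator of ``thr * |x|``."""
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
    return out if out.ndim else float(out)


def scad_threshold(z, lam: float, a: float = 3.7, step: float = 1.0):
    """Proximal operator of ``step * scad(x; lam, a)``, elementwise.

    Solves ``argmin_x (x-z)^2 / (2*step) + scad(x)`` by evaluating the
    stationary candidates of the three SCAD pieces (plus zero) and keeping
    the minimizer; for ``step = 1`` this reduces to the classical
    soft-threshold / linear-blend / identity three-zone rule.
    """
    if not a > 2:
        raise ValueError(f"SCAD shape a must exceed 2, got {a}")
    z = np.asarray(z, dtype=float)
    zf = np.atleast_1d(z).ravel()
    cands = np.stack(
        [
            np.zeros_like(zf),
            # piece 1: lam*|x| on [0, lam]
            np.clip(np.abs(soft_threshold(zf, step * lam)), 0.0, lam) * np.sign(zf),
            # piece 2: quadratic blend on (lam, a*lam]
            _clip_signed(
                (zf * (a - 1) - np.sign(zf) * step * a * lam) / (a - 1 - step)
                if a - 1 != step
                else np.sign(zf) * a * lam,
                lam,
                a * lam,
            ),
            # piece 3: constant beyond a*lam
            _clip_signed(zf, a * lam, np.inf),
        ]
    )
    obj = (cands - zf) ** 2 / (2.0 * step) + scad(cands, lam, a)
    best = cands[np.argmin(obj, axis=0), np.arange(zf.size)]
    if np.ndim(z) == 0:
        return float(best[0])
    return best.reshape(z.shape)


def _clip_signed(x, lo, hi):
    """Clip |x| into [lo, hi] keeping the sign."""
    return np.sign(x) * np.clip(np.abs(x), lo, hi)
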