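"""Crystallite-orientation (powder) sampling schemes.

For interactions without a gamma dependence beyond the rotor phase, a powder
average over the hemisphere in (alpha, beta) is sufficient; the rotor phase
itself is kept fixed (stroboscopic detection over whole rotor periods).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PowderScheme", "zcw_scheme", "repulsion_scheme", "single_orientation"]

_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class PowderScheme:
    """Weighted set of (alpha, beta) crystallite orientations, angles in rad."""

    alpha: np.ndarray
    beta: np.ndarray
    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        a = np.asarray(self.alpha, float)
        b = np.asarray(self.beta, float)
        w = np.asarray(self.weights, float)
        if not (a.shape == b.shape == w.shape) or a.ndim != 1:
            raise ValueError("alpha, beta, weights must be 1-D arrays of equal length")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        if np.any(b < 0) or np.any(b > math.pi):
            raise ValueError("beta must lie in [0, pi]")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.alpha.size


def single_orientation(alpha: float = 0.0, beta: float = 0.0) -> PowderScheme:
    return PowderScheme(np.array([alpha]), np.array([beta]), np.array([1.0]), "single")


_ZCW_G = [8, 13, 21, 34, 55, 89, 144, 233, 377, 610, 987, 1597, 2584]


def zcw_scheme(n_min: int = 100) -> PowderScheme:
    """Low-discrepancy ZCW-style hemisphere set with at least ``n_min`` points."""
    g = _ZCW_G
    m = 0
    while m + 2 < len(g) and g[m + 2] < n_min:
        m += 1
    n = g[m + 2]
    j = np.arange(n)
    frac = np.mod(j / n, 1.0)
    beta = np.arccos(1.0 - frac)  # cos(beta) uniform on (0, 1]
    alpha = 2.0 * math.pi * np.mod(j * g[m] / n, 1.0)
    w = np.full(n, 1.0 / n)
    return PowderScheme(alpha, beta, w, f"zcw-{n}")


def repulsion_scheme(n: int = 100, n_iter: int = 60) -> PowderScheme:
    """REPULSION-style hemisphere set: golden-spiral start, electrostatic
    relaxation on the full sphere with antipodal symmetry, folded back to the
    upper hemisphere.  Fully deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    j = np.arange(n) + 0.5
    z = j / n  # upper hemisphere
    phi = 2.0 * math.pi * np.mod(j / _GOLDEN, 1.0)
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pts = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    # antipodal partner set enforces inversion symmetry during relaxation
    for _ in range(n_iter):
        full = np.vstack([pts, -pts])
        diff = pts[:, None, :] - full[None, :, :]
        d2 = np.sum(diff**2, axis=2)
        np.fill_diagonal(d2[:, :n], np.inf)
        force = np.sum(diff / (d2[..., None] ** 1.5 + 1e-12), axis=1)
        pts = pts + 2e-3 * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts[pts[:, 2] < 0] *= -1.0
    beta = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
    alpha = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * math.pi)
    w = np.full(n, 1.0 / n)
    return PowderScheme(alpha, beta, w, f"repulsion-{n}")
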