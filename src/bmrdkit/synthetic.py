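"""Synthetic fixtures: every input the processing/fitting modules consume.

Ground-truth dispersion profiles are fast-exchange curves plus Gaussian
bumps; one-point intensity scans and anchor decay curves follow the forward
model of the one-point method (tilted-frame rates, sin^2-theta projection,
exponential prefactor, additive Gaussian spectral noise); toy structures are
minimal PDB files with explicit protons at controlled distances together
with a 1H shift table.  Identical seeds give identical outputs.

Defaults mirror the regimes of interest: 64-point nu1 grids over
0.5-17 kHz, k_ex/2pi near 1800 s^-1, bump widths 100-300 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import TWO_PI
from .processing import DecayCurve, DispersionProfile, OnePointSeries, tilt_angle_deg

__all__ = [
    "GroundTruth",
    "default_nu1_grid",
    "gen_profile",
    "gen_one_point",
    "gen_toy_structure",
]


@dataclass
class GroundTruth:
    """Per-site generating parameters for synthetic dispersion data."""

    site: str
    k_ex: float = TWO_PI * 1800.0  # rad/s
    phi_ex: float = 0.0  # (rad/s)^2
    r1rho0: float = 8.0  # s^-1
    bumps: list[tuple[float, float, float]] = field(default_factory=list)  # (center Hz, width Hz, height s^-1)
    carrier_hz: float = 0.0
    site_freq_hz: float = 0.0
    r1_s: float = 0.05
    noise_sigma: float = 0.01  # on unit-scale intensities
    prefactor: float = 0.9  # I(0) of the decay, gives the offset term
    seed: int = 0

    def __post_init__(self):
        if self.k_ex <= 0 or self.phi_ex < 0 or self.r1rho0 < 0 or self.r1_s < 0:
            raise ValueError("rates must be non-negative (k_ex positive)")

    def r1rho(self, nu1_hz: np.ndarray) -> np.ndarray:
        nu1 = np.asarray(nu1_hz, float)
        r = self.phi_ex * self.k_ex / (self.k_ex**2 + (TWO_PI * nu1) ** 2) + self.r1rho0
        for center, width, height in self.bumps:
            r = r + height * np.exp(-0.5 * ((nu1 - center) / width) ** 2)
        return r


def default_nu1_grid(n: int = 64, lo: float = 500.0, hi: float = 17000.0) -> np.ndarray:
    return np.linspace(lo, hi, n)


def gen_profile(truth: GroundTruth, nu1_grid: np.ndarray | None = None) -> DispersionProfile:
    """Noiseless corrected profile straight from the ground truth."""
    nu1 = default_nu1_grid() if nu1_grid is None else np.asarray(nu1_grid, float)
    if np.any(nu1 <= 0):
        raise ValueError("grid must be positive")
    off = truth.carrier_hz - truth.site_freq_hz
    theta = np.array([tilt_angle_deg(n, truth.carrier_hz, truth.site_freq_hz) for n in nu1])
    frame = pd.DataFrame(
        {
            "nu1_hz": np.hypot(nu1, off),
            "r1rho_s-1": truth.r1rho(np.hypot(nu1, off)),
            "u_s-1": np.full(nu1.size, max(truth.noise_sigma, 1e-9)),
            "theta_deg": theta,
        }
    )
    return DispersionProfile(truth.site, frame)


def gen_one_point(
    truth: GroundTruth,
    nu1_grid: np.ndarray | None = None,
    duration_s: float | None = None,
    n_anchors: int = 5,
    seed: int | None = None,
    two_component: bool = False,
    noise: str = "additive",
) -> tuple[OnePointSeries, list[DecayCurve]]:
    """One-point intensity scan plus matching anchor decay curves.

    Forward model per nominal nu1': theta and the corrected nu1 follow from
    the transmitter offset; the tilted-frame rate is
    R1rho' = R1rho sin^2(theta) + R1 cos^2(theta); the measured intensity is
    ``prefactor * sin^2(theta) * exp(-R1rho' t)`` plus seeded Gaussian noise
    (``noise="multiplicative"`` scales the noise with the signal).  The
    spin-lock length defaults to 1/median(R1rho') — inside the linear-decay
    regime.  ``two_component=True`` replaces the monoexponential by an equal
    mix of rates R and 2R, emulating multiexponential solid-state decays.

    Anchors are full decay curves at ``n_anchors`` frequencies spread over
    the grid interior.
    """
    nu1p = default_nu1_grid() if nu1_grid is None else np.asarray(nu1_grid, float)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    off = truth.carrier_hz - truth.site_freq_hz
    theta = np.array([tilt_angle_deg(n, truth.carrier_hz, truth.site_freq_hz) for n in nu1p])
    s2 = np.sin(np.radians(theta)) ** 2
    c2 = np.cos(np.radians(theta)) ** 2
    nu1 = np.hypot(nu1p, off)
    r_tilted = truth.r1rho(nu1) * s2 + truth.r1_s * c2
    if duration_s is None:
        duration_s = 1.0 / float(np.median(r_tilted))

    def decay(rates, t):
        if two_component:
            return 0.5 * np.exp(-rates * t) + 0.5 * np.exp(-2.0 * rates * t)
        return np.exp(-rates * t)

    clean = truth.prefactor * s2 * decay(r_tilted, duration_s)
    if noise == "additive":
        meas = clean + rng.normal(0.0, truth.noise_sigma, clean.shape)
    elif noise == "multiplicative":
        meas = clean * (1.0 + rng.normal(0.0, truth.noise_sigma, clean.shape))
    else:
        raise ValueError("noise must be 'additive' or 'multiplicative'")
    series = OnePointSeries(
        truth.site,
        nu1p,
        meas,
        np.full(nu1p.size, max(truth.noise_sigma, 1e-12)),
        duration_s,
        truth.carrier_hz,
        truth.site_freq_hz,
        truth.r1_s,
    )
    # anchors: interior frequencies, complete decay curves
    anchor_idx = np.linspace(2, nu1p.size - 3, max(n_anchors, 1)).round().astype(int)
    t_anchor = np.linspace(0.002, 3.0 * duration_s, 8)
    anchors = []
    for k in np.unique(anchor_idx):
        amp = truth.prefactor * s2[k]
        vals = amp * decay(r_tilted[k], t_anchor)
        vals = vals + rng.normal(0.0, truth.noise_sigma, vals.shape)
        anchors.append(
            DecayCurve(
                truth.site,
                float(nu1p[k]),
                t_anchor,
                np.clip(vals, 1e-9, None),
                np.full(t_anchor.size, max(truth.noise_sigma, 1e-12)),
            )
        )
    return series, anchors


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}{resnum:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def gen_toy_structure(
    n_sites: int = 4,
    pair_distance_a: float = 3.5,
    spacing_a: float = 10.0,
    amide_shift_ppm: float = 8.5,
    partner_shift_ppm: float = 5.0,
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Minimal PDB text plus 1H shift table for the structural model.

    Each residue carries a backbone N with its amide H and one hydroxyl-like
    partner proton (named HG) at ``pair_distance_a`` from the amide H.
    Residues are spaced far apart so each amide sees exactly one neighbor
    within the default cutoff.  Amide shifts scatter around
    ``amide_shift_ppm``; partner protons sit near ``partner_shift_ppm``
    (serine/threonine hydroxyl-like).  Deterministic given the seed.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    lines = []
    rows = []
    serial = 1
    for i in range(n_sites):
        x0 = i * spacing_a
        resnum = i + 1
        coords = {
            "N": (x0, 0.0, 0.0),
            "H": (x0, 0.0, 1.02),
            "HG": (x0 + pair_distance_a, 0.0, 1.02),
        }
        for name, (x, y, z) in coords.items():
            elem = "N" if name == "N" else "H"
            lines.append(
                _PDB_ATOM.format(
                    serial=serial, name=name, alt=" ", res="SER", chain="A",
                    resnum=resnum, x=x, y=y, z=z, occ=1.0, b=0.0, elem=elem,
                )
            )
            serial += 1
        rows.append({"residue": resnum, "atom": "H",
                     "shift_ppm": round(amide_shift_ppm + rng.normal(0.0, 0.4), 3)})
        rows.append({"residue": resnum, "atom": "HG",
                     "shift_ppm": round(partner_shift_ppm + rng.normal(0.0, 0.2), 3)})
    lines.append("END\n")
    return "".join(lines), pd.DataFrame(rows)
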