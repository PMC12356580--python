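"""Spin-system, irradiation and relaxation descriptions.

A :class:`SpinSystem` collects rotating-frame isotropic offsets, dipolar
couplings (anisotropy in Hz plus the internuclear-vector orientation in the
crystal frame) and optional chemical-shift anisotropies for a small cluster
of spins.  Exactly one spin sits on the observed (S) channel — in the
motivating application the amide 15N — while the remaining I spins are the
protons whose chemical-shift difference sets the MIRROR matching condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import dipolar_coupling_hz

__all__ = [
    "CSATensor",
    "DipolarCoupling",
    "IrradiationScheme",
    "RelaxationSpec",
    "Spin",
    "SpinSystem",
    "three_spin_reference_system",
    "two_spin_control_system",
]


@dataclass(frozen=True)
class Spin:
    label: str
    channel: str  # "I" or "S"

    def __post_init__(self):
        if self.channel not in ("I", "S"):
            raise ValueError(f"channel must be 'I' or 'S', got {self.channel!r}")


@dataclass(frozen=True)
class DipolarCoupling:
    """Pairwise dipolar coupling.

    ``delta_hz`` is the anisotropy delta_D = -(mu0/4pi) g1 g2 hbar / r^3 in Hz;
    ``polar``/``azimuth`` (radians) orient the internuclear vector in the
    crystal frame.
    """

    spin1: str
    spin2: str
    delta_hz: float
    polar: float = 0.0
    azimuth: float = 0.0

    def __post_init__(self):
        if self.spin1 == self.spin2:
            raise ValueError("dipolar coupling must reference two distinct spins")
        if not (math.isfinite(self.polar) and math.isfinite(self.azimuth)):
            raise ValueError("orientation angles must be finite")


@dataclass(frozen=True)
class CSATensor:
    spin: str
    delta_hz: float
    eta: float = 0.0
    polar: float = 0.0
    azimuth: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("CSA asymmetry must lie in [0, 1]")
        if not (math.isfinite(self.polar) and math.isfinite(self.azimuth)):
            raise ValueError("orientation angles must be finite")


@dataclass(frozen=True)
class SpinSystem:
    spins: tuple[Spin, ...]
    offsets_hz: tuple[float, ...]
    dipolar: tuple[DipolarCoupling, ...] = ()
    csa: tuple[CSATensor, ...] = ()

    def __post_init__(self):
        labels = [s.label for s in self.spins]
        if len(set(labels)) != len(labels):
            raise ValueError("spin labels must be unique")
        if len(self.offsets_hz) != len(self.spins):
            raise ValueError("one offset per spin required")
        n_s = sum(1 for s in self.spins if s.channel == "S")
        if n_s != 1:
            raise ValueError("exactly one S-channel (observed) spin required")
        for c in self.dipolar:
            for lab in (c.spin1, c.spin2):
                if lab not in labels:
                    raise ValueError(f"dipolar coupling references unknown spin {lab!r}")
        for t in self.csa:
            if t.spin not in labels:
                raise ValueError(f"CSA references unknown spin {t.spin!r}")

    @property
    def n_spins(self) -> int:
        return len(self.spins)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spins]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def s_index(self) -> int:
        return next(i for i, s in enumerate(self.spins) if s.channel == "S")

    @property
    def i_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.spins) if s.channel == "I"]


@dataclass(frozen=True)
class IrradiationScheme:
    """RF fields: S-channel spin lock plus optional I-channel decoupling."""

    nu1_s_hz: float
    decoupling_mode: str = "none"  # none | CW | TPPM
    nu1_i_hz: float = 0.0
    tppm_pulse_s: float | None = None
    tppm_phase_deg: float | None = None

    def __post_init__(self):
        if self.nu1_s_hz < 0 or self.nu1_i_hz < 0:
            raise ValueError("RF amplitudes must be non-negative")
        if self.decoupling_mode not in ("none", "CW", "TPPM"):
            raise ValueError(f"unknown decoupling mode {self.decoupling_mode!r}")
        has_tppm = self.tppm_pulse_s is not None and self.tppm_phase_deg is not None
        if (self.decoupling_mode == "TPPM") != has_tppm:
            raise ValueError("TPPM parameters must be given iff mode is TPPM")

    def replace_nu1_s(self, nu1_s_hz: float) -> "IrradiationScheme":
        return IrradiationScheme(
            nu1_s_hz,
            self.decoupling_mode,
            self.nu1_i_hz,
            self.tppm_pulse_s,
            self.tppm_phase_deg,
        )


@dataclass(frozen=True)
class RelaxationSpec:
    """Per-spin random-field rates in s^-1.

    Each listed spin is subject to an independent isotropically fluctuating
    local field, realised as Lindblad dissipators on its x, y and z operators
    with equal strengths.  The quoted rate is the resulting decay rate of that
    spin's longitudinal *and* transverse single-spin coherences.
    """

    rates_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for lab, r in self.rates_s.items():
            if r < 0:
                raise ValueError(f"relaxation rate for {lab!r} must be >= 0")

    def rate(self, label: str) -> float:
        return self.rates_s.get(label, 0.0)

    @property
    def is_zero(self) -> bool:
        return all(r == 0.0 for r in self.rates_s.values())


def _vec_from_points(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    v = np.asarray(b, float) - np.asarray(a, float)
    r = float(np.linalg.norm(v))
    polar = math.acos(v[2] / r)
    azimuth = math.atan2(v[1], v[0])
    return r, polar, azimuth


def system_from_coordinates(
    labels: Sequence[str],
    channels: Sequence[str],
    isotopes: Sequence[str],
    coords_angstrom: Sequence[Sequence[float]],
    offsets_hz: Sequence[float],
) -> SpinSystem:
    """Build a SpinSystem with all pairwise dipolar couplings from coordinates."""
    spins = tuple(Spin(l, c) for l, c in zip(labels, channels))
    couplings = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            r, polar, azimuth = _vec_from_points(coords_angstrom[i], coords_angstrom[j])
            couplings.append(
                DipolarCoupling(
                    labels[i],
                    labels[j],
                    dipolar_coupling_hz(r, isotopes[i], isotopes[j]),
                    polar,
                    azimuth,
                )
            )
    return SpinSystem(spins, tuple(float(o) for o in offsets_hz), tuple(couplings))


def three_spin_reference_system(
    shift_a_hz: float = -700.0,
    shift_b_hz: float = 700.0,
    offset_s_hz: float = 0.0,
    nh_distance: float = 1.02,
    hnh_angle_deg: float = 107.0,
) -> SpinSystem:
    """The illustrative I2S (1H-1H-15N) cluster used throughout.

    Geometry default: an NH2-like group with both protons bonded to the
    nitrogen at ``nh_distance`` (1.02 A) and an H-N-H angle of 107 deg
    (H-H contact of about 1.64 A).  The strong, comparable N-H couplings and
    the short H-H contact make the second-order fictitious-field shift of the
    MIRROR matching condition — the downward displacement of the bump from
    the chemical-shift difference that shrinks with faster spinning — clearly
    visible.  All three pairwise dipolar couplings are derived from the
    distances; every geometric parameter is exposed.
    """
    a = math.radians(hnh_angle_deg)
    h1 = (0.0, 0.0, nh_distance)
    h2 = (nh_distance * math.sin(a), 0.0, nh_distance * math.cos(a))
    return system_from_coordinates(
        labels=["H1", "H2", "N"],
        channels=["I", "I", "S"],
        isotopes=["1H", "1H", "15N"],
        coords_angstrom=[h1, h2, (0.0, 0.0, 0.0)],
        offsets_hz=[shift_a_hz, shift_b_hz, offset_s_hz],
    )


def amide_pair_system(
    shift_a_hz: float = -700.0,
    shift_b_hz: float = 700.0,
    offset_s_hz: float = 0.0,
    nh_distance: float = 1.05,
    hh_distance: float = 2.5,
) -> SpinSystem:
    """Amide-like alternative cluster: one bonded proton plus a remote one.

    N at the origin with its amide H along +z; the second proton sits in the
    xz plane at ``hh_distance`` from the first, displaced perpendicular to
    the N-H bond.  With the weak remote couplings the MIRROR bump appears
    essentially at the chemical-shift difference at all spinning rates.
    """
    h1 = (0.0, 0.0, nh_distance)
    h2 = (hh_distance, 0.0, nh_distance)
    return system_from_coordinates(
        labels=["H1", "H2", "N"],
        channels=["I", "I", "S"],
        isotopes=["1H", "1H", "15N"],
        coords_angstrom=[h1, h2, (0.0, 0.0, 0.0)],
        offsets_hz=[shift_a_hz, shift_b_hz, offset_s_hz],
    )


def two_spin_control_system(
    shift_hz: float = -700.0, offset_s_hz: float = 0.0, nh_distance: float = 1.05
) -> SpinSystem:
    """Single-proton IS control: no MIRROR condition can exist."""
    return system_from_coordinates(
        labels=["H1", "N"],
        channels=["I", "S"],
        isotopes=["1H", "15N"],
        coords_angstrom=[(0.0, 0.0, nh_distance), (0.0, 0.0, 0.0)],
        offsets_hz=[shift_hz, offset_s_hz],
    )
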