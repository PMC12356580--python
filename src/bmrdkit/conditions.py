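"""Recoupling-condition calculators and experimental-design checks.

Dangerous spin-lock / decoupling frequency combinations under MAS:

* MIRROR: S irradiation at ``n*nu_r +/- |nu0_A - nu0_B|`` of two I spins
  (|n| <= 4) recouples the heteronuclear couplings in second order.
* rotary resonance: ``nu1 = n*nu_r`` (first order), HORROR at ``nu_r/2``.
* CP matches between the two RF channels (first and second order).

All frequencies in Hz; ppm inputs are converted by the caller with an
explicit Larmor frequency (:func:`bmrdkit.constants.ppm_to_hz`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConditionReport",
    "mirror_conditions",
    "rotary_and_horror",
    "decoupling_check",
    "nerrd_flag",
    "DEFAULT_MARGIN_HZ",
]

# reflects the observed widening of the conditions by RF inhomogeneity
DEFAULT_MARGIN_HZ = 200.0


@dataclass(frozen=True)
class ConditionReport:
    kind: str  # MIRROR | rotary | HORROR | CP_first_order | CP_second_order | decoupling_rule
    nu1_hz: float
    order: int = 0
    participants: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self):
        if self.kind == "MIRROR" and abs(self.order) > 4:
            raise ValueError("MIRROR order |n| must be <= 4")
        if self.nu1_hz < 0:
            raise ValueError("nu1 must be >= 0")


def mirror_conditions(
    shift_a_hz: float,
    shift_b_hz: float,
    nu_r: float,
    n_max: int = 4,
    labels: tuple[str, str] = ("A", "B"),
) -> list[ConditionReport]:
    """All non-negative MIRROR matching amplitudes ``n*nu_r +/- |dA - dB|``.

    Symmetric under swapping the two shifts; the n = 0 entry is independent
    of the MAS rate.  Results are deduplicated and sorted by nu1.
    """
    if nu_r <= 0:
        raise ValueError("nu_r must be positive")
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    n_max = min(n_max, 4)
    delta = abs(shift_a_hz - shift_b_hz)
    seen: dict[float, ConditionReport] = {}
    for n in range(-n_max, n_max + 1):
        for sign in (+1.0, -1.0):
            nu1 = n * nu_r + sign * delta
            if nu1 < 0:
                continue
            key = round(nu1, 9)
            if key not in seen or abs(n) < abs(seen[key].order):
                seen[key] = ConditionReport(
                    "MIRROR",
                    nu1,
                    n,
                    labels,
                    f"n={n}, |shift difference|={delta:g} Hz",
                )
    return sorted(seen.values(), key=lambda c: c.nu1_hz)


def rotary_and_horror(nu_r: float, n_max: int = 2) -> list[ConditionReport]:
    """HORROR at nu_r/2 plus rotary-resonance conditions n*nu_r, n <= n_max."""
    if nu_r <= 0:
        raise ValueError("nu_r must be positive")
    out = [ConditionReport("HORROR", nu_r / 2.0, 0, (), "homonuclear recoupling at nu_r/2")]
    for n in range(1, n_max + 1):
        out.append(ConditionReport("rotary", n * nu_r, n, (), f"rotary resonance n={n}"))
    return out


def decoupling_check(
    nu1_h: float,
    max_nu1_n: float,
    nu_r: float,
    margin: float = DEFAULT_MARGIN_HZ,
    grid_step: float = 50.0,
) -> tuple[bool, list[ConditionReport]]:
    """Validate a CW decoupling amplitude against an S spin-lock range.

    Rules: nu1_H >= 1.5 * max(nu1_N); no nu1_N <= max with
    |nu1_H + nu1_N - nu_r| < margin (first-order CP) or
    |nu1_H - nu1_N| < margin (second-order CP match); nu1_H itself clear of
    the HORROR condition nu_r/2.  Returns (passed, violations).
    """
    if min(nu1_h, max_nu1_n, nu_r) <= 0:
        raise ValueError("all frequencies must be positive")
    violations: list[ConditionReport] = []
    if nu1_h < 1.5 * max_nu1_n:
        violations.append(
            ConditionReport(
                "decoupling_rule",
                nu1_h,
                0,
                (),
                f"nu1_H = {nu1_h:g} Hz is below 1.5 x max nu1_N = {1.5 * max_nu1_n:g} Hz",
            )
        )
    grid = np.arange(grid_step, max_nu1_n + grid_step / 2.0, grid_step)
    cp1 = grid[np.abs(nu1_h + grid - nu_r) < margin]
    if cp1.size:
        violations.append(
            ConditionReport(
                "CP_first_order",
                float(cp1[0]),
                1,
                (),
                f"nu1_H + nu1_N = nu_r within {margin:g} Hz for nu1_N near {cp1[0]:g} Hz",
            )
        )
    cp2 = grid[np.abs(nu1_h - grid) < margin]
    if cp2.size:
        violations.append(
            ConditionReport(
                "CP_second_order",
                float(cp2[0]),
                2,
                (),
                f"nu1_N = nu1_H = {nu1_h:g} Hz (second-order CP match)",
            )
        )
    if abs(nu1_h - nu_r / 2.0) < margin:
        violations.append(
            ConditionReport(
                "HORROR", nu1_h, 0, (), f"nu1_H within {margin:g} Hz of HORROR at nu_r/2"
            )
        )
    return (not violations, violations)


def nerrd_flag(
    nu1: float,
    nu_r: float,
    shift_pairs: Sequence[tuple[float, float]],
    margin: float = DEFAULT_MARGIN_HZ,
) -> list[ConditionReport]:
    """Flag near-rotary-resonance lock amplitudes hitting an n = 1 MIRROR match.

    For each (shiftA, shiftB) pair the conditions ``nu_r +/- |dA - dB|`` are
    compared against ``nu1`` within ``margin``.
    """
    flags = []
    for k, (sa, sb) in enumerate(shift_pairs):
        delta = abs(sa - sb)
        for sign in (+1.0, -1.0):
            cond = nu_r + sign * delta
            if cond >= 0 and abs(nu1 - cond) <= margin:
                flags.append(
                    ConditionReport(
                        "MIRROR",
                        cond,
                        1,
                        (f"pair{k}",),
                        f"n=1 MIRROR overlap: nu1={nu1:g} Hz vs nu_r{'+' if sign > 0 else '-'}{delta:g} Hz",
                    )
                )
    return flags
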