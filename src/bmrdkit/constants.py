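"""Physical constants and small unit helpers.

Frequencies are handled in Hz throughout the package; angular frequencies
(rad/s) appear only inside Hamiltonian construction and in the fast-exchange
model where the exchange rate is conventionally angular.
"""

import math

# gyromagnetic ratios, rad s^-1 T^-1 (CODATA)
GAMMA = {
    "1H": 2.6752218744e8,
    "2H": 4.10662791e7,
    "13C": 6.728284e7,
    "15N": -2.71261804e7,
}

HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1.0e-7  # T^2 m^3 J^-1

MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))  # 54.7356... deg in rad

TWO_PI = 2.0 * math.pi


def dipolar_coupling_hz(r_angstrom: float, iso1: str = "1H", iso2: str = "1H") -> float:
    """Dipolar coupling anisotropy delta_D = -(mu0/4pi) * g1*g2*hbar / r^3, in Hz.

    ``r_angstrom`` is the internuclear distance.  The sign follows the usual
    convention (negative for two spins of like-sign gamma).
    """
    if r_angstrom <= 0:
        raise ValueError("internuclear distance must be positive")
    r = r_angstrom * 1e-10
    b_rad = -MU0_OVER_4PI * GAMMA[iso1] * GAMMA[iso2] * HBAR / r**3
    return b_rad / TWO_PI


def ppm_to_hz(shift_ppm: float, larmor_hz: float) -> float:
    """Convert a chemical shift in ppm to Hz at the given Larmor frequency."""
    return shift_ppm * larmor_hz * 1e-6
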