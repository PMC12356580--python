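"""One-point spin-lock processing: intensities to corrected dispersion profiles.

The one-point method records a single spectrum after a constant-length spin
lock at each nominal amplitude nu1', anchored by a handful of full decay
curves.  The processing chain is

1. scale each measured intensity by 1/sin^2(theta) for the projection onto
   the effective-field axis (theta from the transmitter offset);
2. convert to an offset-contaminated rate, -ln(I)/t, whose constant offset
   stems from the unknown decay-curve prefactor;
3. estimate that offset as the median difference against anchor rates from
   full monoexponential decay fits, interpolated on the nominal grid;
4. remove the offset, correct the rate and abscissa for the tilt of the
   effective field, and drop points with theta at or below 60 degrees;
5. optionally remove isolated rate jumps larger than a threshold.

Uncertainties propagate linearly from the per-point noise sigma.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "OnePointSeries",
    "DecayCurve",
    "DispersionProfile",
    "DecayFit",
    "fit_decay",
    "scale_intensity",
    "intensity_to_offset_rate",
    "estimate_offset",
    "remove_offset_and_tilt",
    "jump_filter",
    "tilt_angle_deg",
    "process_one_point",
    "combine_profiles",
    "THETA_MIN_DEG",
    "JUMP_THRESHOLD_S",
]

THETA_MIN_DEG = 60.0
JUMP_THRESHOLD_S = 7.0


@dataclass
class OnePointSeries:
    """Constant-duration spin-lock intensity scan for one site."""

    site: str
    nu1_nominal_hz: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    duration_s: float
    carrier_hz: float
    site_freq_hz: float
    r1_s: float = 0.0

    def __post_init__(self):
        self.nu1_nominal_hz = np.asarray(self.nu1_nominal_hz, float)
        self.intensity = np.asarray(self.intensity, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.duration_s <= 0:
            raise ValueError("spin-lock duration must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("noise sigma must be positive")
        if np.any(self.nu1_nominal_hz <= 0):
            raise ValueError("nominal nu1 must be positive")
        if np.unique(self.nu1_nominal_hz).size != self.nu1_nominal_hz.size:
            raise ValueError("nominal nu1 values must be unique")


@dataclass
class DecayCurve:
    """Full spin-lock decay at one nominal amplitude (an anchor point)."""

    site: str
    nu1_nominal_hz: float
    times_s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, float)
        self.intensity = np.asarray(self.intensity, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.times_s.size < 3:
            raise ValueError("a decay curve needs at least 3 time points")
        if self.times_s[0] < 0 or np.any(np.diff(self.times_s) <= 0):
            raise ValueError("durations must increase strictly from >= 0")


@dataclass
class DispersionProfile:
    """Corrected per-site dispersion: (nu1, R1rho, uncertainty, theta)."""

    site: str
    data: pd.DataFrame  # columns nu1_hz, r1rho_s-1, u_s-1, theta_deg
    filtered: list[dict] = field(default_factory=list)

    def __post_init__(self):
        req = {"nu1_hz", "r1rho_s-1", "u_s-1", "theta_deg"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"profile table must have columns {sorted(req)}")
        th = self.data["theta_deg"].to_numpy()
        if np.any(th <= 0) or np.any(th > 90.0):
            raise ValueError("theta must lie in (0, 90] degrees")
        if np.any(self.data["u_s-1"].to_numpy() <= 0):
            raise ValueError("uncertainties must be positive")

    @property
    def nu1_hz(self) -> np.ndarray:
        return self.data["nu1_hz"].to_numpy()

    @property
    def r1rho(self) -> np.ndarray:
        return self.data["r1rho_s-1"].to_numpy()

    @property
    def u(self) -> np.ndarray:
        return self.data["u_s-1"].to_numpy()


@dataclass
class DecayFit:
    rate: float
    rate_std: float
    amplitude: float
    converged: bool = True


def fit_decay(curve: DecayCurve) -> DecayFit:
    """Weighted monoexponential fit I0*exp(-R t) to an anchor decay curve."""
    t, y, s = curve.times_s, curve.intensity, curve.sigma
    if np.any(y <= 0):
        raise ValueError("decay intensities must be positive")
    slope = -np.polyfit(t, np.log(y), 1, w=1.0 / s)[0]
    try:
        popt, pcov = curve_fit(
            lambda tt, a, r: a * np.exp(-r * tt),
            t,
            y,
            p0=[y[0], max(slope, 1e-9)],
            sigma=s,
            absolute_sigma=True,
            maxfev=10000,
        )
    except RuntimeError:
        return DecayFit(math.nan, math.nan, math.nan, converged=False)
    return DecayFit(float(popt[1]), float(np.sqrt(max(pcov[1][1], 0.0))), float(popt[0]))


def tilt_angle_deg(nu1_nominal_hz: float, carrier_hz: float, site_freq_hz: float) -> float:
    """Tilt of the effective field: theta = arctan(nu1' / |nu_rf - nu0|).

    The absolute offset keeps theta in (0, 90]; the corrections depend only
    on even powers of cos/sin so the offset sign is immaterial.
    """
    off = abs(carrier_hz - site_freq_hz)
    if off == 0.0:
        return 90.0
    return math.degrees(math.atan2(nu1_nominal_hz, off))


def scale_intensity(
    i_meas: float | np.ndarray, theta_deg: float | np.ndarray, sigma: float | np.ndarray | None = None
):
    """Offset-corrected intensity I = I_meas / sin^2(theta); sigma scales alike."""
    theta = np.radians(theta_deg)
    if np.any(np.atleast_1d(theta) <= 0):
        raise ValueError("theta must be positive")
    s2 = np.sin(theta) ** 2
    if sigma is None:
        return i_meas / s2
    return i_meas / s2, sigma / s2


def intensity_to_offset_rate(
    i_scaled: float | np.ndarray, sigma: float | np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Offset-contaminated rate -ln(I)/t with uncertainty sigma/(I*t)."""
    i_scaled = np.asarray(i_scaled, float)
    if np.any(i_scaled <= 0):
        raise ValueError("scaled intensity must be positive")
    rate = -np.log(i_scaled) / t
    u = np.asarray(sigma, float) / (i_scaled * t)
    return rate, u


def estimate_offset(
    nu1_nominal_hz: np.ndarray,
    offset_rates: np.ndarray,
    anchors: list[tuple[float, float]],
) -> float:
    """Median difference between interpolated one-point rates and anchor rates.

    ``anchors`` are (nominal nu1', R1rho' from a full decay fit).  Anchors
    outside the one-point frequency range are excluded rather than
    extrapolated; at least one in-range anchor is required.
    """
    nu = np.asarray(nu1_nominal_hz, float)
    rr = np.asarray(offset_rates, float)
    order = np.argsort(nu)
    nu, rr = nu[order], rr[order]
    diffs = []
    for a_nu, a_rate in anchors:
        if nu[0] <= a_nu <= nu[-1]:
            diffs.append(float(np.interp(a_nu, nu, rr)) - a_rate)
    if not diffs:
        raise ValueError(
            "no anchor lies inside the one-point frequency range "
            f"[{nu[0]:g}, {nu[-1]:g}] Hz; record at least one anchor decay "
            "curve at a frequency covered by the scan"
        )
    return float(np.median(diffs))


def remove_offset_and_tilt(
    series: OnePointSeries,
    offset_rates: np.ndarray,
    rate_u: np.ndarray,
    offset: float,
    theta_min_deg: float = THETA_MIN_DEG,
) -> DispersionProfile:
    """Subtract the offset, then tilt-correct rate and abscissa.

    Per point: R1rho' = [R' + offset] - offset; theta from the transmitter
    offset; nu1 = sqrt(nu1'^2 + (nu_rf - nu0)^2);
    R1rho = (R1rho' - R1 cos^2 theta)/sin^2 theta.  Points with
    theta <= ``theta_min_deg`` are dropped and logged.
    """
    if series.r1_s < 0:
        raise ValueError("R1 must be >= 0")
    off_hz = series.carrier_hz - series.site_freq_hz
    rows, filtered = [], []
    for nu1p, rp, u in zip(series.nu1_nominal_hz, offset_rates, rate_u):
        theta = tilt_angle_deg(nu1p, series.carrier_hz, series.site_freq_hz)
        nu1 = math.hypot(nu1p, off_hz)
        if theta <= theta_min_deg:
            filtered.append(
                {"nu1_nominal_hz": float(nu1p), "reason": f"theta={theta:.1f} deg <= {theta_min_deg:g}"}
            )
            continue
        s2 = math.sin(math.radians(theta)) ** 2
        c2 = math.cos(math.radians(theta)) ** 2
        r_tilted = rp - offset
        r1rho = (r_tilted - series.r1_s * c2) / s2
        rows.append(
            {
                "nu1_hz": nu1,
                "r1rho_s-1": r1rho,
                "u_s-1": u / s2,
                "theta_deg": theta,
            }
        )
    frame = pd.DataFrame(rows, columns=["nu1_hz", "r1rho_s-1", "u_s-1", "theta_deg"])
    frame = frame.sort_values("nu1_hz", ignore_index=True)
    return DispersionProfile(series.site, frame, filtered)


def jump_filter(profile: DispersionProfile, threshold: float = JUMP_THRESHOLD_S) -> DispersionProfile:
    """Drop points showing a sudden rate jump beyond ``threshold`` (s^-1).

    Sudden jumps flag poorly converged intensity estimates, so a point is
    removed when it departs from *both* neighbors by more than the threshold
    while the neighbors agree with each other — an isolated spike.  A smooth
    but steep (genuine) dispersion is untouched because consecutive points
    follow the trend.  Removals are logged with reasons.
    """
    df = profile.data.sort_values("nu1_hz", ignore_index=True)
    n = len(df)
    if n < 3 or not math.isfinite(threshold):
        return profile
    r = df["r1rho_s-1"].to_numpy()
    spike = np.zeros(n, bool)
    for i in range(1, n - 1):
        spike[i] = (
            abs(r[i] - r[i - 1]) > threshold
            and abs(r[i] - r[i + 1]) > threshold
            and abs(r[i + 1] - r[i - 1]) <= threshold
        )
    spike[0] = abs(r[0] - r[1]) > threshold and abs(r[1] - r[2]) <= threshold
    spike[-1] = abs(r[-1] - r[-2]) > threshold and abs(r[-2] - r[-3]) <= threshold
    filtered = list(profile.filtered)
    for i in np.flatnonzero(spike):
        filtered.append(
            {
                "nu1_hz": float(df["nu1_hz"].iloc[i]),
                "reason": f"isolated rate jump > {threshold:g} s-1",
            }
        )
    return DispersionProfile(
        profile.site, df.loc[~spike].reset_index(drop=True), filtered
    )


def process_one_point(
    series: OnePointSeries,
    anchor_curves: list[DecayCurve],
    theta_min_deg: float = THETA_MIN_DEG,
    jump_threshold: float | None = JUMP_THRESHOLD_S,
) -> DispersionProfile:
    """Full chain from a one-point scan plus anchors to a corrected profile."""
    if series.r1_s == 0.0:
        warnings.warn(
            f"site {series.site}: R1 missing or zero; tilt correction of the rate "
            "assumes R1 = 0 (negligible when theta is near 90 deg)"
        )
    thetas = np.array(
        [tilt_angle_deg(n, series.carrier_hz, series.site_freq_hz) for n in series.nu1_nominal_hz]
    )
    i_scaled, s_scaled = scale_intensity(series.intensity, thetas, series.sigma)
    good = i_scaled > 0
    dropped = [
        {"nu1_nominal_hz": float(n), "reason": "non-positive scaled intensity"}
        for n in series.nu1_nominal_hz[~good]
    ]
    rates, u = intensity_to_offset_rate(i_scaled[good], s_scaled[good], series.duration_s)
    anchors, anchor_u = [], []
    for curve in anchor_curves:
        fit = fit_decay(curve)
        if fit.converged:
            anchors.append((curve.nu1_nominal_hz, fit.rate))
            anchor_u.append(fit.rate_std)
    offset = estimate_offset(series.nu1_nominal_hz[good], rates, anchors)
    # the median offset is itself uncertain and shifts all points coherently;
    # propagate it (median efficiency factor ~ 1.2533 for Gaussian errors)
    u_interp = np.interp([a[0] for a in anchors], series.nu1_nominal_hz[good], u)
    u_diff2 = u_interp**2 + np.asarray(anchor_u) ** 2
    u_offset = 1.2533 * math.sqrt(float(np.mean(u_diff2)) / len(anchors))
    u = np.hypot(u, u_offset)
    sub = OnePointSeries(
        series.site,
        series.nu1_nominal_hz[good],
        series.intensity[good],
        series.sigma[good],
        series.duration_s,
        series.carrier_hz,
        series.site_freq_hz,
        series.r1_s,
    )
    profile = remove_offset_and_tilt(sub, rates, u, offset, theta_min_deg)
    profile.filtered.extend(dropped)
    if jump_threshold is not None and math.isfinite(jump_threshold):
        profile = jump_filter(profile, jump_threshold)
    return profile


def combine_profiles(p1: DispersionProfile, p2: DispersionProfile) -> DispersionProfile:
    """Inverse-variance combination of two profiles (dual spin-lock durations).

    Points are matched on nu1 (within 1e-6 relative); unmatched points pass
    through unchanged.
    """
    if p1.site != p2.site:
        raise ValueError("profiles must belong to the same site")
    d1 = p1.data.set_index(np.round(p1.data["nu1_hz"], 6))
    d2 = p2.data.set_index(np.round(p2.data["nu1_hz"], 6))
    rows = []
    for key in sorted(set(d1.index) | set(d2.index)):
        if key in d1.index and key in d2.index:
            a, b = d1.loc[key], d2.loc[key]
            w1, w2 = 1.0 / a["u_s-1"] ** 2, 1.0 / b["u_s-1"] ** 2
            rows.append(
                {
                    "nu1_hz": a["nu1_hz"],
                    "r1rho_s-1": (w1 * a["r1rho_s-1"] + w2 * b["r1rho_s-1"]) / (w1 + w2),
                    "u_s-1": 1.0 / math.sqrt(w1 + w2),
                    "theta_deg": a["theta_deg"],
                }
            )
        else:
            rows.append(dict((d1 if key in d1.index else d2).loc[key]))
    return DispersionProfile(
        p1.site, pd.DataFrame(rows), p1.filtered + p2.filtered
    )
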