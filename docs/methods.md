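# Methods

`bmrdkit` addresses a measurement artifact in solid-state ¹⁵N R₁ρ
relaxation-dispersion (Bloch–McConnell relaxation dispersion, BMRD)
experiments under magic-angle spinning (MAS): when the ¹⁵N spin-lock
amplitude ν₁ matches a Mixed Rotational and Rotary Resonance (MIRROR)
condition,

    ν₁ = n·ν_r ± |ν₀(Hᴬ) − ν₀(Hᴮ)|,   |n| ≤ 4,

a second-order three-spin recoupling between two protons and the observed
nitrogen opens a polarization-transfer channel. The proton bath then acts as
a relaxation sink, and the measured R₁ρ(ν₁) shows a localized "bump" that is
easily mistaken for microsecond chemical exchange. The package simulates
this artifact from first principles, enumerates the dangerous frequency
combinations, converts raw one-point spin-lock intensity scans into
corrected dispersion profiles, fits fast exchange globally, and turns the
artifact itself into a structural probe of the local proton environment.

## Spin-dynamics simulation

**Model.** A small spin cluster (default: two ¹H on the I channel, one ¹⁵N
on the S channel; up to 5 spins) evolves in the rotating frame under

* per-spin isotropic offsets (Hz),
* an S-channel spin lock along x, with optional CW or TPPM irradiation on
  the I channel,
* heteronuclear dipolar couplings in their secular 2·IzSz form and
  homonuclear couplings retaining the flip-flop term (3·IzIz − **I**·**I**),
  both MAS-modulated,
* optional chemical-shift anisotropy per spin.

Spatial tensors are rotated geometrically: for each interaction the
crystal-frame Cartesian tensor T is contracted with the lab z axis expressed
in the crystal frame, n(t)ᵀ·T·n(t), with the rotor axis at the magic angle.
This is exact for rank-2 interactions and gives the time-modulated secular
coefficients directly; their average over a rotor period vanishes, as it
must at the magic angle.

**Propagation.** The Liouville-space propagator over one rotor period is
built from piecewise-constant slices (default 100 steps/period, midpoint
sampling, exact 8×8 eigendecomposition per slice). Random-field relaxation
is a Lindblad superoperator — independent x/y/z dissipators of equal
strength per relaxed spin, normalized so the quoted rate is the decay rate
of that spin's longitudinal *and* transverse single-spin coherences — and is
applied by symmetric operator splitting around each slice. The propagator is
trace-preserving, and unitary to machine precision when relaxation is off.
Detection is stroboscopic: the one-period propagator is powered, so a full
R₁ρ trajectory costs one propagator build plus matrix–vector products.
Midpoint sampling makes the integrator second-order: at 55.56 kHz MAS,
doubling 400 → 800 steps/period changes the observable by < 10⁻⁶, and the
default 100 steps/period is converged to ≲ 10⁻⁵ — far below the ~1 s⁻¹
scale of interest.

**Initial/detected state.** S magnetization along the S-channel
effective-field axis, mirroring the experimental sin²θ projection; a pure
transverse start is available for comparison and makes no practical
difference on resonance.

**Powder averaging.** Hemisphere (α, β) sets: a deterministic REPULSION-style
scheme (golden-spiral start, electrostatic relaxation with antipodal
symmetry) and a ZCW-style low-discrepancy set. The rotor phase is fixed
(single γ) — adequate for stroboscopic detection of γ-independent
observables. The default is to average *trajectories* over the powder and
fit a single monoexponential, matching how an experimental (inherently
multi-exponential) powder decay is analyzed; per-crystallite fitting with
rate averaging is available as an option.

**Reference spin system.** The illustrative cluster is NH₂-like: both
protons bonded to the nitrogen at 1.02 Å with an H–N–H angle of 107°
(H–H ≈ 1.64 Å), proton offsets −700/+700 Hz, and 30 s⁻¹ random-field
relaxation on the protons only. The strong, comparable couplings make the
second-order fictitious-field physics of the artifact clearly visible: at
55.56 kHz MAS the bump sits ~25 Hz below the 1400 Hz shift difference and
approaches it from below as ν_r grows, while its amplitude falls — the
characteristic MAS dependence. A weakly coupled amide-like alternative
(one bonded H at 1.05 Å plus a remote H at 2.5 Å) is provided
(`amide_pair_system`); its bump sits essentially at the shift difference at
all spinning rates because its second-order shifts are negligible. Every
geometric parameter is exposed in the configuration.

**Bump detection.** `find_bump` excludes ±2 kHz windows around ν_r/2, ν_r
and 2ν_r (first-order rotary/HORROR neighborhoods), requires an interior
local maximum (an edge maximum is a trend, not a bump), refines the peak by
three-point parabolic interpolation, breaks ties toward lower frequency, and
reports "no bump" when the retained span falls below a noise floor
(default 0.5 s⁻¹; simulations are noiseless, so this floor is purely a
sensitivity control).

## Recoupling-condition calculators

Pure arithmetic on the MIRROR, rotary-resonance (n·ν_r), HORROR (ν_r/2) and
CP-match conditions, with a default matching margin of ±200 Hz reflecting
the width added by RF-field inhomogeneity. The decoupling validator enforces
ν₁ᴴ ≥ 1.5× the maximum ν₁ᴺ, rejects ν₁ᴴ + ν₁ᴺ = ν_r (first-order CP) and
ν₁ᴴ = ν₁ᴺ (second-order CP) anywhere on the lock grid, and keeps ν₁ᴴ clear
of HORROR. ppm inputs are converted only with an explicit Larmor frequency.

## One-point processing

R₁ρ at many lock amplitudes is estimated from a single constant-length
spin-lock intensity per ν₁′, anchored by a few full decay curves:

1. θ = arctan(ν₁′/|ν_rf − ν₀ᴺ|); intensities divided by sin²θ,
2. rate = −ln(I)/t with u = σ/(I·t), contaminated by a constant offset from
   the unknown decay prefactor,
3. offset = median over anchors of (interpolated one-point rate − anchor
   rate), anchors fit by weighted monoexponential least squares; anchors
   outside the scan range are excluded rather than extrapolated,
4. offset removal, then tilt correction
   R₁ρ = (R₁ρ′ − R₁cos²θ)/sin²θ and ν₁ = √(ν₁′² + offset²); points with
   θ ≤ 60° are dropped,
5. an isolated-spike filter removes points jumping > 7 s⁻¹ away from *both*
   neighbors while the neighbors agree — flagging poorly converged
   intensities without touching genuinely steep dispersion.

The median-offset estimate is itself uncertain and shifts every point of a
profile coherently; its standard error (median efficiency factor 1.2533,
anchor-fit and interpolation uncertainties combined) is propagated in
quadrature into every per-point uncertainty. Without this the error bars
are underdispersed (≈91% empirical 2σ coverage instead of ≥95%).

Per-site R₁ is an input column (typically a literature or companion
measurement); when absent it defaults to 0 with a logged warning — harmless
near θ = 90° where the cos²θ correction vanishes. Two spin-lock durations
can be combined by inverse-variance weighting.

## Exchange fitting

The fast-exchange model R₁ρ(ν₁) = φ_ex·k_ex/(k_ex² + (2πν₁)²) + R₁ρ,₀ is
fit jointly over sites (ν₁ > 1.7 kHz, ≥ 4 points per site) with a global
k_ex (rad/s) and per-site φ_ex ≥ 0, R₁ρ,₀. Because the site parameters
enter linearly, the fit uses variable projection: exact weighted linear
solves per site inside a 1-D search over log k_ex (coarse scan over three
decades, then bounded refinement). This is deterministic, immune to
local-minima trapping at this dimensionality, and fast enough for
hundreds of replicate fits per second. Uncertainties come from the full
weighted Jacobian at the optimum.

The two-step protocol of the reference analysis is kept: after step 1, any
site with φ_ex < 10⁵ (rad/s)² is clamped to φ_ex = 0 (baseline-only) and
the rest are refit; if every site is clamped the fit refuses, since k_ex is
then unidentifiable. The model is an evaluation tool for comparing
experimental conditions, not a claim of two-site kinetics. A per-profile
chi-square flatness test against the point uncertainties is provided.

## Bump-residual model

Δ₁ρ(ν₁) = R₁ρ(non-decoupled) − R₁ρ(decoupled), with the decoupled profile
linearly interpolated onto the overlap of the two grids and uncertainties
combined in quadrature; negative plateaus are permitted (the two baselines
sample the spectral density differently).

Assuming the directly bonded amide proton is one MIRROR partner, each
assigned proton j near an amide predicts a peak at
ν₁ = s·|δ_NH − δ_j|·ν_larmor with amplitude A·r_j⁻ᵃ. The peak shape is a
unit-height Gaussian of standard deviation w, isolated in one function so it
can be swapped. Four global parameters (A, w, a, s with 0 < s ≤ 1 for the
MAS-dependent compression of the matching frequency) are fit jointly over
all sites by weighted least squares with domain-respecting transforms.
With A calibrated so a proton 3.5 Å away contributes 1 s⁻¹ at exact match,
the exponent a ≈ 3.7 reproduces that calibration. Identifiability is
flagged: when the fitted contribution stays within ~3× the noise, or the
width collapses below the grid spacing (a delta-like peak chasing noise),
the remaining parameters carry no information.

Structures are read with gemmi (first model, alternate locations by highest
occupancy); amide protons are the explicit atoms named "H"; neighbors are
all *assigned* protons within a 6 Å default cutoff, with unassigned protons
counted and reported.

## Synthetic data

The generator emulates the statistical structure of the experimental data:
fast-exchange dispersion curves plus Gaussian bumps; one-point intensities
via the exact forward model (tilted-frame rates, sin²θ projection,
prefactor 0.9, additive Gaussian spectral noise σ = 0.01 on unit-scale
intensities; a multiplicative mode exists); anchor decay curves at five
interior frequencies; spin-lock duration defaulting to 1/median(R₁ρ′),
inside the linear-decay regime. Defaults mirror the regimes of interest:
64-point ν₁ grids over 0.5–17 kHz, k_ex/2π near 1800 s⁻¹, bump widths
100–300 Hz. An optional two-component decay mode (equal mix of R and 2R)
emulates solid-state multi-exponentiality, with the analytically known
upward bias of the one-point estimate. Toy structures are minimal PDB files
with explicit protons at controlled distances plus amide (≈8.5 ppm) and
hydroxyl-like (≈5 ppm) shift tables.

What this does *not* emulate: spectral overlap and deconvolution errors,
RF-field inhomogeneity, temperature drift, or site-to-site correlated
noise. Passing round-trip tests therefore validates the estimator chain,
not the upstream spectral processing.

Synthetic proton environments used in the model-recovery tests are
protein-like shells of ~10 assigned protons at 2.0–5.5 Å; with sparser
(2-proton) environments the distance exponent is identifiable only to
about ±0.2 at the reference noise level.

## Problem sizes and numerical choices

Simulated acceptance quantities use 100 powder orientations with 25 Hz
(artifact region) or 250 Hz (CP-match region) grids at 100 steps per rotor
period and 30 ms spin locks; test-suite variants use 30–60 orientations,
which shift the detected bump position by well under the quoted tolerances.
Statistical suites use 100–200 seeded replicates. All simulation outputs
are deterministic; random number generation appears only in the synthetic
data generator and is always seeded.

Known limitations: no γ-angle powder averaging (appropriate only for
stroboscopic observables); TPPM phases are assigned per integration slice,
so very short TPPM pulses need raised step counts; clusters beyond 5 spins
are out of scope, as are closed-form second-order effective Hamiltonians —
the simulator is the quantitative route to those effects.
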