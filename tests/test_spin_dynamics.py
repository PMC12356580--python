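"""Unit tests for the MAS spin-lock propagation machinery.

Heavier physics checks (bump position, MAS trends, decoupling) live in the
acceptance suite; here the integrator, operators and rate extraction are
verified on small, fast configurations.
"""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import brute

import bmrdkit as bk
from bmrdkit.constants import TWO_PI
from bmrdkit.spin_dynamics import (
    SimProfile,
    _lock_axis_operator,
    _ops_for,
    _step_hamiltonians,
    build_hamiltonian,
    evolve_spinlock,
    find_bump,
    fit_r1rho_from_trajectory,
    mas_coefficient,
    mas_scan,
    powder_average,
    rotor_period_propagator,
)
from bmrdkit.systems import (
    IrradiationScheme,
    RelaxationSpec,
    SpinSystem,
    Spin,
    three_spin_reference_system,
    two_spin_control_system,
)

NO_RELAX = RelaxationSpec({})
ORIENT = (0.7, 1.1)


def bare_system():
    """Three spins, no couplings, no offsets."""
    return SpinSystem(
        (Spin("H1", "I"), Spin("H2", "I"), Spin("N", "S")), (0.0, 0.0, 0.0)
    )


class TestHamiltonian:
    def test_lock_only_commutes_with_lock_axis(self):
        h = build_hamiltonian(bare_system(), ORIENT, 0.3, IrradiationScheme(5000.0))
        sx = _ops_for(bare_system()).sx
        assert np.allclose(h @ sx - sx @ h, 0.0, atol=1e-12)

    @pytest.mark.parametrize("phase", [0.0, 1.0, 4.0])
    @pytest.mark.parametrize("orient", [(0.0, 0.0), (0.7, 1.1), (3.0, 2.5)])
    def test_hermitian_everywhere(self, ref_system, phase, orient):
        h = build_hamiltonian(ref_system, orient, phase, IrradiationScheme(1400.0, "CW", 8000.0))
        assert np.allclose(h, h.conj().T, atol=1e-10)

    def test_mas_coefficient_averages_to_zero(self, ref_system):
        # magic-angle property of rank-2 spatial tensors, fine quadrature
        phases = TWO_PI * (np.arange(4000) + 0.5) / 4000
        for k in range(3):
            c = mas_coefficient(ref_system, k, ORIENT, phases)
            assert abs(c.mean()) < 1e-9 * np.abs(c).max()

    def test_rotor_phase_domain_checked(self, ref_system):
        with pytest.raises(ValueError):
            build_hamiltonian(ref_system, ORIENT, 7.0, IrradiationScheme(1000.0))


class TestPropagator:
    def test_unitary_without_relaxation(self, ref_system):
        p = rotor_period_propagator(
            ref_system, ORIENT, IrradiationScheme(1400.0), NO_RELAX, 55560.0
        )
        assert np.max(np.abs(p.conj().T @ p - np.eye(64))) < 1e-10

    def test_trace_preserving_with_relaxation(self, ref_system, proton_relax):
        p = rotor_period_propagator(
            ref_system, ORIENT, IrradiationScheme(1400.0), proton_relax, 55560.0
        )
        tr = np.eye(8, dtype=complex).ravel()
        assert np.max(np.abs(tr @ p - tr)) < 1e-10

    def test_identity_on_locked_s_when_bare(self):
        sys = bare_system()
        p = rotor_period_propagator(sys, ORIENT, IrradiationScheme(2000.0), NO_RELAX, 50000.0)
        sx = _ops_for(sys).sx.ravel()
        assert np.allclose(p @ sx, sx, atol=1e-10)

    def test_step_count_validated(self, ref_system):
        with pytest.raises(ValueError):
            rotor_period_propagator(
                ref_system, ORIENT, IrradiationScheme(1000.0), NO_RELAX, 50000.0, n_steps=0
            )

    def test_self_convergence_on_doubling(self, ref_system, proton_relax):
        # doubling the step count at converged settings changes the
        # propagated observable by < 1e-6
        sch = IrradiationScheme(1375.0)
        t1 = evolve_spinlock(ref_system, sch, proton_relax, ORIENT, 2e-3, 55560.0,
                             n_steps=400, sample_stride=1)
        t2 = evolve_spinlock(ref_system, sch, proton_relax, ORIENT, 2e-3, 55560.0,
                             n_steps=800, sample_stride=1)
        assert np.max(np.abs(t1.s_lock - t2.s_lock)) < 1e-6

    def test_stroboscopic_matches_direct_integration(self, ref_system, proton_relax):
        """One-period propagator powered vs direct fine-step integration.

        The oracle integrates straight through 10 ms with full-Liouvillian
        matrix exponentials (no period factorization, no splitting).
        """
        sch = IrradiationScheme(1375.0)
        nur, n_steps = 55560.0, 200
        traj = evolve_spinlock(ref_system, sch, proton_relax, ORIENT, 10e-3, nur,
                               n_steps=n_steps, sample_stride=1)
        ops = _ops_for(ref_system)
        h = _step_hamiltonians(ops, ORIENT[0], ORIENT[1], sch, nur, n_steps)
        gamma = ops.relaxation_superop(proton_relax)
        eye = np.eye(8)
        dt = 1.0 / (nur * n_steps)
        steps = [expm((-1j * (np.kron(hh, eye) - np.kron(eye, hh.T)) + gamma) * dt) for hh in h]
        obs = _lock_axis_operator(ops, sch)
        vec = obs.astype(complex).ravel()
        obs_vec = obs.conj().ravel()
        norm = float(np.real(obs_vec @ vec))
        direct = [1.0]
        for _ in range(round(10e-3 * nur)):
            for s in steps:
                vec = s @ vec
            direct.append(float(np.real(obs_vec @ vec)) / norm)
        assert np.max(np.abs(np.array(direct) - traj.s_lock)) < 1e-6


class TestEvolution:
    def test_z_polarization_conserved_without_couplings(self):
        sys = SpinSystem(
            (Spin("H1", "I"), Spin("H2", "I"), Spin("N", "S")), (-700.0, 700.0, 0.0)
        )
        traj = evolve_spinlock(sys, IrradiationScheme(1400.0), NO_RELAX, ORIENT,
                               2e-3, 55560.0, sample_stride=1)
        total_iz = traj.i_z["H1"] + traj.i_z["H2"]
        assert np.max(np.abs(total_iz - total_iz[0])) < 1e-8

    def test_off_condition_negligible_decay(self, ref_system, proton_relax):
        # spin lock far from any recoupling condition: S survives,
        # in contrast with the strong loss at the matching condition
        off = evolve_spinlock(ref_system, IrradiationScheme(100.0), proton_relax,
                              ORIENT, 20e-3, 55560.0)
        on = evolve_spinlock(ref_system, IrradiationScheme(1375.0), proton_relax,
                             ORIENT, 20e-3, 55560.0)
        assert off.s_lock[-1] > 0.9
        assert 1.0 - on.s_lock[-1] > 4.0 * (1.0 - off.s_lock[-1])

    def test_mirror_match_transfers_and_decays(self, ref_system, proton_relax):
        # at the matching condition: visible S decay, differential I polarization
        traj = evolve_spinlock(ref_system, IrradiationScheme(1375.0), proton_relax,
                               ORIENT, 20e-3, 55560.0)
        assert traj.s_lock[-1] < 0.8
        assert np.max(np.abs(traj.i_z["H1"] - traj.i_z["H2"])) > 0.01

    def test_no_proton_relaxation_no_dispersion_contribution(self, ref_system,
                                                             proton_relax):
        """Without the proton random-field sink the coherent transfer does not
        build up into an apparent powder-average R1rho."""
        powder = bk.repulsion_scheme(10)
        rates = {}
        for label, relax in (("off", NO_RELAX), ("on", proton_relax)):
            prof = bk.simulate_dispersion(
                ref_system, IrradiationScheme(0.0), relax, [1375.0], 55560.0,
                powder=powder,
            )
            rates[label] = prof.r1rho[0]
        assert rates["off"] < 0.25 * rates["on"]


class TestRateFit:
    def test_exact_exponential(self):
        t = np.linspace(0, 0.2, 80)
        fit = fit_r1rho_from_trajectory(t, np.exp(-10.0 * t))
        assert fit.rate == pytest.approx(10.0, rel=1e-8)

    def test_constant_trajectory_zero_rate(self):
        t = np.linspace(0, 0.2, 50)
        fit = fit_r1rho_from_trajectory(t, np.ones_like(t))
        assert fit.rate == pytest.approx(0.0, abs=1e-6)

    def test_growing_trajectory_clipped_with_flag(self):
        t = np.linspace(0, 0.1, 30)
        with pytest.warns(UserWarning, match="clipped"):
            fit = fit_r1rho_from_trajectory(t, np.exp(+3.0 * t))
        assert fit.rate == 0.0 and fit.clipped

    def test_biexponential_matches_grid_search_oracle(self):
        t = np.linspace(0, 0.05, 60)
        y = 0.5 * np.exp(-5.0 * t) + 0.5 * np.exp(-15.0 * t)
        fit = fit_r1rho_from_trajectory(t, y)

        def sse(params):
            a, r = params
            return np.sum((a * np.exp(-r * t) - y) ** 2)

        a_opt, r_opt = brute(sse, [(0.9, 1.1), (5.0, 15.0)], Ns=201, finish=None)
        # refine the brute grid once around the minimum
        a_opt, r_opt = brute(
            sse, [(a_opt - 0.01, a_opt + 0.01), (r_opt - 0.2, r_opt + 0.2)], Ns=201,
            finish=None,
        )
        assert fit.rate == pytest.approx(r_opt, abs=2e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_r1rho_from_trajectory(np.array([0.0, 1.0]), np.array([1.0, 0.5]))


class TestPowderAverage:
    def test_single_orientation_identity(self):
        s = bk.single_orientation()
        np.testing.assert_allclose(powder_average(np.array([[1.0, 2.0]]), s), [1.0, 2.0])

    def test_two_equal_weights_mean(self):
        s = bk.PowderScheme(np.zeros(2), np.zeros(2), np.array([0.5, 0.5]))
        np.testing.assert_allclose(
            powder_average(np.array([[1.0], [3.0]]), s), [2.0]
        )

    def test_length_mismatch_rejected(self, small_powder):
        with pytest.raises(ValueError):
            powder_average(np.zeros((3, 5)), small_powder)

    def test_cross_scheme_agreement_near_condition(self, ref_system, proton_relax):
        """REPULSION-100 and ZCW-144 rates agree within 3% at the condition."""
        vals = []
        for pw in (bk.repulsion_scheme(100), bk.zcw_scheme(144)):
            prof = bk.simulate_dispersion(
                ref_system, IrradiationScheme(0.0), proton_relax, [1375.0],
                55560.0, powder=pw,
            )
            vals.append(prof.r1rho[0])
        assert abs(vals[0] - vals[1]) / vals[1] < 0.03


class TestBumpSearch:
    @staticmethod
    def gaussian_profile(center=1300.0, height=5.0, baseline=1.0, step=25.0):
        nu1 = np.arange(500.0, 2500.0 + step, step)
        r = baseline + height * np.exp(-0.5 * ((nu1 - center) / 120.0) ** 2)
        return SimProfile(nu1, r, 55560.0)

    def test_injected_gaussian_found_within_half_step(self):
        b = find_bump(self.gaussian_profile())
        assert b.found and b.nu1_hz == pytest.approx(1300.0, abs=12.5)

    def test_monotone_profile_no_bump(self):
        nu1 = np.arange(500.0, 2500.0, 50.0)
        prof = SimProfile(nu1, 10.0 - 0.003 * (nu1 - 500.0), 55560.0)
        assert not find_bump(prof).found

    def test_flat_profile_below_noise_floor(self):
        nu1 = np.arange(500.0, 2500.0, 50.0)
        prof = SimProfile(nu1, np.full(nu1.size, 2.0), 55560.0)
        assert not find_bump(prof, noise_floor=0.5).found

    def test_exclusion_windows_remove_rotary_peak(self):
        prof = self.gaussian_profile()
        # a fake rotary spike inside the excluded window around nu_r/2 = 1000 Hz
        prof2 = SimProfile(prof.nu1_hz, prof.r1rho + 50.0 * (np.abs(prof.nu1_hz - 1000.0) < 30), 2000.0)
        b = find_bump(prof2, exclusion=[(900.0, 1100.0)])
        assert b.nu1_hz == pytest.approx(1300.0, abs=12.5)

    def test_strictly_increasing_grid_enforced(self):
        with pytest.raises(ValueError):
            SimProfile(np.array([1.0, 1.0, 2.0]), np.zeros(3), 5e4)


class TestDispersionScan:
    def test_single_proton_control_shows_no_bump(self, proton_relax):
        sys = two_spin_control_system()
        table = mas_scan(
            sys, IrradiationScheme(0.0), RelaxationSpec({"H1": 30.0}),
            [55560.0],
            lambda nur: np.arange(1200.0, 1560.0, 60.0),
            powder=bk.repulsion_scheme(6),
        )
        assert not table["found"].any()

    def test_degenerate_shifts_show_no_bump_off_rotary(self, proton_relax):
        sys = three_spin_reference_system(shift_a_hz=700.0, shift_b_hz=700.0)
        prof = bk.simulate_dispersion(
            sys, IrradiationScheme(0.0), proton_relax,
            np.arange(1200.0, 1560.0, 60.0), 55560.0, powder=bk.repulsion_scheme(6),
        )
        assert not find_bump(prof).found
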