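"""Drude-oscillator parametrization, MBD Hamiltonian and Gaussian states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbdcs import (DampingParams, Geometry, OscillatorSet, coupled_states,
                   default_table, dipole_tensor, fermi_damping, ground_state,
                   interaction_matrix, mbd_energy, parametrize, solve_modes)
from mbdcs.errors import (PolarizationCatastropheError, SingularityError,
                          ValidationError)
from conftest import random_rotation


class TestParametrize:
    def test_free_xe_atom_frequency(self):
        geom = Geometry(elements=["Xe"], coordinates=[[0.0, 0.0, 0.0]])
        osc = parametrize(geom)
        xe = default_table()["Xe"]
        assert osc.alpha[0] == pytest.approx(xe.alpha)
        assert osc.omega[0] == pytest.approx(4.0 * xe.c6 / (3.0 * xe.alpha**2))
        assert osc.r_vdw[0] == pytest.approx(xe.r_vdw)
        # q = 1 convention pins the mass
        assert osc.mass[0] == pytest.approx(1.0 / (osc.alpha[0] * osc.omega[0] ** 2))

    def test_alpha_scale_scales_alpha_at_fixed_omega(self):
        geom = Geometry(elements=["C"], coordinates=[[0.0, 0.0, 0.0]])
        base = parametrize(geom)
        scaled = parametrize(geom, alpha_scale=1.5)
        # C6 ~ s^2 and omega = 4 C6 / (3 alpha^2) => omega invariant,
        # i.e. the polarizability grows at fixed oscillator frequency
        assert scaled.alpha[0] == pytest.approx(1.5 * base.alpha[0], rel=1e-14)
        assert scaled.omega[0] == pytest.approx(base.omega[0], rel=1e-14)
        implied_c6 = 0.75 * scaled.alpha[0] ** 2 * scaled.omega[0]
        base_c6 = 0.75 * base.alpha[0] ** 2 * base.omega[0]
        assert implied_c6 == pytest.approx(1.5**2 * base_c6, rel=1e-12)

    def test_hirshfeld_ratio_scaling(self):
        geom = Geometry(elements=["C"], coordinates=[[0.0, 0.0, 0.0]],
                        hirshfeld_ratios=[0.8])
        osc = parametrize(geom)
        c = default_table()["C"]
        assert osc.alpha[0] == pytest.approx(0.8 * c.alpha)
        assert osc.r_vdw[0] == pytest.approx(0.8 ** (1 / 3) * c.r_vdw)
        # omega is invariant under a pure volume rescaling
        free = parametrize(Geometry(elements=["C"], coordinates=[[0, 0, 0]]))
        assert osc.omega[0] == pytest.approx(free.omega[0], rel=1e-14)

    def test_rejected_inputs(self):
        geom = Geometry(elements=["C"], coordinates=[[0.0, 0.0, 0.0]])
        with pytest.raises(ValidationError):
            parametrize(geom, alpha_scale=0.0)
        with pytest.raises(ValidationError):
            Geometry(elements=["C"], coordinates=[[0, 0, 0]],
                     hirshfeld_ratios=[0.0])
        with pytest.raises(KeyError):
            parametrize(Geometry(elements=["Uuq"], coordinates=[[0, 0, 0]]))


class TestDipoleTensor:
    def test_axial_case(self):
        t = dipole_tensor([0.0, 0.0, 2.0])
        np.testing.assert_allclose(t, np.diag([-1.0, -1.0, 2.0]) / 8.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_traceless_and_symmetric(self, seed):
        r = np.random.default_rng(seed).uniform(-5, 5, 3)
        if np.linalg.norm(r) < 0.1:
            return
        t = dipole_tensor(r)
        assert abs(np.trace(t)) < 1e-12 * np.abs(t).max()
        np.testing.assert_allclose(t, t.T)

    def test_matches_hessian_of_coulomb_potential(self):
        r = np.array([1.3, -0.7, 2.1])
        h = 1e-4
        fd = np.empty((3, 3))
        for a in range(3):
            for b in range(3):
                ea, eb = np.eye(3)[a], np.eye(3)[b]
                fd[a, b] = (
                    1 / np.linalg.norm(r + h * ea + h * eb)
                    - 1 / np.linalg.norm(r + h * ea - h * eb)
                    - 1 / np.linalg.norm(r - h * ea + h * eb)
                    + 1 / np.linalg.norm(r - h * ea - h * eb)
                ) / (4 * h * h)
        np.testing.assert_allclose(dipole_tensor(r), fd, atol=1e-6)

    def test_zero_separation_rejected(self):
        with pytest.raises(SingularityError):
            dipole_tensor([0.0, 0.0, 0.0])


class TestFermiDamping:
    def test_limits_and_midpoint(self):
        params = DampingParams.dcs()
        assert fermi_damping(1e6, 2.0, 2.0, params) == pytest.approx(1.0)
        s = params.beta * 4.0
        assert fermi_damping(s, 2.0, 2.0, params) == pytest.approx(0.5)
        # R = 0 with a = 10.12: 1/(1 + e^a)
        assert fermi_damping(0.0, 2.0, 2.0, params) == pytest.approx(
            1.0 / (1.0 + np.exp(10.12)), rel=1e-12)

    def test_monotone_in_distance(self):
        params = DampingParams.mbd()
        r = np.linspace(0.0, 30.0, 200)
        f = fermi_damping(r, 3.0, 3.0, params)
        assert np.all(np.diff(f) > 0)
        assert np.all((f > 0) & (f < 1))


class TestInteractionMatrix:
    def test_single_atom_block(self):
        osc = OscillatorSet.from_parameters([[0, 0, 0]], 5.0, 0.7, 3.0)
        c = interaction_matrix(osc)
        np.testing.assert_allclose(c, 0.49 * np.eye(3))

    def test_two_atom_closed_form_eigenvalues(self, dimer, undamped):
        # identical oscillators on the z axis, damping ~ 1:
        # z modes omega^2 (1 -+ 2 alpha/R^3), x/y modes omega^2 (1 +- alpha/R^3)
        c = interaction_matrix(dimer, undamped)
        g = dimer.alpha[0] / 8.0**3
        w2 = dimer.omega[0] ** 2
        expected = np.sort([w2 * (1 + 2 * g), w2 * (1 - 2 * g),
                            w2 * (1 + g), w2 * (1 + g),
                            w2 * (1 - g), w2 * (1 - g)])
        got = np.sort(np.linalg.eigvalsh(c))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_symmetry_and_trace_conservation(self, trimer):
        c = interaction_matrix(trimer, DampingParams.mbd())
        np.testing.assert_allclose(c, c.T, atol=0.0)
        assert np.trace(c) == pytest.approx(3 * (trimer.omega**2).sum())

    def test_coincident_atoms_rejected(self):
        osc = OscillatorSet.from_parameters(
            [[0, 0, 0], [0, 0, 0]], 5.0, 0.7, 3.0)
        with pytest.raises(SingularityError):
            interaction_matrix(osc)


class TestSolveModes:
    def test_uncoupled_eigenvalues(self):
        osc = OscillatorSet.from_parameters(
            [[0, 0, 0], [0, 0, 100.0]], [3.0, 5.0], [0.4, 0.9], 2.0)
        spectrum = solve_modes(interaction_matrix(osc, DampingParams.mbd()),
                               osc.omega)
        # at 100 Bohr the coupling is ~alpha/R^3 ~ 1e-6: nearly uncoupled
        np.testing.assert_allclose(
            np.sort(spectrum.eigenvalues),
            np.sort(np.repeat(osc.omega**2, 3)), rtol=1e-5)
        np.testing.assert_allclose(
            spectrum.mode_matrix.T @ spectrum.mode_matrix, np.eye(6),
            atol=1e-10)

    def test_trace_invariance(self, trimer):
        c = interaction_matrix(trimer, DampingParams.mbd())
        spectrum = solve_modes(c)
        assert spectrum.eigenvalues.sum() == pytest.approx(np.trace(c))

    def test_polarization_catastrophe_names_eigenvalue(self):
        osc = OscillatorSet.from_parameters(
            [[0, 0, 0], [0, 0, 2.0]], 10.0, 0.5, 0.1)
        with pytest.raises(PolarizationCatastropheError, match=r"-?\d\.\d+e"):
            solve_modes(interaction_matrix(osc, DampingParams.undamped()))


class TestMbdEnergy:
    def test_single_atom_zero(self):
        osc = OscillatorSet.from_parameters([[0, 0, 0]], 5.0, 0.7, 3.0)
        assert mbd_energy(osc) == 0.0

    def test_leading_order_c6(self, undamped):
        # E ~ -(3/4) alpha^2 omega / R^6 for alpha = omega = 1, R = 10
        osc = OscillatorSet.from_parameters(
            [[0, 0, 0], [0, 0, 10.0]], 1.0, 1.0, 1.0)
        e = mbd_energy(osc, undamped)
        assert e == pytest.approx(-7.5e-7, rel=1e-2)

    def test_asymptotic_r6_decay(self, undamped):
        from mbdcs import fit_decay_exponent
        rs = np.linspace(10.0, 40.0, 13)
        es = np.array([
            mbd_energy(OscillatorSet.from_parameters(
                [[0, 0, 0], [0, 0, r]], 1.0, 1.0, 1.0), undamped)
            for r in rs])
        slope, _ = fit_decay_exponent(rs, es)
        assert slope == pytest.approx(-6.0, abs=0.05)

    def test_rigid_motion_invariance(self, trimer):
        e0 = mbd_energy(trimer)
        rot = random_rotation(5)
        moved = trimer.transformed(rotation=rot, translation=[3.0, -2.0, 11.0])
        assert mbd_energy(moved) == pytest.approx(e0, abs=1e-10)

    def test_permutation_invariance(self, trimer):
        assert mbd_energy(trimer.subset([2, 0, 1])) == pytest.approx(
            mbd_energy(trimer), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 8.0])
    @pytest.mark.parametrize("r", [4.0, 8.0, 16.0])
    def test_attractive_in_stability_region(self, alpha, r, undamped):
        if 2 * alpha / r**3 >= 1:
            pytest.skip("outside the stability region")
        osc = OscillatorSet.from_parameters(
            [[0, 0, 0], [0, 0, r]], alpha, 1.0, 1.0)
        assert mbd_energy(osc, undamped) <= 0.0

    def test_many_body_nonadditivity(self, undamped):
        # equilateral triangle: E(3-body) differs from the sum of pair terms
        pos = np.array([[0, 0, 0], [6.0, 0, 0], [3.0, 3.0 * np.sqrt(3), 0]])
        osc = OscillatorSet.from_parameters(pos, 8.0, 0.5, 2.0)
        e3 = mbd_energy(osc, undamped)
        pair_sum = sum(
            mbd_energy(osc.subset(p), undamped)
            for p in ([0, 1], [0, 2], [1, 2]))
        assert abs(e3 - pair_sum) > 1e-3 * abs(pair_sum)


class TestGroundState:
    def test_uncoupled_isotropic_blocks(self, dimer):
        state = ground_state(dimer, correlated=False)
        for i in range(2):
            np.testing.assert_allclose(
                state.marginal(i),
                0.5 * dimer.alpha[i] * dimer.omega[i] * np.eye(3))
        assert not state.correlated

    def test_correlated_requires_spectrum(self, dimer):
        with pytest.raises(ValidationError):
            ground_state(dimer, correlated=True)

    def test_coupling_off_limit(self):
        # a damping that is numerically 0 everywhere switches the coupling off
        off = DampingParams(a=600.0, beta=1e9)
        osc = OscillatorSet.from_parameters(
            [[0, 0, 0], [0, 0, 8.0]], 4.0, 0.6, 2.0)
        state_dc, state_0 = coupled_states(osc, off)
        np.testing.assert_allclose(state_dc.covariance, state_0.covariance,
                                   atol=1e-12)

    def test_sampled_covariance_matches(self, dimer, undamped):
        state_dc, _ = coupled_states(dimer, undamped)
        rng = np.random.default_rng(42)
        n = 200_000
        draws = state_dc.sample(n, rng)
        empirical = draws.T @ draws / n
        # entrywise within 5 standard errors (se ~ sqrt(2) sigma^2 / sqrt(n))
        scale = np.sqrt(np.outer(np.diag(state_dc.covariance),
                                 np.diag(state_dc.covariance)))
        se = np.sqrt(2.0) * scale / np.sqrt(n)
        assert np.all(np.abs(empirical - state_dc.covariance) < 5 * se + 1e-12)

    def test_cross_blocks_vanish_with_distance(self):
        norms = []
        for r in (10.0, 20.0, 40.0, 80.0):
            osc = OscillatorSet.from_parameters(
                [[0, 0, 0], [0, 0, r]], 6.0, 0.5, 2.0)
            state_dc, _ = coupled_states(osc, DampingParams.mbd())
            norms.append(np.abs(state_dc.cross(0, 1)).max())
        assert np.all(np.diff(norms) < 0)
        # the cross block falls off like the coupling itself, ~ R^-3
        assert norms[-1] < norms[0] / 300.0

    def test_covariant_rotation(self, trimer):
        rot = random_rotation(9)
        state, _ = coupled_states(trimer, DampingParams.mbd())
        rotated_state, _ = coupled_states(trimer.transformed(rotation=rot),
                                          DampingParams.mbd())
        big = np.kron(np.eye(3), rot)
        np.testing.assert_allclose(
            rotated_state.covariance, big @ state.covariance @ big.T,
            atol=1e-12)
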