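"""Nose-Hoover chain structure matrix, equations of motion, conservation,
and canonical sampling."""

import numpy as np
import pytest
import sympy as sp
from scipy import stats

from qcdyn.model import PhasePoint, symplectic_matrix
from qcdyn.statmech import ClassicalEnsemble, ThermalSpec, sample_initial_conditions
from qcdyn.thermostat import (
    ExtendedPoint,
    NHCSpec,
    extended_energy,
    extended_eom,
    integrate_nhc,
    nhc_structure_matrix,
)


def make_ext(r, p, eta, peta):
    return ExtendedPoint(
        point=PhasePoint(r=np.atleast_1d(r), p=np.atleast_1d(p)),
        eta=np.atleast_2d(eta),
        p_eta=np.atleast_2d(peta),
    )


class TestExtendedEnergy:
    def test_kinetic_only(self, uncoupled_symbol):
        nhc = NHCSpec(targets=[1.0], masses=1.0)
        ext = make_ext([0.0], [1.0], [[0.0, 0.0]], [[0.0, 0.0]])
        scalar, matrix = extended_energy(ext, uncoupled_symbol, nhc)
        assert scalar == pytest.approx(0.5, abs=1e-15)

    def test_all_zero_gives_subsystem_matrix(self, spin_boson_symbol):
        nhc = NHCSpec(targets=[1.0], masses=1.0)
        ext = make_ext([0.0], [0.0], [[0.0, 0.0]], [[0.0, 0.0]])
        scalar, matrix = extended_energy(ext, spin_boson_symbol, nhc)
        assert scalar == 0.0
        np.testing.assert_array_equal(matrix, spin_boson_symbol.subsystem.h_s)

    def test_eta_shift_is_linear_in_target_temperature(self, uncoupled_symbol):
        T = 0.7
        nhc = NHCSpec(targets=[T], masses=2.0)
        e0, _ = extended_energy(
            make_ext([0.3], [0.4], [[0.0, 0.0]], [[0.1, 0.2]]), uncoupled_symbol, nhc
        )
        delta = 1.7
        e1, _ = extended_energy(
            make_ext([0.3], [0.4], [[delta, 0.0]], [[0.1, 0.2]]), uncoupled_symbol, nhc
        )
        assert e1 - e0 == pytest.approx(T * delta, rel=1e-12)


class TestStructureMatrix:
    def test_exact_antisymmetry_at_random_points(self, rng):
        nhc = NHCSpec(targets=[1.0, 0.5], masses=[[1.0, 2.0], [0.5, 3.0]])
        for _ in range(5):
            ext = make_ext(
                rng.normal(size=2), rng.normal(size=2),
                rng.normal(size=(2, 2)), rng.normal(size=(2, 2)),
            )
            B = nhc_structure_matrix(ext, nhc)
            np.testing.assert_array_equal(B, -B.T)

    def test_reduces_to_symplectic_block_on_physical_sector(self):
        """With chain momenta and P at zero the thermostat entries vanish and
        the physical (R, P) sector carries the plain symplectic pairing."""
        nhc = NHCSpec(targets=[1.0, 1.0], masses=1.0)
        ext = make_ext([0.4, -0.2], [0.0, 0.0], np.zeros((2, 2)), np.zeros((2, 2)))
        B = nhc_structure_matrix(ext, nhc)
        nq = B.shape[0] // 2
        phys = np.ix_([0, 1, nq, nq + 1], [0, 1, nq, nq + 1])
        np.testing.assert_array_equal(B[phys], symplectic_matrix(2))

    def test_symbolic_product_reproduces_nhc_equations(self, uncoupled_symbol):
        """Computer-algebra check: B(X_e) grad H_e equals the thermostatted
        equations of motion for one mode with a chain of length two."""
        R, P, e1, e2, p1, p2 = sp.symbols("R P eta1 eta2 p1 p2", real=True)
        w, T, M1, M2 = sp.symbols("omega T M1 M2", positive=True)
        H = (
            P**2 / 2 + w**2 * R**2 / 2
            + p1**2 / (2 * M1) + p2**2 / (2 * M2) + T * e1 + T * e2
        )
        coords = [R, e1, e2, P, p1, p2]
        grad = sp.Matrix([sp.diff(H, c) for c in coords])
        B = sp.zeros(6, 6)
        B[0, 3], B[3, 0] = 1, -1
        B[1, 4], B[4, 1] = 1, -1
        B[2, 5], B[5, 2] = 1, -1
        B[3, 4], B[4, 3] = -P, P
        B[4, 5], B[5, 4] = -p1, p1
        rhs = sp.simplify(B * grad)
        expected = sp.Matrix(
            [
                P,
                p1 / M1,
                p2 / M2,
                -(w**2) * R - P * p1 / M1,
                P**2 - T - p1 * p2 / M2,
                p1**2 / M1 - T,
            ]
        )
        assert sp.simplify(rhs - expected) == sp.zeros(6, 1)
        # and the numerical structure matrix agrees with the symbolic one
        subs = {R: 0.3, P: -0.7, e1: 0.1, e2: -0.4, p1: 0.5, p2: 0.9}
        nhc = NHCSpec(targets=[1.0], masses=[[1.0, 2.0]])
        ext = make_ext([0.3], [-0.7], [[0.1, -0.4]], [[0.5, 0.9]])
        Bn = nhc_structure_matrix(ext, nhc)
        np.testing.assert_allclose(Bn, np.array(B.subs(subs), dtype=float))


class TestExtendedEom:
    def test_rest_chain_derivative_example(self, uncoupled_symbol):
        # harmonic mode omega=1 at R=0, P=1, T=1, masses 1, chains at rest
        nhc = NHCSpec(targets=[1.0], masses=1.0)
        ext = make_ext([0.0], [1.0], [[0.0, 0.0]], [[0.0, 0.0]])
        d = extended_eom(ext, uncoupled_symbol, nhc, surface_force=np.array([0.0]))
        np.testing.assert_allclose(d.point.r, [1.0])
        np.testing.assert_allclose(d.point.p, [0.0])
        np.testing.assert_allclose(d.eta, [[0.0, 0.0]])
        np.testing.assert_allclose(d.p_eta, [[0.0, -1.0]])

    def test_thermostat_equilibrium_point(self, uncoupled_symbol):
        # P^2 = T and chains at rest: no thermostat force builds up on link 1
        nhc = NHCSpec(targets=[2.25], masses=1.0)
        ext = make_ext([0.0], [1.5], [[0.0, 0.0]], [[0.0, 0.0]])
        d = extended_eom(ext, uncoupled_symbol, nhc, surface_force=np.array([-1.0]))
        assert d.p_eta[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_structure_matrix_flow(self, rng, uncoupled_symbol):
        """dX_e/dt from the explicit equations equals B grad H_e."""
        nhc = NHCSpec(targets=[0.8], masses=[[1.2, 0.7]])
        ext = make_ext(
            rng.normal(size=1), rng.normal(size=1),
            rng.normal(size=(1, 2)), rng.normal(size=(1, 2)),
        )
        omega = 1.0
        force = -(omega**2) * ext.point.r
        d = extended_eom(ext, uncoupled_symbol, nhc, surface_force=force)
        B = nhc_structure_matrix(ext, nhc)
        grad = np.concatenate([
            omega**2 * ext.point.r, np.full(2, 0.8),
            ext.point.p, (ext.p_eta / nhc.masses).ravel(),
        ])
        flow = B @ grad
        np.testing.assert_allclose(
            np.concatenate([d.point.r, d.eta.ravel(), d.point.p, d.p_eta.ravel()]),
            flow, rtol=1e-12,
        )


class TestIntegrator:
    def test_detached_thermostat_is_symplectic(self, uncoupled_symbol):
        """Without thermostats the 4th-order composition conserves the
        harmonic energy to 1e-8 over 1e5 steps at dt = 1e-3."""
        ens = ClassicalEnsemble(
            r=np.array([[1.0]]), p=np.array([[0.0]]),
            eta=np.zeros((1, 1, 2)), p_eta=np.zeros((1, 1, 2)),
            omega=np.array([1.0]),
        )
        out, rec = integrate_nhc(
            ens, uncoupled_symbol, None, 1e-3, 100_000,
            record_stride=10_000, record_energy=True, order=4,
        )
        e = rec.energy[:, 0]
        assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-8

    def test_thermostatted_energy_conserved(self, uncoupled_symbol):
        """H_e is a constant of the thermostatted flow (antisymmetry of the
        structure matrix); the reversible integrator keeps it to ~dt^2."""
        nhc = NHCSpec.for_modes([1.0], 1.0)
        ens = ClassicalEnsemble(
            r=np.array([[1.2]]), p=np.array([[0.3]]),
            eta=np.zeros((1, 1, 2)), p_eta=np.zeros((1, 1, 2)),
            omega=np.array([1.0]),
        )
        out, rec = integrate_nhc(
            ens, uncoupled_symbol, nhc, 1e-2, 20_000,
            record_stride=2_000, record_energy=True,
        )
        e = rec.energy[:, 0]
        assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-4

    def test_canonical_second_moment(self, uncoupled_symbol):
        """A T=1 thermostatted mode time-averages <P^2> near T."""
        bank_spec = ThermalSpec(beta=1.0, regime="classical")
        from qcdyn.model import OscillatorBank

        bank = OscillatorBank("phonon", [1.0], [0.0])
        ens = sample_initial_conditions([bank], bank_spec, 16, seed=12)
        nhc = NHCSpec.for_modes([1.0], 1.0)
        out, rec = integrate_nhc(ens, uncoupled_symbol, nhc, 0.02, 10_000, record_stride=10)
        p2 = (rec.p[rec.times > 40] ** 2).mean()
        assert p2 == pytest.approx(1.0, rel=0.05)

    def test_histograms_pass_ks_against_gaussian(self, uncoupled_symbol):
        """Decorrelated thermostat samples of (R, P) pass two-sided KS tests
        (alpha = 0.01) against the canonical Gaussians."""
        from qcdyn.model import OscillatorBank

        T, omega = 0.8, 1.0
        bank = OscillatorBank("phonon", [omega], [0.0])
        ens = sample_initial_conditions(
            [bank], ThermalSpec(beta=1.0 / T, regime="classical"), 64, seed=9
        )
        nhc = NHCSpec.for_modes([omega], T)
        out, rec = integrate_nhc(ens, uncoupled_symbol, nhc, 0.05, 4_000, record_stride=100)
        sel = rec.times > 50  # discard equilibration, keep decorrelated snapshots
        p_samples = rec.p[sel].ravel()
        r_samples = rec.r[sel].ravel()
        assert stats.kstest(p_samples / np.sqrt(T), "norm").pvalue > 0.01
        assert stats.kstest(r_samples / np.sqrt(T / omega**2), "norm").pvalue > 0.01

    def test_overflow_guard_signals_unstable_dt(self, uncoupled_symbol):
        nhc = NHCSpec.for_modes([1.0], 1.0, tau=1e-6)  # absurdly light chain
        ens = ClassicalEnsemble(
            r=np.array([[3.0]]), p=np.array([[3.0]]),
            eta=np.zeros((1, 1, 2)), p_eta=np.zeros((1, 1, 2)),
            omega=np.array([1.0]),
        )
        with pytest.raises(RuntimeError, match="dt"):
            integrate_nhc(ens, uncoupled_symbol, nhc, 10.0, 50)

    def test_coupled_symbol_requires_explicit_force(self, spin_boson_symbol):
        ens = ClassicalEnsemble(
            r=np.array([[0.0]]), p=np.array([[0.0]]),
            eta=np.zeros((1, 1, 2)), p_eta=np.zeros((1, 1, 2)),
            omega=np.array([1.0]),
        )
        with pytest.raises(ValueError, match="force"):
            integrate_nhc(ens, spin_boson_symbol, None, 0.01, 10)
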