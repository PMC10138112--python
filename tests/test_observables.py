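"""Averages, correlation functions, and response spectra."""

import numpy as np
import pytest

from qcdyn.dynamics import initial_state_grid, make_grid, sstp_propagate
from qcdyn.model import OscillatorBank, SubsystemSpec, assemble_hamiltonian
from qcdyn.observables import (
    ObservableSpec,
    ensemble_average_series,
    qc_average,
    qc_correlation,
    response_spectrum,
)
from qcdyn.statmech import ThermalSpec, sample_initial_conditions

from conftest import SIGMA_X, SIGMA_Z


def decoupled_two_level(h_s):
    sub = SubsystemSpec(h_s=h_s, chi=np.zeros((2, 2)))
    return assemble_hamiltonian(sub, OscillatorBank("phonon", [1.0], [0.0]))


class TestAverages:
    def test_identity_average_is_one_on_grid(self):
        th = ThermalSpec(beta=1.0)
        grid = make_grid(1.0, th, n_r=48, n_p=48)
        state = initial_state_grid(grid, np.diag([0.5, 0.5]), 1.0, th)
        assert qc_average(state, ObservableSpec(matrix_part=np.eye(2))) == pytest.approx(1.0)

    def test_unnormalized_state_rejected_with_measured_norm(self):
        th = ThermalSpec(beta=1.0)
        grid = make_grid(1.0, th, n_r=48, n_p=48)
        state = initial_state_grid(grid, np.diag([0.5, 0.5]), 1.0, th)
        state.rho = 2.0 * state.rho
        with pytest.raises(ValueError, match="2.0"):
            qc_average(state, ObservableSpec(matrix_part=np.eye(2)))

    def test_ground_state_sigma_z_at_time_zero(self, spin_boson_symbol):
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.2])
        ens = sample_initial_conditions([bank], th, 3000, seed=2)
        sh = sstp_propagate(ens, spin_boson_symbol, np.diag([1.0, 0.0]), 0.01, 1,
                            seed=5, record_stride=1)
        val, err = qc_average(sh, ObservableSpec(matrix_part=SIGMA_Z), t_index=0)
        assert val == pytest.approx(1.0, abs=3 * max(err, 1e-3))

    def test_hermitian_observable_average_is_real(self, spin_boson_symbol):
        from qcdyn.observables import _sh_contributions

        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.2])
        ens = sample_initial_conditions([bank], th, 2000, seed=2)
        sh = sstp_propagate(ens, spin_boson_symbol, np.diag([0.5, 0.5]), 0.01, 50,
                            seed=5, record_stride=50)
        c = _sh_contributions(sh, spin_boson_symbol,
                              ObservableSpec(matrix_part=SIGMA_X), 1, sh.init_factor)
        assert abs(c.imag.mean()) < 3 * c.imag.std() / np.sqrt(c.size) + 1e-10


class TestCorrelations:
    def test_sigma_z_autocorrelation_at_time_zero(self):
        """sigma_z^2 = 1: C(0) = 1 for any subsystem density."""
        sym = decoupled_two_level(SIGMA_Z)
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.0])
        ens = sample_initial_conditions([bank], th, 8000, seed=3)
        sh = sstp_propagate(ens, sym, np.diag([0.6, 0.4]), 0.01, 1, seed=9,
                            record_stride=1)
        obs = ObservableSpec(matrix_part=SIGMA_Z)
        c = qc_correlation(sh, obs, obs)
        assert c[0].real == pytest.approx(1.0, abs=0.08)
        assert abs(c[0].imag) < 0.08

    def test_decoupled_sigma_x_correlation_oscillates_at_gap(self):
        """H_S = (Omega/2) sigma_z, maximally mixed w_S: <sx(t) sx> = cos(Omega t)."""
        Omega = 2.0
        sym = decoupled_two_level(0.5 * Omega * SIGMA_Z)
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.0])
        ens = sample_initial_conditions([bank], th, 4000, seed=4)
        sh = sstp_propagate(ens, sym, 0.5 * np.eye(2), 0.01, 300, seed=13,
                            record_stride=10)
        obs = ObservableSpec(matrix_part=SIGMA_X)
        c = qc_correlation(sh, obs, obs)
        np.testing.assert_allclose(c.real, np.cos(Omega * sh.times), atol=0.05)
        np.testing.assert_allclose(c.imag, 0.0, atol=0.05)

    def test_classical_only_correlation_is_real(self):
        sym = decoupled_two_level(SIGMA_Z)
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.0])
        ens = sample_initial_conditions([bank], th, 1000, seed=6)
        sh = sstp_propagate(ens, sym, 0.5 * np.eye(2), 0.02, 100, seed=21,
                            record_stride=20)
        obs = ObservableSpec(
            matrix_part=np.eye(2),
            classical_part=lambda r, p: np.sum(p * p, axis=-1),
        )
        c = qc_correlation(sh, obs, obs)
        np.testing.assert_allclose(c.imag, 0.0, atol=1e-10)

    def test_dimension_mismatch_rejected(self, spin_boson_symbol):
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.2])
        ens = sample_initial_conditions([bank], th, 50, seed=1)
        sh = sstp_propagate(ens, spin_boson_symbol, np.diag([1.0, 0.0]), 0.01, 2,
                            seed=2, record_stride=1)
        obs2 = ObservableSpec(matrix_part=np.eye(3))
        with pytest.raises(ValueError, match="dimension"):
            qc_correlation(sh, ObservableSpec(matrix_part=SIGMA_Z), obs2)


class TestEstimatorConvergence:
    def test_subensemble_scatter_consistent_with_reported_se(self, spin_boson_symbol):
        """The ensemble-mean estimator converges as 1/sqrt(N): the scatter of
        independent sub-ensemble means matches the reported standard error."""
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.2])
        ens = sample_initial_conditions([bank], th, 8000, seed=14)
        sh = sstp_propagate(ens, spin_boson_symbol, np.diag([1.0, 0.0]), 0.01, 150,
                            seed=3, record_stride=150)
        from qcdyn.observables import _sh_contributions

        c = _sh_contributions(sh, spin_boson_symbol,
                              ObservableSpec(matrix_part=SIGMA_Z), 1,
                              sh.init_factor).real
        chunks = c.reshape(8, -1).mean(axis=1)
        scatter = chunks.std(ddof=1) / np.sqrt(8)
        reported = c.std(ddof=1) / np.sqrt(c.size)
        assert 0.4 < scatter / reported < 2.5


class TestResponseSpectrum:
    def test_cosine_peak_within_one_bin(self):
        t = np.arange(2**12) * 0.05
        res = response_spectrum(np.cos(t), t)
        dw = res.freq[1] - res.freq[0]
        assert abs(res.peak_freq - 1.0) <= dw

    def test_zero_input_gives_zero_spectrum(self):
        t = np.linspace(0, 10, 256)
        res = response_spectrum(np.zeros_like(t), t)
        np.testing.assert_array_equal(np.abs(res.spectrum), 0.0)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            response_spectrum(np.ones(5), np.array([0.0, 0.1, 0.3, 0.4, 0.5]))

    def test_rabi_correlation_peaks_at_adiabatic_gap(self):
        """The sigma_x autocorrelation of a decoupled two-level system peaks
        at the gap frequency from the adiabatic eigensystem."""
        from qcdyn.model import PhasePoint, adiabatic_eigensystem

        Omega = 2.0
        sym = decoupled_two_level(0.5 * Omega * SIGMA_Z)
        energies, _ = adiabatic_eigensystem(sym, PhasePoint(r=[0.0], p=[0.0]))
        gap = energies[1] - energies[0]
        th = ThermalSpec(beta=1.0)
        bank = OscillatorBank("phonon", [1.0], [0.0])
        ens = sample_initial_conditions([bank], th, 1000, seed=8)
        sh = sstp_propagate(ens, sym, 0.5 * np.eye(2), 0.02, 1024, seed=30,
                            record_stride=1)
        obs = ObservableSpec(matrix_part=SIGMA_X)
        c = qc_correlation(sh, obs, obs)
        res = response_spectrum(c.real, sh.times)
        dw = res.freq[1] - res.freq[0]
        assert abs(res.peak_freq - gap) <= dw
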