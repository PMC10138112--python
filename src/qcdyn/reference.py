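"""Numerically exact truncated-Fock references for small benchmarks.

These solve the *fully quantum* problem (subsystem plus one quantized
oscillator) by dense diagonalization on a truncated Fock space.  They share
no code with the phase-space solvers and serve as independent oracles for
cross-validation: pure-dephasing coherence decay, and generic few-level /
one-mode expectation values.  Feasible for a handful of modes at most; that
is their purpose, not a limitation of the phase-space solvers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ladder",
    "dephasing_coherence",
    "quantum_reference_expectation",
]


def ladder(cutoff: int) -> np.ndarray:
    """Truncated annihilation operator on a Fock space of dimension cutoff."""
    return np.diag(np.sqrt(np.arange(1, cutoff)), k=1)


def _full_hamiltonian(h_s, chi, omega, c, cutoff):
    a = ladder(cutoff)
    n_op = a.T @ a
    r_op = (a + a.T) / np.sqrt(2.0 * omega)
    eye_s = np.eye(h_s.shape[0])
    eye_b = np.eye(cutoff)
    return (
        np.kron(h_s, eye_b)
        + omega * np.kron(eye_s, n_op + 0.5 * eye_b)
        - c * np.kron(chi, r_op)
    )


def _thermal_oscillator(beta: float, omega: float, cutoff: int) -> np.ndarray:
    if np.isinf(beta):
        rho = np.zeros((cutoff, cutoff))
        rho[0, 0] = 1.0
        return rho
    w = np.exp(-beta * omega * np.arange(cutoff))
    return np.diag(w / w.sum())


def dephasing_coherence(
    h_s: np.ndarray,
    chi: np.ndarray,
    omega: float,
    c: float,
    beta: float,
    t_grid: np.ndarray,
    w_s: np.ndarray,
    cutoff: int = 40,
) -> np.ndarray:
    """Exact subsystem coherence <0| rho_S(t) |1> for a two-level system
    coupled to one quantized mode, from dense diagonalization.

    The initial state is w_s (subsystem) times the thermal (or ground,
    beta = inf) oscillator density.  Returns the complex coherence on
    ``t_grid``.
    """
    H = _full_hamiltonian(np.asarray(h_s, complex), np.asarray(chi, complex), omega, c, cutoff)
    rho0 = np.kron(np.asarray(w_s, complex), _thermal_oscillator(beta, omega, cutoff))
    evals, U = np.linalg.eigh(H)
    rho_e = U.conj().T @ rho0 @ U
    out = np.empty(len(t_grid), dtype=complex)
    n_s = np.asarray(h_s).shape[0]
    for k, t in enumerate(np.asarray(t_grid, dtype=float)):
        phase = np.exp(-1j * evals * t)
        rho_t = U @ (phase[:, None] * rho_e * phase.conj()[None, :]) @ U.conj().T
        rho_s = np.trace(
            rho_t.reshape(n_s, cutoff, n_s, cutoff), axis1=1, axis2=3
        )
        out[k] = rho_s[0, 1]
    return out


def quantum_reference_expectation(
    h_s: np.ndarray,
    chi: np.ndarray,
    omega: float,
    c: float,
    beta: float,
    obs_matrix: np.ndarray,
    t_grid: np.ndarray,
    w_s: np.ndarray,
    cutoff: int = 40,
) -> np.ndarray:
    """Exact <O(t)> for a subsystem observable, same setting as above."""
    H = _full_hamiltonian(np.asarray(h_s, complex), np.asarray(chi, complex), omega, c, cutoff)
    rho0 = np.kron(np.asarray(w_s, complex), _thermal_oscillator(beta, omega, cutoff))
    O_full = np.kron(np.asarray(obs_matrix, complex), np.eye(cutoff))
    evals, U = np.linalg.eigh(H)
    rho_e = U.conj().T @ rho0 @ U
    O_e = U.conj().T @ O_full @ U
    out = np.empty(len(t_grid))
    for k, t in enumerate(np.asarray(t_grid, dtype=float)):
        phase = np.exp(-1j * evals * t)
        rho_t = phase[:, None] * rho_e * phase.conj()[None, :]
        out[k] = float(np.trace(rho_t @ O_e).real)
    return out
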