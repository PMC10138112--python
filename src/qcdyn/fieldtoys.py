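"""Exactly checkable companion models: superposition-lifetime utilities and
the doubled-boson (thermo-field) mode pair on a truncated Fock space.

Two small, closed-form-verifiable pieces accompany the quantum-classical
simulator:

* *Superposition timescales*: the Bohr frequency omega = Delta E / hbar of a
  two-eigenstate superposition and the associated objective-reduction-style
  lifetime tau ~ h / Delta E.  In hbar = 1 units these satisfy
  omega * tau = 2 pi identically.

* *Doubled-boson mode* ("thermo-field doubling"): each physical mode a is
  paired with a fictitious double v, with

      H = hbar omega (a^+ a - v^+ v) + i hbar gamma (a^+ v^+ - a v).

  The interaction is a two-mode squeezing generator: evolving the two-sector
  vacuum gives <a^+ a>(t) = <v^+ v>(t) = sinh^2(gamma t), while the Casimir
  a^+ a - v^+ v is conserved.  The k-mode sum is a direct product of
  independent pairs (see :func:`dqmb_hamiltonian` for a single pair).

Truncated-Fock propagation is by dense diagonalization (spaces are tiny);
truncation leakage is monitored, not assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .reference import ladder

__all__ = [
    "DqmbModeSpec",
    "bohr_frequency",
    "or_lifetime",
    "dqmb_hamiltonian",
    "dqmb_mode_occupation",
    "dqmb_occupation_series",
    "dqmb_paired_occupation",
]


def bohr_frequency(e_upper: float, e_lower: float) -> float:
    """Bohr frequency (E_upper - E_lower)/hbar of two energy eigenvalues
    (hbar = 1)."""
    return float(e_upper - e_lower)


def or_lifetime(delta_e: float) -> float:
    """Superposition lifetime tau = h/Delta E = 2 pi / Delta E (hbar = 1).

    Satisfies bohr_frequency * or_lifetime = 2 pi for the same gap.
    """
    if not delta_e > 0:
        raise ValueError(f"delta_e must be positive, got {delta_e}")
    return 2.0 * math.pi / float(delta_e)


@dataclass(frozen=True)
class DqmbModeSpec:
    """One doubled-boson mode pair: frequency, damping constant, and the
    Fock truncation per sector (physical a-quanta and tilde v-quanta)."""

    omega: float
    gamma: float
    cutoff: int = 40

    def __post_init__(self):
        if self.cutoff < 2:
            raise ValueError("cutoff must be >= 2")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def _pair_operators(cutoff: int):
    a1 = ladder(cutoff)
    eye = np.eye(cutoff)
    a = np.kron(a1, eye)  # physical sector
    v = np.kron(eye, a1)  # tilde sector
    return a, v


def dqmb_hamiltonian(spec: DqmbModeSpec) -> np.ndarray:
    """H = omega (a^+ a - v^+ v) + i gamma (a^+ v^+ - a v) on the truncated
    two-sector Fock space (dimension cutoff^2); Hermitian by construction."""
    a, v = _pair_operators(spec.cutoff)
    h0 = spec.omega * (a.conj().T @ a - v.conj().T @ v)
    hi = 1j * spec.gamma * (a.conj().T @ v.conj().T - a @ v)
    return h0 + hi


def _evolved_vacuum(spec: DqmbModeSpec, t: float):
    H = dqmb_hamiltonian(spec)
    evals, U = np.linalg.eigh(H)
    psi0 = np.zeros(spec.cutoff**2, dtype=complex)
    psi0[0] = 1.0  # |0>_a |0>_v
    return U @ (np.exp(-1j * evals * t) * (U.conj().T @ psi0))


def _check_leakage(psi: np.ndarray, cutoff: int, tol: float = 1e-8) -> None:
    pop = np.abs(psi.reshape(cutoff, cutoff)) ** 2
    leak = pop[-1, :].sum() + pop[:, -1].sum()
    if leak > tol:
        raise ValueError(
            f"truncation leakage {leak:.2e} exceeds {tol:.0e}: "
            f"increase cutoff (try {2 * cutoff})"
        )


def dqmb_mode_occupation(spec: DqmbModeSpec, t: float) -> float:
    """<a^+ a>(t) for the state evolved from the two-sector vacuum.

    Exact answer (two-mode squeezed vacuum): sinh^2(gamma t), independent of
    omega.  Occupation of the top Fock levels is checked to stay below 1e-8;
    a violation is rejected with a suggested larger cutoff.
    """
    psi = _evolved_vacuum(spec, t)
    _check_leakage(psi, spec.cutoff)
    a, _ = _pair_operators(spec.cutoff)
    n_op = a.conj().T @ a
    return float((psi.conj() @ (n_op @ psi)).real)


def dqmb_occupation_series(spec: DqmbModeSpec, t_grid) -> np.ndarray:
    """<a^+ a> on a time grid (single diagonalization, leakage checked at
    the final time, where it is largest for gamma > 0)."""
    t_grid = np.asarray(t_grid, dtype=float)
    H = dqmb_hamiltonian(spec)
    evals, U = np.linalg.eigh(H)
    psi0 = np.zeros(spec.cutoff**2, dtype=complex)
    psi0[0] = 1.0
    c0 = U.conj().T @ psi0
    a, _ = _pair_operators(spec.cutoff)
    n_op = a.conj().T @ a
    out = np.empty(t_grid.size)
    for k, t in enumerate(t_grid):
        psi = U @ (np.exp(-1j * evals * t) * c0)
        if k == t_grid.size - 1:
            _check_leakage(psi, spec.cutoff)
        out[k] = float((psi.conj() @ (n_op @ psi)).real)
    return out


def dqmb_paired_occupation(spec: DqmbModeSpec, t) -> np.ndarray | float:
    """<a^+ a>(t) from the vacuum, evolved in the paired subspace.

    a^+ a - v^+ v commutes with H, so the vacuum only ever populates the
    paired states |n, n>; the Hamiltonian restricted to that block is
    tridiagonal with <n+1, n+1|H|n, n> = i gamma (n + 1).  Mathematically
    identical to the full two-sector evolution, but the dimension is
    ``cutoff`` instead of ``cutoff^2``, so large cutoffs (strong squeezing,
    gamma t ~ 2 needs a few hundred levels) stay cheap.  Leakage into the
    top paired state is checked the same way.
    """
    N = spec.cutoff
    h = np.zeros((N, N), dtype=complex)
    n1 = np.arange(1, N)
    h[n1, n1 - 1] = 1j * spec.gamma * n1
    h[n1 - 1, n1] = -1j * spec.gamma * n1
    evals, U = np.linalg.eigh(h)
    c0 = U.conj().T[:, 0]
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty(t_arr.size)
    for k, tk in enumerate(t_arr):
        psi = U @ (np.exp(-1j * evals * tk) * c0)
        tail = abs(psi[-1]) ** 2
        if tail > 1e-8:
            raise ValueError(
                f"truncation leakage {tail:.2e} exceeds 1e-08: "
                f"increase cutoff (try {2 * N})"
            )
        out[k] = float(np.sum(np.arange(N) * np.abs(psi) ** 2))
    return out if np.ndim(t) else float(out[0])
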