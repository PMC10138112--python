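"""Model definition: quantum subsystem, harmonic mode banks, and the mixed
Weyl symbol of the Hamiltonian.

The physical picture is an n-level quantum subsystem (tunneling charges,
spins, excitons, ...) bilinearly coupled to two banks of classical harmonic
modes: "phonon" modes representing conformational/vibrational degrees of
freedom and "electromagnetic-field" (EM) modes representing coherent field
coordinates.  After a partial Wigner transform over the heavy coordinates,
every operator becomes a *mixed Weyl symbol*: an n x n Hermitian-matrix-valued
function of the classical phase point.

Units: hbar = k_B = 1 and unit mode masses, so kinetic terms read P^2/2 and
all frequencies/energies are dimensionless.

The model Hamiltonian symbol is

    H(X) = H_S + sum_J [P_J^2/2 + omega_J^2 R_J^2/2] * I
               + sum_K [Pi_K^2/2 + omega_K^2 Q_K^2/2] * I
               - sum_J C_J R_J chi  -  sum_K F_K Q_K zeta

with chi and zeta dimensionless Hermitian coupling operators acting on the
subsystem space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SubsystemSpec",
    "OscillatorBank",
    "PhasePoint",
    "MixedWeylSymbol",
    "HamiltonianSymbol",
    "AdiabaticResult",
    "assemble_hamiltonian",
    "classical_force",
    "adiabatic_eigensystem",
    "OMEGA",
    "symplectic_matrix",
]

_HERM_RTOL = 1e-12

#: 2x2 antisymmetric matrix pairing an operator with the Hamiltonian in the
#: commutator part of the quantum-classical bracket.
OMEGA = np.array([[0.0, 1.0], [-1.0, 0.0]])


def symplectic_matrix(n_modes: int) -> np.ndarray:
    """Block-antisymmetric matrix Lambda over (coordinates; momenta).

    Applying Lambda between two phase-space gradients produces the Poisson
    bracket:  a <-grad Lambda grad-> b = sum_j (dа/dR_j db/dP_j -
    da/dP_j db/dR_j).  Exactly antisymmetric by construction.
    """
    eye = np.eye(n_modes)
    zero = np.zeros((n_modes, n_modes))
    return np.block([[zero, eye], [-eye, zero]])


def _as_hermitian(name: str, mat: np.ndarray, n: int | None = None) -> np.ndarray:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if n is not None and mat.shape[0] != n:
        raise ValueError(f"{name} must be {n}x{n}, got {mat.shape[0]}x{mat.shape[0]}")
    scale = max(np.abs(mat).max(), 1.0)
    if not np.allclose(mat, mat.conj().T, atol=_HERM_RTOL * scale, rtol=0.0):
        raise ValueError(f"{name} is not Hermitian to within {_HERM_RTOL} relative tolerance")
    if np.isrealobj(mat):
        mat = mat.astype(float)
    else:
        mat = mat.astype(complex)
    return mat


@dataclass(frozen=True)
class SubsystemSpec:
    """The quantum side: subsystem Hamiltonian and the two coupling operators.

    Parameters
    ----------
    h_s : (n, n) Hermitian array
        Subsystem Hamiltonian (energy units).
    chi : (n, n) Hermitian array
        Dimensionless operator coupling the subsystem to the phonon bank.
    zeta : (n, n) Hermitian array, optional
        Dimensionless operator coupling the subsystem to the EM bank.
        Defaults to the zero matrix (no EM coupling channel).
    """

    h_s: np.ndarray
    chi: np.ndarray
    zeta: np.ndarray | None = None

    def __post_init__(self):
        h_s = _as_hermitian("h_s", self.h_s)
        n = h_s.shape[0]
        chi = _as_hermitian("chi", self.chi, n)
        zeta = self.zeta
        zeta = np.zeros((n, n)) if zeta is None else _as_hermitian("zeta", zeta, n)
        object.__setattr__(self, "h_s", h_s)
        object.__setattr__(self, "chi", chi)
        object.__setattr__(self, "zeta", zeta)

    @property
    def n(self) -> int:
        return self.h_s.shape[0]


@dataclass(frozen=True)
class OscillatorBank:
    """A bank of classical harmonic modes.

    ``kind`` distinguishes phonon modes (coupled through chi) from EM-field
    modes (coupled through zeta); the two banks are structurally identical
    harmonic banks.
    """

    kind: str
    omega: np.ndarray
    coupling: np.ndarray

    def __post_init__(self):
        if self.kind not in ("phonon", "em"):
            raise ValueError(f"bank kind must be 'phonon' or 'em', got {self.kind!r}")
        omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        coupling = np.atleast_1d(np.asarray(self.coupling, dtype=float))
        if omega.shape != coupling.shape or omega.ndim != 1:
            raise ValueError(
                f"bank {self.kind!r}: omega (len {omega.size}) and coupling "
                f"(len {coupling.size}) must be equal-length vectors"
            )
        if np.any(omega <= 0):
            bad = int(np.argmax(omega <= 0))
            raise ValueError(f"bank {self.kind!r}: omega[{bad}] = {omega[bad]} must be > 0")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "coupling", coupling)

    @property
    def n_modes(self) -> int:
        return self.omega.size

    @staticmethod
    def empty(kind: str) -> "OscillatorBank":
        bank = object.__new__(OscillatorBank)
        object.__setattr__(bank, "kind", kind)
        object.__setattr__(bank, "omega", np.empty(0))
        object.__setattr__(bank, "coupling", np.empty(0))
        return bank


@dataclass(frozen=True)
class PhasePoint:
    """Classical phase point: mode coordinates and conjugate momenta,
    concatenated in bank order (phonons first, then EM modes)."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if r.shape != p.shape or r.ndim != 1:
            raise ValueError("r and p must be equal-length vectors")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)

    @property
    def n_modes(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class MixedWeylSymbol:
    """A Hermitian-matrix-valued function of the classical phase point.

    ``evaluate`` maps a :class:`PhasePoint` to an n x n Hermitian matrix;
    ``gradient_r`` / ``gradient_p`` return the list of matrices
    d(symbol)/d(coordinate_j) and d(symbol)/d(momentum_j).
    """

    n: int
    n_modes: int
    evaluate: Callable[[PhasePoint], np.ndarray]
    gradient_r: Callable[[PhasePoint], np.ndarray]
    gradient_p: Callable[[PhasePoint], np.ndarray]


@dataclass(frozen=True)
class HamiltonianSymbol(MixedWeylSymbol):
    """Mixed Weyl symbol of the model Hamiltonian, retaining its parts.

    ``omega`` is the concatenated frequency vector over both banks,
    ``coupling`` the concatenated coupling constants, and ``coupling_ops``
    the per-mode coupling operator (chi for phonon modes, zeta for EM modes).
    """

    subsystem: SubsystemSpec = None
    omega: np.ndarray = None
    coupling: np.ndarray = None
    coupling_ops: np.ndarray = None  # (n_modes, n, n)


def _check_point(symbol: MixedWeylSymbol, point: PhasePoint) -> None:
    if point.n_modes != symbol.n_modes:
        raise ValueError(
            f"phase point has {point.n_modes} modes, symbol expects {symbol.n_modes}"
        )


def assemble_hamiltonian(
    sub: SubsystemSpec,
    phonons: OscillatorBank | None = None,
    em: OscillatorBank | None = None,
) -> HamiltonianSymbol:
    """Assemble the mixed Weyl symbol of the model Hamiltonian.

    The returned symbol evaluates at a phase point to

        h_s + [sum_J (P_J^2 + omega_J^2 R_J^2)/2
             + sum_K (Pi_K^2 + omega_K^2 Q_K^2)/2] * I
            - sum_J C_J R_J chi - sum_K F_K Q_K zeta

    with unit masses and hbar = 1.
    """
    phonons = OscillatorBank.empty("phonon") if phonons is None else phonons
    em = OscillatorBank.empty("em") if em is None else em
    if phonons.kind != "phonon":
        raise ValueError(f"first bank must have kind 'phonon', got {phonons.kind!r}")
    if em.kind != "em":
        raise ValueError(f"second bank must have kind 'em', got {em.kind!r}")

    n = sub.n
    omega = np.concatenate([phonons.omega, em.omega])
    coupling = np.concatenate([phonons.coupling, em.coupling])
    n_modes = omega.size
    ops = np.empty((n_modes, n, n), dtype=np.result_type(sub.chi, sub.zeta, float))
    ops[: phonons.n_modes] = sub.chi
    ops[phonons.n_modes :] = sub.zeta
    eye = np.eye(n)

    def evaluate(point: PhasePoint) -> np.ndarray:
        _check_point(symbol, point)
        scalar = 0.5 * np.sum(point.p**2 + omega**2 * point.r**2)
        mat = sub.h_s + scalar * eye
        if n_modes:
            mat = mat - np.tensordot(coupling * point.r, ops, axes=(0, 0))
        return mat

    def gradient_r(point: PhasePoint) -> np.ndarray:
        _check_point(symbol, point)
        grads = (omega**2 * point.r)[:, None, None] * eye
        return grads - coupling[:, None, None] * ops

    def gradient_p(point: PhasePoint) -> np.ndarray:
        _check_point(symbol, point)
        return point.p[:, None, None] * eye

    symbol = HamiltonianSymbol(
        n=n,
        n_modes=n_modes,
        evaluate=evaluate,
        gradient_r=gradient_r,
        gradient_p=gradient_p,
        subsystem=sub,
        omega=omega,
        coupling=coupling,
        coupling_ops=ops,
    )
    return symbol


def classical_force(symbol: MixedWeylSymbol, point: PhasePoint) -> np.ndarray:
    """Matrix-valued force -dH/dR_j on each classical coordinate.

    For a phonon coordinate J this is -omega_J^2 R_J * I + C_J * chi (and the
    analogue with zeta for EM coordinates); it is the operator whose adiabatic
    expectation values drive the classical trajectories.
    """
    _check_point(symbol, point)
    return -symbol.gradient_r(point)


@dataclass(frozen=True)
class AdiabaticResult:
    """Eigen-decomposition of a symbol at a phase point.

    ``energies`` ascending; ``basis`` columns are the adiabatic states with a
    deterministic phase (largest-magnitude component real positive);
    ``near_degenerate`` flags any adjacent gap below ``gap_tol``.
    """

    energies: np.ndarray
    basis: np.ndarray
    near_degenerate: bool

    def __iter__(self):  # allow tuple unpacking (energies, basis)
        return iter((self.energies, self.basis))


def adiabatic_eigensystem(
    symbol: MixedWeylSymbol, point: PhasePoint, gap_tol: float = 1e-10
) -> AdiabaticResult:
    """Instantaneous eigenbasis of the symbol at a phase point.

    Hermitian diagonalization with energies ascending and a deterministic
    eigenvector phase convention so that trajectories are reproducible.
    """
    mat = symbol.evaluate(point)
    energies, basis = np.linalg.eigh(mat)
    basis = fix_phase(basis)
    gaps = np.diff(energies)
    near = bool(gaps.size and np.min(gaps) < gap_tol)
    return AdiabaticResult(energies=energies, basis=basis, near_degenerate=near)


def fix_phase(basis: np.ndarray) -> np.ndarray:
    """Rotate each eigenvector column so its largest-magnitude component is
    real and positive (deterministic gauge). Works on batched (..., n, n)."""
    idx = np.argmax(np.abs(basis), axis=-2)
    lead = np.take_along_axis(basis, idx[..., None, :], axis=-2)[..., 0, :]
    phase = lead / np.where(np.abs(lead) == 0, 1.0, np.abs(lead))
    return basis / np.where(phase == 0, 1.0, phase)[..., None, :]
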