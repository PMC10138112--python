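"""Propagation of mixed Weyl symbols under the quantum-classical bracket.

Two complementary solvers:

* A deterministic phase-space **grid solver** (reference): the n x n
  matrix-valued symbol is discretized on a rectangular (R, P) lattice for a
  single classical mode, phase-space derivatives are evaluated with
  4th-order central finite differences, and the bracket

      dO/dt = i[H, O] - (1/2)(dH/dR dO/dP - dH/dP dO/dR)
                      + (1/2)(dO/dR dH/dP - dO/dP dH/dR)

  (Heisenberg picture; all products matrix products, hbar = 1) is integrated
  with classical RK4.  Evolving a statistical symbol W (Schrodinger picture)
  uses the opposite overall sign.  The bracket couples a commutator with two
  Poisson-bracket terms and is a quasi-Lie bracket (no Jacobi identity).

* An adiabatic-basis **trajectory solver** (production): sequential
  short-time propagation of an ensemble of phase-space trajectories, each
  carrying a pair (a, b) of adiabatic indices.  The classical coordinates
  move on the mean surface (E_a + E_b)/2, a phase exp(i int (E_a - E_b) dt)
  accumulates, and in nonadiabatic mode Monte-Carlo transitions between
  index pairs are sampled from the nonadiabatic coupling with momentum-jump
  energy adjustment and importance weights.

The two solvers are cross-validated against each other in the test suite on
two-level/one-mode benchmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import HamiltonianSymbol, MixedWeylSymbol, fix_phase
from .statmech import ClassicalEnsemble, ThermalSpec, _mode_variances
from .thermostat import NHCSpec, _nhc_half_step

__all__ = [
    "PhaseSpaceGrid",
    "GridState",
    "make_grid",
    "initial_state_grid",
    "uniform_observable_grid",
    "qc_bracket_rhs",
    "propagate_grid",
    "trace_functional",
    "SurfaceHoppingEnsemble",
    "sstp_propagate",
]


# --------------------------------------------------------------------------
# phase-space grid solver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSpaceGrid:
    """Rectangular (R, P) lattice for one classical mode."""

    r: np.ndarray
    p: np.ndarray

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def dp(self) -> float:
        return float(self.p[1] - self.p[0])

    @property
    def cell(self) -> float:
        return self.dr * self.dp


@dataclass
class GridState:
    """Matrix field over the lattice: a mixed Weyl symbol sampled on a grid.

    ``kind`` is 'state' for statistical symbols W (normalized: trace
    functional 1) or 'observable' for Heisenberg-evolved symbols O.
    """

    grid: PhaseSpaceGrid
    rho: np.ndarray  # (Nr, Np, n, n) complex
    time: float = 0.0
    kind: str = "state"

    def __post_init__(self):
        if self.kind not in ("state", "observable"):
            raise ValueError("kind must be 'state' or 'observable'")
        rho = np.asarray(self.rho, dtype=complex)
        if rho.shape[:2] != (self.grid.r.size, self.grid.p.size):
            raise ValueError("rho field shape does not match the grid")
        self.rho = rho

    @property
    def n(self) -> int:
        return self.rho.shape[-1]


def make_grid(
    omega: float,
    thermal: ThermalSpec | None = None,
    n_r: int = 96,
    n_p: int = 96,
    extent_sigmas: float = 6.0,
    r_shift: float = 0.0,
) -> PhaseSpaceGrid:
    """Grid spanning +-extent_sigmas thermal Wigner widths (plus an optional
    coordinate shift to cover displaced surface minima)."""
    thermal = thermal or ThermalSpec()
    from .model import OscillatorBank

    bank = OscillatorBank("phonon", [omega], [0.0])
    var_r, var_p = _mode_variances([bank], thermal)
    half_r = extent_sigmas * float(np.sqrt(var_r[0])) + abs(r_shift)
    half_p = extent_sigmas * float(np.sqrt(var_p[0]))
    return PhaseSpaceGrid(
        r=np.linspace(-half_r, half_r, n_r), p=np.linspace(-half_p, half_p, n_p)
    )


def initial_state_grid(
    grid: PhaseSpaceGrid, w_s: np.ndarray, omega: float, thermal: ThermalSpec
) -> GridState:
    """Product initial state: subsystem density matrix times the thermal
    (or zero-point) Wigner Gaussian of the mode, normalized on the grid."""
    w_s = np.asarray(w_s, dtype=complex)
    if not np.allclose(w_s, w_s.conj().T):
        raise ValueError("w_s must be Hermitian")
    if abs(np.trace(w_s).real - 1.0) > 1e-10:
        raise ValueError(f"w_s must have unit trace, got {np.trace(w_s).real}")
    from .model import OscillatorBank

    bank = OscillatorBank("phonon", [omega], [0.0])
    var_r, var_p = _mode_variances([bank], thermal)
    R, P = np.meshgrid(grid.r, grid.p, indexing="ij")
    gauss = np.exp(-0.5 * R**2 / var_r[0] - 0.5 * P**2 / var_p[0])
    gauss /= gauss.sum() * grid.cell
    rho = gauss[:, :, None, None] * w_s
    return GridState(grid=grid, rho=rho, kind="state")


def uniform_observable_grid(grid: PhaseSpaceGrid, matrix: np.ndarray) -> GridState:
    """Phase-space-independent observable symbol sampled on the grid."""
    matrix = np.asarray(matrix, dtype=complex)
    rho = np.broadcast_to(
        matrix, (grid.r.size, grid.p.size) + matrix.shape
    ).copy()
    return GridState(grid=grid, rho=rho, kind="observable")


def _fd4(f: np.ndarray, h: float, axis: int) -> np.ndarray:
    """4th-order central differences on a periodic topology.

    One-sided boundary stencils are weakly unstable under long advection
    runs; wrapping the stencil instead is benign because states are required
    to have negligible boundary mass and phase-space-uniform observable
    fields then stay exactly uniform."""
    fp1 = np.roll(f, -1, axis=axis)
    fm1 = np.roll(f, 1, axis=axis)
    fp2 = np.roll(f, -2, axis=axis)
    fm2 = np.roll(f, 2, axis=axis)
    return (-fp2 + 8.0 * fp1 - 8.0 * fm1 + fm2) / (12.0 * h)


class _GridWork:
    """Precomputed Hamiltonian fields on a grid for one symbol."""

    def __init__(self, symbol: HamiltonianSymbol, grid: PhaseSpaceGrid, n: int):
        if symbol.n_modes != 1:
            raise ValueError(
                "the grid solver is a one-classical-mode reference implementation"
            )
        omega = float(symbol.omega[0])
        c = float(symbol.coupling[0])
        op = symbol.coupling_ops[0]
        eye = np.eye(n)
        R = grid.r[:, None, None, None]
        P = grid.p[None, :, None, None]
        scalar = 0.5 * (grid.p[None, :] ** 2 + omega**2 * grid.r[:, None] ** 2)
        self.H = symbol.subsystem.h_s + scalar[:, :, None, None] * eye - c * R * op
        # dH/dR = omega^2 R I - c * op ; dH/dP = P I  (fields over the grid)
        self.HR = (omega**2) * R * eye - c * op
        self.HP = P * eye
        self.grid = grid


def _commutator(A, B):
    return A @ B - B @ A


def qc_bracket_rhs(
    state: GridState,
    symbol: HamiltonianSymbol,
    work: _GridWork | None = None,
    check_boundary: bool = True,
) -> np.ndarray:
    """Right-hand side of the quantum-classical bracket on the grid.

    Heisenberg sign for ``kind='observable'``; the opposite sign is applied
    for statistical symbols (``kind='state'``, Schrodinger picture).  For
    states the classical mass near the grid boundary is checked to be
    negligible (< 1e-8 of the total) and a violation is flagged.
    """
    work = work or _GridWork(symbol, state.grid, state.n)
    rho = state.rho
    if state.kind == "state" and check_boundary:
        mass = np.abs(np.trace(rho, axis1=2, axis2=3))
        total = mass.sum()
        edge = mass[:2].sum() + mass[-2:].sum() + mass[2:-2, :2].sum() + mass[2:-2, -2:].sum()
        if total > 0 and edge / total > 1e-8:
            warnings.warn(
                f"boundary mass fraction {edge / total:.2e} exceeds 1e-8: "
                "enlarge the grid extents",
                RuntimeWarning,
                stacklevel=2,
            )
    dR = _fd4(rho, state.grid.dr, 0)
    dP = _fd4(rho, state.grid.dp, 1)
    heis = (
        1j * _commutator(work.H, rho)
        - 0.5 * (work.HR @ dP - work.HP @ dR)
        + 0.5 * (dR @ work.HP - dP @ work.HR)
    )
    return heis if state.kind == "observable" else -heis


def _cfl_limit(symbol: HamiltonianSymbol, grid: PhaseSpaceGrid, n: int) -> float:
    omega = float(symbol.omega[0])
    c = float(symbol.coupling[0])
    vmax = float(np.abs(grid.p).max())
    op_norm = float(np.linalg.norm(symbol.coupling_ops[0], 2)) if n else 0.0
    fmax = omega**2 * float(np.abs(grid.r).max()) + abs(c) * op_norm
    # advection rates plus the fastest quantum frequency on the grid
    h_corner = symbol.subsystem.h_s + 0.5 * (
        grid.p.max() ** 2 + omega**2 * grid.r.max() ** 2
    ) * np.eye(n)
    e_spread = float(np.abs(np.linalg.eigvalsh(h_corner)).max())
    rate = vmax / grid.dr + max(fmax, 1e-300) / grid.dp + e_spread
    return 2.0 / rate  # RK4 stability margin along the imaginary axis (~2.8)


def trace_functional(state: GridState) -> float:
    """Tr' integral of the matrix field over the grid (quadrature)."""
    return float(np.trace(state.rho.sum(axis=(0, 1))).real * state.grid.cell)


def propagate_grid(
    state: GridState,
    symbol: HamiltonianSymbol,
    dt: float,
    n_steps: int,
    record_stride: int | None = None,
    callback=None,
    check_trace: bool = True,
) -> tuple[GridState, list]:
    """RK4 integration of the bracket on the grid.

    Hermiticity is re-symmetrized each step.  For states the trace
    functional must be conserved within 1e-6 over the run.  A dt above the
    grid-derived stability limit is rejected with a suggested value.
    ``callback(state)`` is evaluated every ``record_stride`` steps (and at
    t = 0); its results are returned as the second element.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    work = _GridWork(symbol, state.grid, state.n)
    limit = _cfl_limit(symbol, state.grid, state.n)
    if dt > limit:
        raise ValueError(
            f"dt = {dt} exceeds the grid stability limit; use dt <= {limit:.3e}"
        )
    rho = state.rho.copy()
    current = replace(state, rho=rho)
    trace0 = trace_functional(current) if current.kind == "state" else None
    records = []

    def emit():
        if callback is not None:
            records.append(callback(current))

    if record_stride:
        emit()
    for step in range(1, n_steps + 1):
        check = step == 1  # boundary-mass precondition checked on entry
        k1 = qc_bracket_rhs(current, symbol, work, check_boundary=check)
        current.rho = rho + 0.5 * dt * k1
        k2 = qc_bracket_rhs(current, symbol, work, check_boundary=False)
        current.rho = rho + 0.5 * dt * k2
        k3 = qc_bracket_rhs(current, symbol, work, check_boundary=False)
        current.rho = rho + dt * k3
        k4 = qc_bracket_rhs(current, symbol, work, check_boundary=False)
        rho += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.add(rho, np.conj(np.swapaxes(rho, -1, -2)), out=rho)
        rho *= 0.5
        current.rho = rho
        current.time = state.time + step * dt
        if record_stride and step % record_stride == 0:
            emit()
    if check_trace and trace0 is not None:
        drift = abs(trace_functional(current) - trace0)
        if drift > 1e-6 * max(abs(trace0), 1.0):
            raise RuntimeError(
                f"trace functional drifted by {drift:.2e} (> 1e-6): "
                "reduce dt or enlarge the grid"
            )
    return current, records


# --------------------------------------------------------------------------
# adiabatic-basis trajectory solver (sequential short-time propagation)
# --------------------------------------------------------------------------

@dataclass
class SurfaceHoppingEnsemble:
    """Seeded trajectory ensemble carrying adiabatic index pairs.

    Snapshot arrays are indexed (time, member): positions/momenta
    ``r``/``p`` of shape (n_t, N, n_modes), index pairs ``pair`` (n_t, N, 2),
    accumulated complex coefficient ``coeff`` (phase times Monte-Carlo
    weight) of shape (n_t, N).  ``init_factor`` carries n^2 times the
    initial-pair matrix element of the subsystem density in the adiabatic
    basis at the initial phase point, so that

        <O(t)> = Re mean_m[ init_factor_m coeff_m(t) O^adiab_{a_t b_t}(X_t) ].
    """

    times: np.ndarray
    r: np.ndarray
    p: np.ndarray
    pair: np.ndarray
    coeff: np.ndarray
    basis: np.ndarray  # (n_t, N, n, n) trajectory-gauge adiabatic basis
    init_factor: np.ndarray
    w_s: np.ndarray
    frozen: np.ndarray
    seed: int | None = None
    symbol: HamiltonianSymbol | None = None

    @property
    def n_members(self) -> int:
        return self.r.shape[1]

    @property
    def members(self):
        """Per-member view: list of (trajectory dict, seed index)."""
        return [
            {
                "r": self.r[:, m],
                "p": self.p[:, m],
                "pair": self.pair[:, m],
                "coeff": self.coeff[:, m],
                "init_factor": self.init_factor[m],
                "frozen": bool(self.frozen[m]),
            }
            for m in range(self.n_members)
        ]


def _batched_eigh(symbol: HamiltonianSymbol, r: np.ndarray, basis_prev=None):
    """Adiabatic energies/basis at a batch of positions (N, n_modes).

    With ``basis_prev`` the eigenvector labels and gauge are transported
    continuously along the trajectory: when a true (or extremely narrow
    avoided) crossing swaps the energy ordering, columns are relabeled to
    follow the physically continuous states (maximum overlap assignment),
    and each column is rotated so its overlap with the previous basis is
    real positive.  Without it the pointwise deterministic phase convention
    is applied.  Returns energies (N, n), basis (N, n, n), and the coupling-
    operator matrix elements in that basis (N, n_modes, n, n).
    """
    h = symbol.subsystem.h_s[None, :, :] - np.einsum(
        "j,Nj,jkl->Nkl", symbol.coupling, r, symbol.coupling_ops
    )
    # the classical harmonic part is proportional to identity: it shifts all
    # adiabatic surfaces equally and is added analytically where needed
    energies, basis = np.linalg.eigh(h)
    if basis_prev is None:
        basis = fix_phase(basis)
    else:
        n = energies.shape[1]
        M = np.einsum("Nki,Nkj->Nij", basis_prev.conj(), basis)
        diag = np.abs(M[:, np.arange(n), np.arange(n)])
        crossed = np.nonzero(diag.min(axis=1) < 0.7071)[0]
        if crossed.size:
            from scipy.optimize import linear_sum_assignment

            for m in crossed:
                _, col = linear_sum_assignment(-np.abs(M[m]))
                basis[m] = basis[m][:, col]
                energies[m] = energies[m][col]
                M[m] = M[m][:, col]
        overlap = M[:, np.arange(n), np.arange(n)]
        mag = np.abs(overlap)
        phase = np.where(mag > 0, overlap / np.where(mag == 0, 1.0, mag), 1.0)
        basis = basis * phase.conj()[:, None, :]
    ops_ad = np.einsum(
        "Nki,jkl,Nlm->Njim", basis.conj(), symbol.coupling_ops, basis
    )
    return energies, basis, ops_ad


def _surface_quantities(symbol, r, pair, energies, ops_ad):
    """Mean-surface force and pair gap for each member."""
    N = r.shape[0]
    idx = np.arange(N)
    a, b = pair[:, 0], pair[:, 1]
    # dE_i/dR_j = omega_j^2 R_j - C_j <i|op_j|i>  (Hellmann-Feynman)
    diag_a = ops_ad[idx, :, a, a].real
    diag_b = ops_ad[idx, :, b, b].real
    force = -(symbol.omega**2) * r + 0.5 * symbol.coupling * (diag_a + diag_b)
    # classical harmonic energy cancels in the gap
    scalar = 0.5 * np.sum(symbol.omega**2 * r**2, axis=1)
    e_a = energies[idx, a] + scalar
    e_b = energies[idx, b] + scalar
    return force, e_a - e_b


def sstp_propagate(
    ensemble: ClassicalEnsemble,
    symbol: HamiltonianSymbol,
    w_s: np.ndarray,
    dt: float,
    n_steps: int,
    hop_mode: str = "nonadiabatic",
    seed: int = 0,
    record_stride: int = 1,
    nhc: NHCSpec | None = None,
    weight_cutoff: float = 1e3,
) -> SurfaceHoppingEnsemble:
    """Sequential short-time propagation of an adiabatic-basis ensemble.

    Each member starts from a phase point of ``ensemble`` (sampled from the
    thermal Wigner weight) with an index pair drawn uniformly from the n^2
    pairs; its statistical factor is n^2 (U0^H w_s U0)_{b0 a0}.  Classical
    coordinates follow velocity Verlet on the mean adiabatic surface
    (E_a + E_b)/2 (with per-mode NHC chain updates when ``nhc`` is given);
    the coherence phase exp(i int (E_a - E_b) dt') accumulates in ``coeff``.

    In ``nonadiabatic`` mode, index transitions are sampled once per step
    with probability g dt/(1 + g dt), g the summed nonadiabatic coupling
    magnitude |P . d_{aa'}|; an accepted hop multiplies the weight by the
    signed factor (1 + g dt) sgn(P . d), adjusts the momentum along the
    coupling direction to conserve energy on the new mean surface, and a
    declined hop multiplies by 1/(1 - p) = 1 + g dt.  Hops with
    insufficient kinetic energy (frustrated) fall back to the no-hop
    branch.  ``adiabatic_only`` forbids transitions.

    Members whose |coeff| exceeds ``weight_cutoff`` are frozen (no further
    hops; documented variance-control measure) and flagged.

    One master seed spawns independent per-member substreams through
    ``numpy.random.SeedSequence``; a fixed seed reproduces trajectories and
    weights bit-for-bit.
    """
    if hop_mode not in ("adiabatic_only", "nonadiabatic"):
        raise ValueError("hop_mode must be 'adiabatic_only' or 'nonadiabatic'")
    w_s = np.asarray(w_s, dtype=complex)
    n = symbol.n
    if w_s.shape != (n, n):
        raise ValueError(f"w_s must be {n}x{n}")
    N = ensemble.n_samples
    r = ensemble.r.copy()
    p = ensemble.p.copy()
    eta = ensemble.eta.copy()
    peta = ensemble.p_eta.copy()
    idx = np.arange(N)

    # one master seed -> one substream per member (hop decisions), so any
    # single trajectory can be replayed in isolation from its substream;
    # the (n_steps, 2) uniforms per member are drawn up front.
    ss = np.random.SeedSequence(seed)
    u_all = np.stack(
        [np.random.default_rng(s).random((n_steps, 2, 2)) for s in ss.spawn(N)], axis=1
    ) if n_steps else np.zeros((0, N, 2, 2))

    rng_pairs = np.random.default_rng(ss.spawn(1)[0])
    pair_flat = rng_pairs.integers(0, n * n, size=N)
    pair = np.stack([pair_flat // n, pair_flat % n], axis=1)

    energies, basis, ops_ad = _batched_eigh(symbol, r)
    w_ad = np.einsum("Nki,kl,Nlm->Nim", basis.conj(), w_s, basis)
    init_factor = (n * n) * w_ad[idx, pair[:, 1], pair[:, 0]]

    coeff = np.ones(N, dtype=complex)
    frozen = np.zeros(N, dtype=bool)

    rec_t, rec_r, rec_p, rec_pair, rec_coeff, rec_basis = [], [], [], [], [], []

    def snapshot(t):
        rec_t.append(t)
        rec_r.append(r.copy())
        rec_p.append(p.copy())
        rec_pair.append(pair.copy())
        rec_coeff.append(coeff.copy())
        rec_basis.append(basis.copy())

    snapshot(ensemble.time)

    force, gap = _surface_quantities(symbol, r, pair, energies, ops_ad)
    for step in range(1, n_steps + 1):
        coeff *= np.exp(0.5j * dt * gap)
        if nhc is not None:
            _nhc_half_step(p, eta, peta, nhc.masses, nhc.targets, 0.5 * dt)
        p += 0.5 * dt * force
        r += dt * p
        energies, basis, ops_ad = _batched_eigh(symbol, r, basis_prev=basis)
        force, gap = _surface_quantities(symbol, r, pair, energies, ops_ad)
        p += 0.5 * dt * force
        if nhc is not None:
            _nhc_half_step(p, eta, peta, nhc.masses, nhc.targets, 0.5 * dt)
        coeff *= np.exp(0.5j * dt * gap)

        if hop_mode == "nonadiabatic" and n > 1:
            _attempt_hops(
                symbol, r, p, pair, coeff, frozen, energies, ops_ad,
                dt, u_all[step - 1], weight_cutoff,
            )
            force, gap = _surface_quantities(symbol, r, pair, energies, ops_ad)

        if step % record_stride == 0:
            snapshot(ensemble.time + step * dt)

    return SurfaceHoppingEnsemble(
        times=np.array(rec_t),
        r=np.array(rec_r),
        p=np.array(rec_p),
        pair=np.array(rec_pair),
        coeff=np.array(rec_coeff),
        basis=np.array(rec_basis),
        init_factor=init_factor,
        w_s=w_s.copy(),
        frozen=frozen,
        seed=seed,
        symbol=symbol,
    )


# relative sign of the hop weight factor for the left (a) and right (b)
# index of the pair; fixed by cross-validation against the grid solver
_HOP_SIGNS = (1.0, 1.0)


def _attempt_hops(
    symbol, r, p, pair, coeff, frozen, energies, ops_ad, dt, u, cutoff
):
    """One Monte-Carlo hop attempt per member and step (both indices).

    The nonadiabatic coupling vector for a -> a' is
    d_{aa'}^j = <a| dH/dR_j |a'> / (E_a' - E_a) = -C_j (op_j)_{aa'} / (E_a' - E_a);
    the transition strength is g = P . d_{aa'} (real part; exact for real
    Hamiltonians).
    """
    N = r.shape[0]
    idx = np.arange(N)
    n = energies.shape[1]
    frozen |= np.abs(coeff) > cutoff
    for slot in range(2):  # 0: left index a, 1: right index b
        u_slot = u[:, slot]
        cur = pair[:, slot]
        # coupling strengths to every partner state
        dE = energies - energies[idx, cur][:, None]  # E_a' - E_a per partner
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (
                -np.einsum("j,Njs->Nsj", symbol.coupling, ops_ad[idx, :, cur, :])
                / dE[:, :, None]
            )
        d[dE == 0] = 0.0
        d = d.real  # real part of P.d drives the sampled transitions
        g = np.einsum("Nj,Nsj->Ns", p, d)  # P . d per partner
        g[idx, cur] = 0.0
        # momentum-jump feasibility per channel: the mean surface shifts by
        # (E_tgt - E_cur)/2, so the kinetic energy along d must cover it;
        # energetically closed channels are excluded from the sampling
        dnorm = np.linalg.norm(d, axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_par = np.where(dnorm > 0, np.einsum("Nj,Nsj->Ns", p, d) / dnorm, 0.0)
        gain = p_par**2 - dE
        open_ch = (dnorm > 0) & (gain >= 0)
        g_abs = np.where(open_ch, np.abs(g), 0.0)
        g_tot = g_abs.sum(axis=1)
        prob = g_tot * dt / (1.0 + g_tot * dt)
        attempt = (~frozen) & (u_slot[:, 0] < prob) & (g_tot > 0)
        nohop_factor = 1.0 + g_tot * dt
        hopped = np.zeros(N, dtype=bool)
        for m in np.nonzero(attempt)[0]:
            # choose an open partner channel proportionally to |g|
            w = g_abs[m] / g_tot[m]
            tgt = int(np.searchsorted(np.cumsum(w), min(u_slot[m, 1], 0.9999999999)))
            dhat = d[m, tgt] / dnorm[m, tgt]
            sgn = 1.0 if p_par[m, tgt] >= 0 else -1.0
            p[m] += (sgn * np.sqrt(gain[m, tgt]) - p_par[m, tgt]) * dhat
            coeff[m] *= _HOP_SIGNS[slot] * np.sign(g[m, tgt]) * nohop_factor[m]
            pair[m, slot] = tgt
            hopped[m] = True
        stay = (~frozen) & (~hopped) & (g_tot > 0)
        coeff[stay] *= nohop_factor[stay]
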