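"""Per-mode Nose-Hoover chain (NHC) thermostats in extended phase space.

Each harmonic mode I gets its own deterministic thermostat chain
(eta_L, P_eta_L), L = 1..chain_length, regulating the mode's kinetic energy
toward a target temperature T(I).  Setting T(I) to the physical temperature
gives classical canonical sampling; setting T(I) = 1/beta_eff(beta, omega_I)
(see :mod:`qcdyn.statmech`) makes the classical-looking dynamics sample the
quantum Wigner variance of the mode, including zero-point motion.

The extended dynamics derives from an exactly antisymmetric structure matrix
B(X_e) acting on the gradient of the extended Hamiltonian

    H_e = H(X) + sum_IL P_eta_L^2 / (2 M_L) + sum_IL T(I) eta_L,

so H_e is a constant of motion (antisymmetry implies grad H . B grad H = 0).
For a chain of length 2 the equations of motion per mode are

    dR/dt     = P
    dP/dt     = F - P P_eta1 / M_1
    deta_L/dt = P_eta_L / M_L
    dP_eta1/dt = P^2 - T - P_eta1 P_eta2 / M_2
    dP_eta2/dt = P_eta1^2 / M_1 - T

(unit mode masses, k_B = 1; the standard P^2 - kT kinetic feedback).

Integration uses a time-reversible Trotter splitting: velocity Verlet on the
physical mode nested between half-step chain updates, the chain part composed
with 7-point Suzuki-Yoshida weights.  An optional 4th-order Yoshida
composition of the whole step is available for high-accuracy energy checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import MixedWeylSymbol, PhasePoint
from .statmech import ClassicalEnsemble

__all__ = [
    "NHCSpec",
    "ExtendedPoint",
    "extended_energy",
    "nhc_structure_matrix",
    "extended_eom",
    "integrate_nhc",
    "TrajectoryRecord",
]

# 7-point Suzuki-Yoshida composition weights (6th-order symmetric scheme)
_SY7 = np.array(
    [
        0.784513610879828,
        0.235573213359357,
        -1.17767998417887,
        1.3151863206839063,
        -1.17767998417887,
        0.235573213359357,
        0.784513610879828,
    ]
)

_PETA_GUARD = 1e8


@dataclass(frozen=True)
class NHCSpec:
    """Nose-Hoover chain settings.

    ``masses`` are the chain inertial parameters M_eta (scalar, per-link, or
    per-mode-per-link); ``targets`` the per-mode temperatures T(I) (k_B = 1).
    A good default mass scale is T(I)/omega_I^2 (chain responding on the
    mode's own period).
    """

    targets: np.ndarray
    masses: np.ndarray
    chain_length: int = 2

    def __post_init__(self):
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        targets = np.atleast_1d(np.asarray(self.targets, dtype=float))
        if np.any(targets <= 0):
            raise ValueError("all thermostat targets must be strictly positive")
        masses = np.asarray(self.masses, dtype=float)
        masses = np.broadcast_to(masses, (targets.size, self.chain_length)).copy()
        if np.any(masses <= 0):
            raise ValueError("all chain masses must be strictly positive")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "masses", masses)

    @property
    def n_modes(self) -> int:
        return self.targets.size

    @classmethod
    def for_modes(cls, omega, targets, tau: float | None = None, chain_length: int = 2):
        """Build a spec with masses M = T * tau^2, tau defaulting to 1/omega."""
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        targets = np.broadcast_to(np.asarray(targets, dtype=float), omega.shape)
        tau_arr = (1.0 / omega) if tau is None else np.broadcast_to(tau, omega.shape)
        masses = (targets * tau_arr**2)[:, None] * np.ones(chain_length)
        return cls(targets=targets, masses=masses, chain_length=chain_length)


@dataclass(frozen=True)
class ExtendedPoint:
    """Full extended phase-space point: physical (R, P) plus per-mode chain
    variables eta, P_eta of shape (n_modes, chain_length)."""

    point: PhasePoint
    eta: np.ndarray
    p_eta: np.ndarray

    def __post_init__(self):
        eta = np.atleast_2d(np.asarray(self.eta, dtype=float))
        p_eta = np.atleast_2d(np.asarray(self.p_eta, dtype=float))
        if eta.shape != p_eta.shape or eta.shape[0] != self.point.n_modes:
            raise ValueError("eta/p_eta must be (n_modes, chain_length) and congruent")
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "p_eta", p_eta)

    @property
    def chain_length(self) -> int:
        return self.eta.shape[1]


def _check_conform(ext: ExtendedPoint, nhc: NHCSpec) -> None:
    if ext.eta.shape != (nhc.n_modes, nhc.chain_length):
        raise ValueError(
            f"extended point chain shape {ext.eta.shape} does not conform to "
            f"NHC spec ({nhc.n_modes} modes, chain length {nhc.chain_length})"
        )
    if ext.point.n_modes != nhc.n_modes:
        raise ValueError("physical point and NHC spec disagree on mode count")


def extended_energy(
    ext: ExtendedPoint, symbol: MixedWeylSymbol, nhc: NHCSpec
) -> tuple[float, np.ndarray]:
    """Mixed Weyl symbol of the extended Hamiltonian, split into its scalar
    (classical + chain) part and its subsystem matrix part.

    scalar = sum_J (P_J^2 + omega_J^2 R_J^2)/2 + sum_IL P_eta^2/(2 M)
           + sum_IL T(I) eta_L;  matrix = h_s - sum couplings (the part of
    the symbol not proportional to the identity... reported as evaluated
    matrix minus the classical scalar times identity).
    """
    _check_conform(ext, nhc)
    full = symbol.evaluate(ext.point)
    classical = 0.5 * float(
        np.sum(ext.point.p**2) + np.sum(_symbol_omega(symbol) ** 2 * ext.point.r**2)
    )
    matrix = full - classical * np.eye(symbol.n)
    chain = 0.5 * np.sum(ext.p_eta**2 / nhc.masses) + np.sum(nhc.targets[:, None] * ext.eta)
    return classical + float(chain), matrix


def _symbol_omega(symbol: MixedWeylSymbol) -> np.ndarray:
    omega = getattr(symbol, "omega", None)
    if omega is None:
        raise TypeError("symbol must be assembled by assemble_hamiltonian (needs .omega)")
    return omega


def nhc_structure_matrix(ext: ExtendedPoint, nhc: NHCSpec) -> np.ndarray:
    """Antisymmetric structure matrix B(X_e) of the thermostatted flow.

    Coordinate ordering: [R_1..R_m, eta_(1,1)..eta_(m,L)] then the conjugate
    momenta in the same order.  The flow is dX_e/dt = B grad H_e; the
    symplectic pairing occupies the physical block, each mode momentum
    couples to its first chain link, and successive links couple to each
    other.  B = -B^T holds exactly at every point.
    """
    _check_conform(ext, nhc)
    m, L = nhc.n_modes, nhc.chain_length
    nq = m * (1 + L)  # coordinates: R's then flattened eta's (mode-major)
    dim = 2 * nq
    B = np.zeros((dim, dim))

    def qi_R(i):  # index of R_i
        return i

    def qi_eta(i, l):  # index of eta_(i,l)
        return m + i * L + l

    def pi(q):  # conjugate momentum index of coordinate q
        return nq + q

    for i in range(m):
        # symplectic pairing: dR/dt = dH/dP, dP/dt = -dH/dR (+thermostat)
        B[qi_R(i), pi(qi_R(i))] = 1.0
        B[pi(qi_R(i)), qi_R(i)] = -1.0
        for l in range(L):
            B[qi_eta(i, l), pi(qi_eta(i, l))] = 1.0
            B[pi(qi_eta(i, l)), qi_eta(i, l)] = -1.0
        # mode momentum <-> first chain link: friction -P * P_eta1/M_1
        P = ext.point.p[i]
        B[pi(qi_R(i)), pi(qi_eta(i, 0))] = -P
        B[pi(qi_eta(i, 0)), pi(qi_R(i))] = P
        # successive links: -P_eta_l * P_eta_(l+1)/M_(l+1) feedback
        for l in range(L - 1):
            B[pi(qi_eta(i, l)), pi(qi_eta(i, l + 1))] = -ext.p_eta[i, l]
            B[pi(qi_eta(i, l + 1)), pi(qi_eta(i, l))] = ext.p_eta[i, l]
    return B


def extended_eom(
    ext: ExtendedPoint,
    symbol: MixedWeylSymbol,
    nhc: NHCSpec,
    surface_force: np.ndarray,
) -> ExtendedPoint:
    """Time derivative of an extended point under the thermostatted flow.

    ``surface_force`` is the scalar classical force per mode supplied by the
    dynamics layer (adiabatic-surface or mean-field force, or simply
    -omega^2 R for uncoupled modes).
    """
    _check_conform(ext, nhc)
    F = np.asarray(surface_force, dtype=float)
    if F.shape != ext.point.r.shape:
        raise ValueError("surface_force must have one entry per mode")
    p, eta, peta = ext.point.p, ext.eta, ext.p_eta
    M, T = nhc.masses, nhc.targets
    dr = p.copy()
    dp = F - p * peta[:, 0] / M[:, 0]
    deta = peta / M
    dpeta = np.empty_like(peta)
    L = nhc.chain_length
    # G_1 = P^2 - T; G_l = P_eta_(l-1)^2/M_(l-1) - T
    dpeta[:, 0] = p**2 - T
    if L > 1:
        dpeta[:, 1:] = peta[:, :-1] ** 2 / M[:, :-1] - T[:, None]
        dpeta[:, :-1] -= peta[:, :-1] * peta[:, 1:] / M[:, 1:]
    return ExtendedPoint(point=PhasePoint(r=dr, p=dp), eta=deta, p_eta=dpeta)


def _nhc_half_step(p, eta, peta, masses, targets, dt_half):
    """Reversible Suzuki-Yoshida chain update over time dt_half, rescaling
    the physical momenta.  Arrays: p (..., m); eta/peta (..., m, L);
    masses (m, L); targets (m,).  Operates in place."""
    L = peta.shape[-1]
    kin = p * p  # 2*K per mode (unit mass, one DOF per thermostat)
    err = np.errstate(over="ignore", invalid="ignore")
    err.__enter__()
    for w in _SY7:
        delta = w * dt_half
        G_last = (peta[..., L - 2] ** 2 / masses[:, L - 2] - targets) if L > 1 else kin - targets
        peta[..., L - 1] += 0.5 * delta * G_last
        for l in range(L - 2, -1, -1):
            s = np.exp(-0.25 * delta * peta[..., l + 1] / masses[:, l + 1])
            G = kin - targets if l == 0 else peta[..., l - 1] ** 2 / masses[:, l - 1] - targets
            peta[..., l] = s * (s * peta[..., l] + 0.5 * delta * G)
        scale = np.exp(-delta * peta[..., 0] / masses[:, 0])
        p *= scale
        kin *= scale * scale
        eta += delta * peta / masses
        for l in range(L - 1):
            s = np.exp(-0.25 * delta * peta[..., l + 1] / masses[:, l + 1])
            G = kin - targets if l == 0 else peta[..., l - 1] ** 2 / masses[:, l - 1] - targets
            peta[..., l] = s * (s * peta[..., l] + 0.5 * delta * G)
        G_last = (peta[..., L - 2] ** 2 / masses[:, L - 2] - targets) if L > 1 else kin - targets
        peta[..., L - 1] += 0.5 * delta * G_last
    err.__exit__(None, None, None)
    if not np.all(np.isfinite(peta)) or np.any(np.abs(peta) > _PETA_GUARD):
        raise RuntimeError(
            "chain momentum exceeded overflow guard (1e8): the time step is "
            "unstable for these chain masses; reduce dt"
        )


@dataclass
class TrajectoryRecord:
    """Snapshots recorded along a thermostatted run."""

    times: np.ndarray
    r: np.ndarray  # (n_snapshots, n_samples, n_modes)
    p: np.ndarray
    energy: np.ndarray | None = None  # scalar extended energy per snapshot/sample


def _ensemble_energy(ens: ClassicalEnsemble, nhc: NHCSpec | None) -> np.ndarray:
    e = 0.5 * np.sum(ens.p**2 + ens.omega**2 * ens.r**2, axis=1)
    if nhc is not None:
        e = e + 0.5 * np.sum(ens.p_eta**2 / nhc.masses, axis=(1, 2))
        e = e + np.sum(nhc.targets[None, :, None] * ens.eta, axis=(1, 2))
    return e


_W1_Y4 = 1.0 / (2.0 - 2.0 ** (1.0 / 3.0))
_YOSHIDA4 = np.array([_W1_Y4, 1.0 - 2.0 * _W1_Y4, _W1_Y4])


def integrate_nhc(
    ensemble: ClassicalEnsemble,
    symbol: MixedWeylSymbol | None,
    nhc: NHCSpec | None,
    dt: float,
    n_steps: int,
    force=None,
    record_stride: int | None = None,
    record_energy: bool = False,
    order: int = 2,
) -> tuple[ClassicalEnsemble, TrajectoryRecord | None]:
    """Advance every ensemble member under (thermostatted) mode dynamics.

    ``nhc=None`` detaches the thermostats (plain symplectic velocity
    Verlet).  ``force(r)`` overrides the default harmonic force -omega^2 R;
    it is required when the symbol carries nonzero couplings, because the
    classical back-reaction then depends on the dynamics scheme (adiabatic
    surface, mean field) chosen by the caller.

    ``order=4`` composes the basic reversible step with Yoshida weights for
    high-accuracy energy conservation checks.  Deterministic for a given
    ensemble and step parameters.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if order not in (2, 4):
        raise ValueError("order must be 2 or 4")
    omega2 = ensemble.omega**2
    if force is None:
        coup = getattr(symbol, "coupling", None) if symbol is not None else None
        if coup is not None and np.any(coup != 0):
            raise ValueError(
                "symbol has nonzero couplings: supply an explicit force callable "
                "(the dynamics layer decides the quantum back-reaction)"
            )
        force = lambda r: -omega2 * r  # noqa: E731

    r = ensemble.r.copy()
    p = ensemble.p.copy()
    eta = ensemble.eta.copy()
    peta = ensemble.p_eta.copy()

    substeps = _YOSHIDA4 * dt if order == 4 else np.array([dt])

    rec_t, rec_r, rec_p, rec_e = [], [], [], []

    def snapshot(t):
        rec_t.append(t)
        rec_r.append(r.copy())
        rec_p.append(p.copy())
        if record_energy:
            ens_now = replace(ensemble, r=r, p=p, eta=eta, p_eta=peta)
            rec_e.append(_ensemble_energy(ens_now, nhc))

    if record_stride:
        snapshot(ensemble.time)

    f_now = force(r)
    for step in range(1, n_steps + 1):
        for h in substeps:
            if nhc is not None:
                _nhc_half_step(p, eta, peta, nhc.masses, nhc.targets, 0.5 * h)
            p += 0.5 * h * f_now
            r += h * p
            f_now = force(r)
            p += 0.5 * h * f_now
            if nhc is not None:
                _nhc_half_step(p, eta, peta, nhc.masses, nhc.targets, 0.5 * h)
        if record_stride and step % record_stride == 0:
            snapshot(ensemble.time + step * dt)

    out = replace(
        ensemble, r=r, p=p, eta=eta, p_eta=peta, time=ensemble.time + n_steps * dt
    )
    record = None
    if record_stride:
        record = TrajectoryRecord(
            times=np.array(rec_t),
            r=np.array(rec_r),
            p=np.array(rec_p),
            energy=np.array(rec_e) if record_energy else None,
        )
    return out, record
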