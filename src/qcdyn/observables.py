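"""Quantum-classical averages, correlation functions, and response spectra.

An observable symbol is O(X) = O_matrix + o_cl(X) * I: a Hermitian subsystem
matrix plus a configurable scalar function of the classical phase point.
Averages are the trace-times-phase-space integral

    <O(t)> = Tr' int dX W(X; t) O(X, t),

implemented as grid quadrature for grid states and as an ensemble mean for
trajectory ensembles.  Correlation functions keep the literal operator order
<O1(t) O2> = Tr' int dX W O1(t) O2 and are complex in general; a symmetrized
(Kubo-style real-part) variant is available on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dynamics import GridState, SurfaceHoppingEnsemble, _batched_eigh
from .model import HamiltonianSymbol
from .statmech import ClassicalEnsemble
from .thermostat import TrajectoryRecord

__all__ = [
    "ObservableSpec",
    "qc_average",
    "qc_correlation",
    "grid_pair_average",
    "ensemble_average_series",
    "response_spectrum",
    "SpectrumResult",
]


@dataclass(frozen=True)
class ObservableSpec:
    """O(X) = matrix_part + classical_part(r, p) * Identity.

    ``classical_part`` maps coordinate/momentum arrays (broadcastable over
    members) to a scalar field; ``None`` means no classical part.
    """

    matrix_part: np.ndarray
    classical_part: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    name: str = "O"

    def __post_init__(self):
        mat = np.asarray(self.matrix_part, dtype=complex)
        if not np.allclose(mat, mat.conj().T, atol=1e-12 * max(1.0, np.abs(mat).max())):
            raise ValueError("matrix_part must be Hermitian")
        object.__setattr__(self, "matrix_part", mat)

    @property
    def n(self) -> int:
        return self.matrix_part.shape[0]


def _grid_observable_field(state: GridState, obs: ObservableSpec) -> np.ndarray:
    field = np.broadcast_to(
        obs.matrix_part, state.rho.shape[:2] + obs.matrix_part.shape
    ).copy()
    if obs.classical_part is not None:
        R, P = np.meshgrid(state.grid.r, state.grid.p, indexing="ij")
        # classical parts take a trailing mode axis (single mode on the grid)
        field += obs.classical_part(R[..., None], P[..., None])[:, :, None, None] * np.eye(obs.n)
    return field


def qc_average(state_or_ensemble, obs: ObservableSpec, t_index: int | None = None):
    """<O> for a grid state, a surface-hopping ensemble, or a thermostatted
    classical record.

    * ``GridState`` (kind 'state'): quadrature of Tr[W(X) O(X)]; the state
      must be normalized (trace functional within 1e-6 of one).
    * ``SurfaceHoppingEnsemble``: ensemble-mean estimator at snapshot
      ``t_index`` (or the full time series when ``t_index`` is None);
      returns (value, standard_error) per time.
    * ``(ClassicalEnsemble | TrajectoryRecord)``: classical-part mean times
      Tr[matrix_part]/n-like reduction is not defined; use classical
      observables with ``ensemble_average_series`` instead.
    """
    if isinstance(state_or_ensemble, GridState):
        state = state_or_ensemble
        if state.kind != "state":
            raise ValueError(
                "qc_average on a grid needs a statistical symbol; for a "
                "Heisenberg-evolved observable use grid_pair_average"
            )
        from .dynamics import trace_functional

        norm = trace_functional(state)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"state is not normalized: trace functional = {norm}")
        field = _grid_observable_field(state, obs)
        val = np.einsum("xyij,xyji->", state.rho, field) * state.grid.cell
        return float(val.real)
    if isinstance(state_or_ensemble, SurfaceHoppingEnsemble):
        series, err = ensemble_average_series(state_or_ensemble, obs)
        if t_index is None:
            return series, err
        return series[t_index], err[t_index]
    raise TypeError(f"unsupported input {type(state_or_ensemble).__name__}")


def grid_pair_average(obs_state: GridState, w_state: GridState) -> float:
    """Tr' int dX O(X, t) W(X): pairing of a Heisenberg-evolved observable
    grid with a (static) statistical grid. Used for observable-vs-state
    duality checks."""
    if obs_state.kind != "observable" or w_state.kind != "state":
        raise ValueError("need an 'observable' grid and a 'state' grid")
    val = np.einsum("xyij,xyji->", w_state.rho, obs_state.rho) * obs_state.grid.cell
    return float(val.real)


def _sh_contributions(
    ens: SurfaceHoppingEnsemble, symbol: HamiltonianSymbol, obs: ObservableSpec, k: int,
    init_factor: np.ndarray,
) -> np.ndarray:
    """Per-member complex contributions at snapshot k (trajectory gauge)."""
    r, p = ens.r[k], ens.p[k]
    pair = ens.pair[k]
    basis = ens.basis[k]
    o_ad = np.einsum("Nki,kl,Nlm->Nim", basis.conj(), obs.matrix_part, basis)
    idx = np.arange(ens.n_members)
    elem = o_ad[idx, pair[:, 0], pair[:, 1]]
    if obs.classical_part is not None:
        diag = pair[:, 0] == pair[:, 1]
        elem = elem + obs.classical_part(r, p) * diag
    return init_factor * ens.coeff[k] * elem


def ensemble_average_series(
    ens: SurfaceHoppingEnsemble,
    obs: ObservableSpec,
    symbol: HamiltonianSymbol | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time series of <O(t)> with Monte-Carlo standard errors."""
    symbol = symbol if symbol is not None else ens.symbol
    n_t = ens.times.size
    N = ens.n_members
    vals = np.empty(n_t)
    errs = np.empty(n_t)
    for k in range(n_t):
        c = _sh_contributions(ens, symbol, obs, k, ens.init_factor).real
        vals[k] = c.mean()
        errs[k] = c.std(ddof=1) / np.sqrt(N)
    return vals, errs


def classical_average_series(
    record: TrajectoryRecord, func: Callable[[np.ndarray, np.ndarray], np.ndarray]
) -> np.ndarray:
    """Ensemble mean of a classical phase function along a thermostatted
    record (snapshots x members x modes)."""
    return np.array([func(record.r[k], record.p[k]).mean() for k in range(record.times.size)])


def qc_correlation(
    ens: SurfaceHoppingEnsemble,
    obs1: ObservableSpec,
    obs2: ObservableSpec,
    symbol: HamiltonianSymbol | None = None,
    symmetrized: bool = False,
) -> np.ndarray:
    """C(t) = <O1(t) O2> estimated on a surface-hopping ensemble.

    O2 is attached at t = 0 by replacing the member's initial statistical
    factor with n^2 (O2(X0) w_S)_{b0 a0} in the adiabatic basis at the
    initial phase point; O1 is evaluated along the evolved pair.  Literal
    operator order (O1(t) left-multiplies O2); ``symmetrized`` returns the
    real part (Kubo-style symmetrization of an autocorrelation).
    """
    symbol = symbol if symbol is not None else ens.symbol
    if obs1.n != obs2.n or obs1.n != ens.w_s.shape[0]:
        raise ValueError("observable and subsystem dimensions disagree")
    r0, p0 = ens.r[0], ens.p[0]
    pair0 = ens.pair[0]
    n = ens.w_s.shape[0]
    basis0 = ens.basis[0]
    o2_full = np.broadcast_to(obs2.matrix_part, (ens.n_members, n, n)).copy()
    if obs2.classical_part is not None:
        o2_full += obs2.classical_part(r0, p0)[:, None, None] * np.eye(n)
    o2w = np.einsum("Nij,jk->Nik", o2_full, ens.w_s)
    o2w_ad = np.einsum("Nki,Nkl,Nlm->Nim", basis0.conj(), o2w, basis0)
    idx = np.arange(ens.n_members)
    factor = (n * n) * o2w_ad[idx, pair0[:, 1], pair0[:, 0]]
    n_t = ens.times.size
    out = np.empty(n_t, dtype=complex)
    for k in range(n_t):
        out[k] = _sh_contributions(ens, symbol, obs1, k, factor).mean()
    return out.real if symmetrized else out


@dataclass(frozen=True)
class SpectrumResult:
    """Discrete Fourier transform of a correlation function."""

    freq: np.ndarray
    spectrum: np.ndarray
    window: str
    peak_freq: float

    def __iter__(self):
        return iter((self.freq, self.spectrum))


def response_spectrum(
    correlation: np.ndarray, time_grid: np.ndarray, window: str = "hann"
) -> SpectrumResult:
    """DFT of a correlation time series on a uniform grid.

    Returns angular frequencies, the windowed transform, and the dominant
    peak location |omega| (window and normalization recorded on the result).
    """
    time_grid = np.asarray(time_grid, dtype=float)
    dt = np.diff(time_grid)
    if time_grid.size < 2 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time grid must be uniform")
    c = np.asarray(correlation)
    if window == "hann":
        w = np.hanning(c.size)
    elif window in (None, "none", "rect"):
        w = np.ones(c.size)
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.fftshift(np.fft.fft(c * w)) * dt[0]
    freq = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(c.size, d=dt[0]))
    if np.abs(spec).max() == 0:
        peak = 0.0
    else:
        peak = float(abs(freq[int(np.argmax(np.abs(spec)))]))
    return SpectrumResult(freq=freq, spectrum=spec, window=str(window), peak_freq=peak)
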