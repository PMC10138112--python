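"""Ohmic bath discretization for the harmonic mode banks.

A continuum Ohmic spectral density with exponential cutoff,

    J(omega) = (pi/2) xi omega exp(-omega / omega_c),

is represented by N discrete modes via the logarithmic (equal reorganization
energy) rule

    omega_j = -omega_c ln(1 - (j - 1/2)/N),      j = 1..N,
    c_j     = omega_j sqrt(2 xi omega_c / N),

i.e. frequencies sample the normalized density exp(-omega/omega_c)/omega_c
at midpoint quantiles and every mode carries the same share of the
reorganization energy: sum_j c_j^2 / (2 omega_j^2) = xi omega_c exactly, for
every N, matching the continuum integral (1/pi) int 2 J(omega)/omega domega.
Deterministic: the same parameters always give the same bank.
"""

from __future__ import annotations

import numpy as np

from .model import OscillatorBank

__all__ = ["ohmic_bath", "reorganization_energy"]


def ohmic_bath(
    n_modes: int, xi: float, omega_c: float, kind: str = "phonon"
) -> OscillatorBank:
    """Discretize an Ohmic bath into an :class:`OscillatorBank`.

    Parameters
    ----------
    n_modes : number of discrete modes (>= 1).
    xi : dimensionless Kondo/friction parameter (>= 0); xi = 0 gives a
        decoupled bank.
    omega_c : exponential cutoff frequency (> 0).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if not omega_c > 0:
        raise ValueError("omega_c must be > 0")
    j = np.arange(1, n_modes + 1)
    omega = -omega_c * np.log1p(-(j - 0.5) / n_modes)
    coupling = omega * np.sqrt(2.0 * xi * omega_c / n_modes)
    return OscillatorBank(kind=kind, omega=omega, coupling=coupling)


def reorganization_energy(bank: OscillatorBank) -> float:
    """Discrete reorganization energy sum_j c_j^2 / (2 omega_j^2)."""
    return float(np.sum(bank.coupling**2 / (2.0 * bank.omega**2)))
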