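"""Thermal and zero-point Wigner statistics of the harmonic mode banks.

The thermal Wigner function of a harmonic mode of frequency omega at inverse
temperature beta is a Gaussian in (R, P) whose momentum variance is

    <P^2> = omega / (2 tanh(beta omega / 2)) = 1 / beta_eff(beta, omega)

with the *effective inverse temperature*

    beta_eff = 2 tanh(beta omega / 2) / omega.

beta_eff interpolates between the classical limit (beta_eff -> beta as
beta*omega -> 0) and the zero-point limit (beta_eff -> 2/omega as T -> 0,
i.e. <P^2/2> -> omega/4 per quadrature).  Thermostatting a mode at the
target temperature T = 1/beta_eff makes otherwise-classical trajectories
sample the quantum thermal variance, including zero-point motion.

Each mode's Wigner weight is normalized to unit integral over (R, P):
W_beta(R, P) = (tanh(beta omega/2)/pi) exp(-beta_eff (P^2/2 + omega^2 R^2/2))
in hbar = 1 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import OscillatorBank

__all__ = [
    "ThermalSpec",
    "effective_beta",
    "wigner_thermal_moments",
    "sample_initial_conditions",
    "ClassicalEnsemble",
]

_REGIMES = ("classical", "thermal_wigner", "zero_point")


@dataclass(frozen=True)
class ThermalSpec:
    """Thermal state specification for the mode banks.

    ``beta`` is the physical inverse temperature (k_B = 1); ``math.inf`` is
    the explicit T = 0 flag.  ``regime`` selects classical Maxwell-Boltzmann
    variances, thermal Wigner variances, or the zero-point (beta = inf)
    Wigner variances.
    """

    beta: float = math.inf
    regime: str = "thermal_wigner"

    def __post_init__(self):
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}, got {self.regime!r}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be positive (math.inf allowed), got {self.beta}")
        if self.regime in ("classical", "thermal_wigner") and math.isinf(self.beta):
            if self.regime == "classical":
                raise ValueError("classical regime requires finite beta")

    @property
    def is_zero_temperature(self) -> bool:
        return math.isinf(self.beta) or self.regime == "zero_point"


def effective_beta(beta: float, omega) -> np.ndarray | float:
    """Per-mode effective inverse temperature 2 tanh(beta omega/2)/omega.

    ``beta = math.inf`` (zero temperature) gives the zero-point value
    2/omega.  Strictly decreasing in omega at fixed finite beta and bounded
    by min(beta, 2/omega).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    if math.isinf(beta):
        out = 2.0 / omega
    else:
        if not beta > 0:
            raise ValueError(f"beta must be positive, got {beta}")
        out = 2.0 * np.tanh(0.5 * beta * omega) / omega
    return out if out.ndim else float(out)


def wigner_thermal_moments(beta: float, omega) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Variances (var_r, var_p) of the thermal Wigner Gaussian of a mode.

    var_p = 1/beta_eff = omega/(2 tanh(beta omega/2)); var_r = var_p/omega^2.
    At beta = inf these are the zero-point variances (omega/4 of energy per
    quadrature); as beta*omega -> 0 they collapse to the classical 1/beta
    and 1/(beta omega^2).
    """
    omega = np.asarray(omega, dtype=float)
    var_p = 1.0 / effective_beta(beta, omega)
    var_r = var_p / omega**2
    if np.ndim(var_p) == 0:
        return float(var_r), float(var_p)
    return var_r, var_p


def _mode_variances(banks, thermal: ThermalSpec) -> tuple[np.ndarray, np.ndarray]:
    omega = np.concatenate([b.omega for b in banks]) if banks else np.empty(0)
    if thermal.regime == "classical":
        var_p = np.full(omega.shape, 1.0 / thermal.beta)
        var_r = var_p / omega**2
    else:
        beta = math.inf if thermal.regime == "zero_point" else thermal.beta
        var_r, var_p = wigner_thermal_moments(beta, omega)
    return np.atleast_1d(var_r), np.atleast_1d(var_p)


@dataclass
class ClassicalEnsemble:
    """A seeded ensemble of classical extended-phase-space points.

    Arrays are (n_samples, n_modes); the Nose-Hoover chain variables
    ``eta`` / ``p_eta`` are (n_samples, n_modes, chain_length) and are all
    zero in a freshly sampled slice (delta-function initial conditions of
    the extended-space statistical symbol).
    """

    r: np.ndarray
    p: np.ndarray
    eta: np.ndarray
    p_eta: np.ndarray
    omega: np.ndarray
    seed: int | None = None
    time: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.r.shape[0]

    @property
    def n_modes(self) -> int:
        return self.r.shape[1]


def sample_initial_conditions(
    banks,
    thermal: ThermalSpec,
    n_samples: int,
    seed: int,
    chain_length: int = 2,
) -> ClassicalEnsemble:
    """Draw seeded initial conditions for the mode banks.

    Per mode, (R, P) are independent zero-mean Gaussians with the Wigner
    (or classical) variances; the NHC variables start at exactly zero.
    The same seed reproduces the ensemble bit-for-bit.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(banks, OscillatorBank):
        banks = [banks]
    var_r, var_p = _mode_variances(banks, thermal)
    omega = np.concatenate([b.omega for b in banks]) if banks else np.empty(0)
    n_modes = omega.size
    rng = np.random.default_rng(seed)
    r = rng.standard_normal((n_samples, n_modes)) * np.sqrt(var_r)
    p = rng.standard_normal((n_samples, n_modes)) * np.sqrt(var_p)
    zeros = np.zeros((n_samples, n_modes, chain_length))
    return ClassicalEnsemble(
        r=r, p=p, eta=zeros.copy(), p_eta=zeros.copy(), omega=omega.copy(), seed=seed
    )
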