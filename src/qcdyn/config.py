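"""Run configuration: TOML parsing, validation, and serialization.

The config dialect is TOML with matrices written as nested arrays of reals
(separate ``real``/``imag`` blocks for complex matrices).  All validation
failures are collected and reported together with their key paths.

Sections: ``model`` (subsystem matrices and mode banks), ``statmech``
(temperature regime, sample count, seed), ``thermostat`` (NHC settings),
``dynamics`` (solver choice and step parameters), ``observables`` (list of
named matrix + classical-part observables), ``output`` (paths/formats).
"""

from __future__ import annotations

import io
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .model import OscillatorBank, SubsystemSpec
from .observables import ObservableSpec
from .statmech import ThermalSpec
from .thermostat import NHCSpec

__all__ = ["RunConfig", "load_config", "parse_config", "serialize_config", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration failures, each tagged with its key path."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


# named classical parts for observables; inputs are (..., n_modes) arrays,
# the mode axis is reduced
CLASSICAL_PARTS = {
    "none": None,
    "r": lambda r, p: np.sum(r, axis=-1),
    "p": lambda r, p: np.sum(p, axis=-1),
    "r_squared": lambda r, p: np.sum(r * r, axis=-1),
    "p_squared": lambda r, p: np.sum(p * p, axis=-1),
    "kinetic": lambda r, p: 0.5 * np.sum(p * p, axis=-1),
}


@dataclass
class DynamicsConfig:
    solver: str = "trajectory"  # grid | trajectory | classical
    dt: float = 0.01
    n_steps: int = 100
    record_stride: int = 1
    hop_mode: str = "nonadiabatic"
    grid_points: tuple[int, int] = (96, 96)
    extent_sigmas: float = 6.0
    r_shift: float = 0.0
    order: int = 2


@dataclass
class ThermostatConfig:
    enabled: bool = False
    chain_length: int = 2
    mode: str = "thermal"  # thermal | zero_point | explicit
    targets: list[float] | None = None  # for mode == explicit
    tau: float | None = None


@dataclass
class OutputConfig:
    directory: str = "qcdyn_out"
    formats: list[str] = field(default_factory=lambda: ["csv"])


@dataclass
class RunConfig:
    """Validated run configuration (typed views plus the raw table)."""

    subsystem: SubsystemSpec
    phonons: OscillatorBank
    em: OscillatorBank
    thermal: ThermalSpec
    n_samples: int
    seed: int
    w_s: np.ndarray
    thermostat: ThermostatConfig
    dynamics: DynamicsConfig
    observables: list[ObservableSpec]
    observable_names: list[str]
    output: OutputConfig
    raw: dict[str, Any] = field(repr=False, default_factory=dict)

    def nhc_spec(self) -> NHCSpec | None:
        """Materialize the NHC settings against the configured banks."""
        if not self.thermostat.enabled:
            return None
        from .statmech import effective_beta

        omega = np.concatenate([self.phonons.omega, self.em.omega])
        if self.thermostat.mode == "thermal":
            if math.isinf(self.thermal.beta):
                raise ConfigError(
                    ["thermostat.mode: 'thermal' requires finite statmech.beta"]
                )
            targets = np.full(omega.shape, 1.0 / self.thermal.beta)
        elif self.thermostat.mode == "zero_point":
            beta = self.thermal.beta if self.thermal.regime == "thermal_wigner" else math.inf
            targets = 1.0 / effective_beta(beta, omega)
        else:
            targets = np.asarray(self.thermostat.targets, dtype=float)
        return NHCSpec.for_modes(
            omega, targets, tau=self.thermostat.tau,
            chain_length=self.thermostat.chain_length,
        )


def _matrix(table, path, errors, n=None, default=None) -> np.ndarray | None:
    if table is None:
        return default
    real = table.get("real")
    if real is None:
        errors.append(f"{path}.real: missing")
        return default
    try:
        mat = np.array(real, dtype=float)
        imag = table.get("imag")
        if imag is not None:
            mat = mat + 1j * np.array(imag, dtype=float)
    except (ValueError, TypeError) as exc:
        errors.append(f"{path}: not a numeric matrix ({exc})")
        return default
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        errors.append(f"{path}: must be a square matrix, got shape {mat.shape}")
        return default
    if n is not None and mat.shape[0] != n:
        errors.append(f"{path}: must be {n}x{n}, got {mat.shape[0]}x{mat.shape[0]}")
        return default
    if not np.allclose(mat, mat.conj().T, atol=1e-12 * max(1.0, np.abs(mat).max())):
        errors.append(f"{path}: matrix is not Hermitian")
        return default
    return mat


def _bank(table, kind, errors) -> OscillatorBank:
    path = f"model.banks.{kind}"
    if table is None:
        return OscillatorBank.empty(kind)
    omega = table.get("omega", [])
    coupling = table.get("coupling", [])
    if len(omega) != len(coupling):
        errors.append(f"{path}: omega and coupling lengths differ "
                      f"({len(omega)} vs {len(coupling)})")
        return OscillatorBank.empty(kind)
    for i, w in enumerate(omega):
        if not w > 0:
            errors.append(f"{path}.omega[{i}]: must be > 0, got {w}")
            return OscillatorBank.empty(kind)
    if not omega:
        return OscillatorBank.empty(kind)
    return OscillatorBank(kind=kind, omega=np.array(omega, float),
                          coupling=np.array(coupling, float))


def parse_config(text: str) -> RunConfig:
    """Parse and validate a TOML configuration string."""
    data = tomllib.loads(text)
    errors: list[str] = []

    mtab = data.get("model", {})
    h_s = _matrix(mtab.get("h_s"), "model.h_s", errors)
    if h_s is None and "model.h_s.real: missing" not in errors:
        errors.append("model.h_s: missing")
    n = h_s.shape[0] if h_s is not None else None
    chi = _matrix(mtab.get("chi"), "model.chi", errors, n=n)
    zeta = _matrix(mtab.get("zeta"), "model.zeta", errors, n=n)
    banks = mtab.get("banks", {})
    phonons = _bank(banks.get("phonon"), "phonon", errors)
    em = _bank(banks.get("em"), "em", errors)

    stab = data.get("statmech", {})
    beta_raw = stab.get("beta", "inf")
    beta = math.inf if beta_raw in ("inf", "infinite") else beta_raw
    regime = stab.get("regime", "zero_point" if math.isinf(beta) else "thermal_wigner")
    thermal = None
    try:
        thermal = ThermalSpec(beta=float(beta), regime=regime)
    except (ValueError, TypeError) as exc:
        errors.append(f"statmech: {exc}")
    n_samples = stab.get("n_samples", 1000)
    if not (isinstance(n_samples, int) and n_samples >= 1):
        errors.append(f"statmech.n_samples: must be a positive integer, got {n_samples}")
    seed = stab.get("seed", 0)

    sub = None
    w_s = None
    if h_s is not None and chi is not None:
        try:
            sub = SubsystemSpec(h_s=h_s, chi=chi, zeta=zeta)
        except ValueError as exc:
            errors.append(f"model: {exc}")
        w_s = _matrix(stab.get("w_s"), "statmech.w_s", errors, n=n)
        if w_s is None and sub is not None:
            # default: pure ground state of h_s
            _, vecs = np.linalg.eigh(sub.h_s)
            g = vecs[:, 0]
            w_s = np.outer(g, g.conj())
        if w_s is not None:
            if abs(np.trace(w_s).real - 1.0) > 1e-10:
                errors.append(f"statmech.w_s: trace must be 1, got {np.trace(w_s).real}")
            elif np.linalg.eigvalsh(w_s).min() < -1e-12:
                errors.append("statmech.w_s: density matrix must be positive semidefinite")

    ttab = data.get("thermostat", {})
    thermostat = ThermostatConfig(
        enabled=ttab.get("enabled", False),
        chain_length=ttab.get("chain_length", 2),
        mode=ttab.get("mode", "thermal"),
        targets=ttab.get("targets"),
        tau=ttab.get("tau"),
    )
    if thermostat.mode not in ("thermal", "zero_point", "explicit"):
        errors.append(f"thermostat.mode: unknown mode {thermostat.mode!r}")
    if thermostat.mode == "explicit" and not thermostat.targets:
        errors.append("thermostat.targets: required for mode = 'explicit'")
    if thermostat.chain_length < 1:
        errors.append("thermostat.chain_length: must be >= 1")

    dtab = data.get("dynamics", {})
    dynamics = DynamicsConfig(
        solver=dtab.get("solver", "trajectory"),
        dt=dtab.get("dt", 0.01),
        n_steps=dtab.get("n_steps", 100),
        record_stride=dtab.get("record_stride", 1),
        hop_mode=dtab.get("hop_mode", "nonadiabatic"),
        grid_points=tuple(dtab.get("grid_points", (96, 96))),
        extent_sigmas=dtab.get("extent_sigmas", 6.0),
        r_shift=dtab.get("r_shift", 0.0),
        order=dtab.get("order", 2),
    )
    if dynamics.solver not in ("grid", "trajectory", "classical"):
        errors.append(f"dynamics.solver: unknown solver {dynamics.solver!r}")
    if not dynamics.dt > 0:
        errors.append(f"dynamics.dt: must be > 0, got {dynamics.dt}")
    if dynamics.hop_mode not in ("adiabatic_only", "nonadiabatic"):
        errors.append(f"dynamics.hop_mode: unknown mode {dynamics.hop_mode!r}")

    observables: list[ObservableSpec] = []
    names: list[str] = []
    for k, otab in enumerate(data.get("observables", [])):
        path = f"observables[{k}]"
        name = otab.get("name", f"obs{k}")
        cname = otab.get("classical", "none")
        if cname not in CLASSICAL_PARTS:
            errors.append(f"{path}.classical: unknown function {cname!r} "
                          f"(choose from {sorted(CLASSICAL_PARTS)})")
            continue
        mat = _matrix(otab.get("matrix"), f"{path}.matrix", errors, n=n)
        if mat is None:
            if n is None:
                continue
            mat = np.zeros((n, n))
        try:
            observables.append(
                ObservableSpec(matrix_part=mat, classical_part=CLASSICAL_PARTS[cname],
                               name=name)
            )
            names.append(name)
        except ValueError as exc:
            errors.append(f"{path}: {exc}")

    otab = data.get("output", {})
    output = OutputConfig(
        directory=otab.get("directory", "qcdyn_out"),
        formats=list(otab.get("formats", ["csv"])),
    )

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        subsystem=sub, phonons=phonons, em=em, thermal=thermal,
        n_samples=n_samples, seed=seed, w_s=w_s, thermostat=thermostat,
        dynamics=dynamics, observables=observables, observable_names=names,
        output=output, raw=data,
    )


def load_config(path: str | Path) -> RunConfig:
    """Read, parse and validate a TOML configuration file."""
    return parse_config(Path(path).read_text())


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if math.isinf(v):
            return '"inf"'
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__}")


def _emit_table(buf: io.StringIO, name: str, table: dict, array_of_tables=False):
    header = f"[[{name}]]" if array_of_tables else f"[{name}]"
    scalars = {k: v for k, v in table.items() if not isinstance(v, (dict, list)) or
               (isinstance(v, list) and not any(isinstance(x, dict) for x in v))}
    subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
    tablelists = {k: v for k, v in table.items()
                  if isinstance(v, list) and any(isinstance(x, dict) for x in v)}
    buf.write(header + "\n")
    for k, v in scalars.items():
        buf.write(f"{k} = {_toml_value(v)}\n")
    buf.write("\n")
    for k, v in subtables.items():
        _emit_table(buf, f"{name}.{k}", v)
    for k, lst in tablelists.items():
        for item in lst:
            _emit_table(buf, f"{name}.{k}", item, array_of_tables=True)


def serialize_config(config: RunConfig) -> str:
    """Serialize back to TOML; parse(serialize(parse(text))) is stable."""
    buf = io.StringIO()
    top_scalars = {k: v for k, v in config.raw.items() if not isinstance(v, (dict, list))}
    for k, v in top_scalars.items():
        buf.write(f"{k} = {_toml_value(v)}\n")
    for k, v in config.raw.items():
        if isinstance(v, dict):
            _emit_table(buf, k, v)
        elif isinstance(v, list) and v and isinstance(v[0], dict):
            for item in v:
                _emit_table(buf, k, item, array_of_tables=True)
    return buf.getvalue()
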