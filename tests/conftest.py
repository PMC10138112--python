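import numpy as np
import pytest

from qcdyn.model import OscillatorBank, SubsystemSpec, assemble_hamiltonian

SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]])
SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]])
SIGMA_Z = np.diag([1.0, -1.0])


@pytest.fixture
def pauli():
    return {"x": SIGMA_X, "y": SIGMA_Y, "z": SIGMA_Z, "i": np.eye(2)}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def spin_boson_symbol():
    """Two-level system (gap 2, sigma_x) coupled through sigma_z to one
    mode (omega = 1, c = 0.2)."""
    sub = SubsystemSpec(h_s=SIGMA_X, chi=SIGMA_Z)
    bank = OscillatorBank("phonon", [1.0], [0.2])
    return assemble_hamiltonian(sub, bank)


@pytest.fixture
def uncoupled_symbol():
    """Single uncoupled harmonic mode under a trivial 1-level subsystem."""
    sub = SubsystemSpec(h_s=np.zeros((1, 1)), chi=np.zeros((1, 1)))
    bank = OscillatorBank("phonon", [1.0], [0.0])
    return assemble_hamiltonian(sub, bank)


def random_subsystem(rng, n, complex_valued=False):
    a = rng.standard_normal((3, n, n))
    if complex_valued:
        a = a + 1j * rng.standard_normal((3, n, n))
    h_s, chi, zeta = [(m + m.conj().T) / 2 for m in a]
    return SubsystemSpec(h_s=h_s, chi=chi, zeta=zeta)


def random_banks(rng, n_ph, n_em):
    ph = OscillatorBank("phonon", rng.uniform(0.3, 2.0, n_ph), rng.normal(0, 0.5, n_ph))
    em = OscillatorBank("em", rng.uniform(0.3, 2.0, n_em), rng.normal(0, 0.5, n_em))
    return ph, em
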