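"""Shared fixtures and an independent brute-force matrix oracle.

The oracle builds the circuit unitaries and noise channels from first
principles — explicit Kronecker products and the Pauli-twirl (Kraus)
form of the depolarizing channel — without touching the package's
simulator internals, so agreement between the two routes is meaningful.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

ASPIRIN = "CC(=O)OC1=CC=CC=C1C(=O)O"
BUTANE = "CCCC"

I2 = np.eye(2, dtype=complex)
X = np.array([[0, 1], [1, 0]], dtype=complex)
Y = np.array([[0, -1j], [1j, 0]], dtype=complex)
Z = np.array([[1, 0], [0, -1]], dtype=complex)
H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
PAULI = {"I": I2, "X": X, "Y": Y, "Z": Z}


def kron3(a, b, c):
    return np.kron(np.kron(a, b), c)


def oracle_pauli(label):
    """Tensor-product Pauli matrix, leftmost character = qubit 0."""
    return kron3(*(PAULI[c] for c in label))


def oracle_ry(theta):
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


# CNOT written out as |0><0|⊗I + |1><1|⊗X on the (control, target) slots
P0 = np.array([[1, 0], [0, 0]], dtype=complex)
P1 = np.array([[0, 0], [0, 1]], dtype=complex)
CNOT_01 = kron3(P0, I2, I2) + kron3(P1, X, I2)
CNOT_02 = kron3(P0, I2, I2) + kron3(P1, I2, X)


def oracle_depolarize(rho, qubits, p):
    """Depolarizing channel via the Pauli-twirl identity.

    Averaging ρ over all 4^k Pauli conjugations on a qubit subset gives
    the maximally mixed state there, so
    ρ → (1−p)ρ + (p/4^k)·Σ_P PρP† is the same channel the simulator
    implements by partial trace and re-tensoring.
    """
    qubits = sorted(qubits)
    k = len(qubits)
    acc = np.zeros_like(rho)
    labels = ["I", "X", "Y", "Z"]
    import itertools

    for combo in itertools.product(labels, repeat=k):
        full = ["I", "I", "I"]
        for q, c in zip(qubits, combo):
            full[q] = c
        P = oracle_pauli("".join(full))
        acc = acc + P @ rho @ P.conj().T
    return (1 - p) * rho + (p / 4**k) * acc


def oracle_noisy_ghz(t, p, arity="two_qubit_on_cnot"):
    """Final density matrix of the encoding circuit, built from scratch."""
    theta = 2 * np.arccos(np.sqrt(t))
    psi0 = np.zeros(8, dtype=complex)
    psi0[0] = 1.0
    rho = np.outer(psi0, psi0.conj())
    u_ry = kron3(oracle_ry(theta), I2, I2)
    rho = u_ry @ rho @ u_ry.conj().T
    for cnot, pair in ((CNOT_01, (0, 1)), (CNOT_02, (0, 2))):
        rho = cnot @ rho @ cnot.conj().T
        if p > 0:
            targets = (0, 1, 2) if arity == "three_qubit_global" else pair
            rho = oracle_depolarize(rho, targets, p)
    return rho


@pytest.fixture(scope="session")
def aspirin_butane_t():
    """Morgan radius-2, 2048-bit Tanimoto of the two reference molecules."""
    from qtanimoto import MoleculePair, similarity_from_pair

    pair = MoleculePair(smiles_a=ASPIRIN, smiles_b=BUTANE, label="aspirin-butane")
    return similarity_from_pair(pair).t_value
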