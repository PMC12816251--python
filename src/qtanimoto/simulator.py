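"""Exact 8×8 density-matrix simulation of the encoding circuit with noise.

The register state is carried as a dense 8×8 complex density matrix ρ
(Hermitian, unit trace, positive semidefinite).  Gates act by unitary
conjugation ρ → UρU†.  Depolarizing noise on a qubit subset Q with
probability p applies

    ρ → (1−p)·ρ + p · (I/2^k) ⊗ Tr_Q(ρ),

i.e. with probability p the state of those k qubits is replaced by the
maximally mixed state.  By default the channel acts on the two qubits
of each CNOT, immediately after the gate; a ``three_qubit_global``
variant depolarizes the whole register after each CNOT instead.  Under
the default model the GHZ parity decays as ⟨ZZZ⟩ = (1−p)²·(2T−1).

Index convention: basis state |b0 b1 b2⟩ maps to integer index
b0·4 + b1·2 + b2 (qubit 0 is the most significant bit), matching the
package-wide rule that the leftmost label character is qubit 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import BASIS_LABELS, N_QUBITS, CircuitSpec, Gate
from .errors import DomainError, NumericalStateError

DIM = 2**N_QUBITS
PSD_TOL = 1e-10

_H = np.array([[1.0, 1.0], [1.0, -1.0]], dtype=complex) / np.sqrt(2.0)
_I2 = np.eye(2, dtype=complex)


def _ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _bit(index: int, qubit: int) -> int:
    return (index >> (N_QUBITS - 1 - qubit)) & 1


def _single_qubit_unitary(u: np.ndarray, qubit: int) -> np.ndarray:
    ops = [u if q == qubit else _I2 for q in range(N_QUBITS)]
    full = ops[0]
    for op in ops[1:]:
        full = np.kron(full, op)
    return full


def _cnot_unitary(control: int, target: int) -> np.ndarray:
    full = np.zeros((DIM, DIM), dtype=complex)
    for i in range(DIM):
        j = i ^ (1 << (N_QUBITS - 1 - target)) if _bit(i, control) else i
        full[j, i] = 1.0
    return full


def gate_unitary(gate: Gate) -> np.ndarray:
    """8×8 unitary matrix of a named gate."""
    if gate.name == "ry":
        return _single_qubit_unitary(_ry(gate.params[0]), gate.qubits[0])
    if gate.name == "h":
        return _single_qubit_unitary(_H, gate.qubits[0])
    if gate.name == "cx":
        return _cnot_unitary(*gate.qubits)
    raise ValueError(f"unknown gate name: {gate.name!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Depolarizing-noise configuration.

    ``p`` is the depolarizing probability; ``arity`` selects whether the
    channel acts on the two qubits of each matched gate
    (``two_qubit_on_cnot``) or on all three qubits
    (``three_qubit_global``); ``apply_after`` names the gates followed
    by noise (default: every CNOT).
    """

    p: float
    arity: str = "two_qubit_on_cnot"
    apply_after: tuple[str, ...] = ("cx",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DomainError(f"depolarizing probability must lie in [0, 1], got {self.p}")
        if self.arity not in ("two_qubit_on_cnot", "three_qubit_global"):
            raise ValueError(f"unknown noise arity: {self.arity!r}")


@dataclass(frozen=True)
class ShotCounts:
    """Measurement counts over the eight 3-bit outcome labels."""

    counts: dict[str, int]
    shots: int
    seed: int
    basis: str = "ZZZ"

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.shots:
            raise ValueError("counts must sum to shots")
        for lbl in self.counts:
            if lbl not in BASIS_LABELS:
                raise ValueError(f"bad outcome label: {lbl!r}")

    def probability(self, label: str) -> float:
        return self.counts.get(label, 0) / self.shots

    def to_json(self) -> str:
        return json.dumps(
            {
                "basis": self.basis,
                "shots": self.shots,
                "seed": self.seed,
                "label_convention": "leftmost character = qubit 0",
                "counts": {lbl: self.counts.get(lbl, 0) for lbl in BASIS_LABELS},
            },
            indent=2,
        )


def initial_state() -> np.ndarray:
    """|000⟩⟨000| as an 8×8 density matrix."""
    rho = np.zeros((DIM, DIM), dtype=complex)
    rho[0, 0] = 1.0
    return rho


def validate_density_matrix(rho: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Check Hermiticity/trace/positivity; clip eigenvalue dust.

    Eigenvalues in [−tol, 0) are clipped to 0 and the state renormalized;
    anything more negative raises :class:`NumericalStateError`.
    """
    if rho.shape != (DIM, DIM):
        raise NumericalStateError(f"expected {DIM}x{DIM} matrix, got {rho.shape}")
    if not np.allclose(rho, rho.conj().T, atol=tol):
        raise NumericalStateError("density matrix is not Hermitian")
    tr = np.trace(rho).real
    if abs(tr - 1.0) > tol:
        raise NumericalStateError(f"trace is {tr}, expected 1")
    evals, evecs = np.linalg.eigh(rho)
    if evals.min() < -tol:
        raise NumericalStateError(f"negative eigenvalue {evals.min()} beyond tolerance")
    if evals.min() < 0.0:
        evals = np.clip(evals, 0.0, None)
        rho = (evecs * evals) @ evecs.conj().T
        rho = rho / np.trace(rho).real
    return rho


def apply_gate(rho: np.ndarray, gate: Gate) -> np.ndarray:
    """Unitary conjugation ρ → UρU† for one gate."""
    u = gate_unitary(gate)
    return u @ rho @ u.conj().T


def depolarize(rho: np.ndarray, qubits, p: float) -> np.ndarray:
    """Depolarizing channel on a qubit subset.

    ρ → (1−p)·ρ + p·(maximally mixed on ``qubits``) ⊗ Tr_qubits(ρ).
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"depolarizing probability must lie in [0, 1], got {p}")
    qubits = sorted(set(qubits))
    if any(q not in range(N_QUBITS) for q in qubits):
        raise ValueError(f"qubit indices must be in 0..{N_QUBITS - 1}: {qubits}")
    if p == 0.0 or not qubits:
        return rho
    keep = [q for q in range(N_QUBITS) if q not in qubits]
    k = len(qubits)

    def keep_index(i: int) -> int:
        out = 0
        for q in keep:
            out = (out << 1) | _bit(i, q)
        return out

    # reduced state on the kept qubits: sum over traced-bit assignments
    red = np.zeros((2 ** len(keep), 2 ** len(keep)), dtype=complex)
    for i in range(DIM):
        for j in range(DIM):
            if all(_bit(i, q) == _bit(j, q) for q in qubits):
                red[keep_index(i), keep_index(j)] += rho[i, j]
    # re-tensor with I/2^k on the depolarized qubits
    mixed = np.zeros((DIM, DIM), dtype=complex)
    for i in range(DIM):
        for j in range(DIM):
            if all(_bit(i, q) == _bit(j, q) for q in qubits):
                mixed[i, j] = red[keep_index(i), keep_index(j)] / 2**k
    return (1.0 - p) * rho + p * mixed


def sample_counts(
    rho: np.ndarray, shots: int, seed: int, basis: str = "ZZZ"
) -> ShotCounts:
    """Multinomial draw of measurement outcomes from diag(ρ)."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    probs = np.diag(rho).real.copy()
    if probs.min() < -PSD_TOL:
        raise NumericalStateError(
            f"negative outcome probability {probs.min()} beyond tolerance"
        )
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draw = rng.multinomial(shots, probs)
    counts = {lbl: int(c) for lbl, c in zip(BASIS_LABELS, draw) if c > 0}
    return ShotCounts(counts=counts, shots=shots, seed=seed, basis=basis)


def run_circuit(
    circuit: CircuitSpec,
    noise: NoiseSpec | None = None,
    mode: str = "exact",
    shots: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, ShotCounts | None]:
    """Evolve |000⟩ through the circuit, injecting noise after matched gates.

    Returns the final (basis-rotated) density matrix and, in ``shots``
    mode, a seeded multinomial sample of measurement outcomes.
    """
    if mode not in ("exact", "shots"):
        raise ValueError(f"mode must be 'exact' or 'shots', got {mode!r}")
    rho = initial_state()
    for gate in circuit.gates:
        if gate.name == "measure":
            continue
        rho = apply_gate(rho, gate)
        if noise is not None and noise.p > 0.0 and gate.name in noise.apply_after:
            targets = (
                range(N_QUBITS)
                if noise.arity == "three_qubit_global"
                else gate.qubits
            )
            rho = depolarize(rho, targets, noise.p)
    rho = validate_density_matrix(rho)
    if mode == "exact":
        return rho, None
    return rho, sample_counts(rho, shots, seed, basis=circuit.measure_basis)
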