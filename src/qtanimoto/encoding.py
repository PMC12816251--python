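"""Amplitude encoding of a similarity value into a 3-qubit GHZ-like state.

A similarity T ∈ [0, 1] is written into the rotation angle

    θ = 2·arccos(√T),   so that   cos²(θ/2) = T,

and the circuit RY(θ) on qubit 0 followed by CNOT(0→1) and CNOT(0→2)
prepares the entangled state

    |ψ⟩ = √T |000⟩ + √(1−T) |111⟩.

Measuring all three qubits in the computational basis therefore yields
|000⟩ with probability T and |111⟩ with probability 1−T; the parity
observable ⟨ZZZ⟩ equals 2T−1.

Basis-label convention (fixed package-wide): the leftmost character of
an outcome string or Pauli label refers to qubit 0.  The encoded state
is permutation-symmetric so "000"/"111" read identically either way,
but downstream parity code relies on one fixed rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

N_QUBITS = 3
BASIS_LABELS = tuple(format(i, "03b") for i in range(8))


@dataclass(frozen=True)
class EncodingAngle:
    """RY rotation angle θ = 2·arccos(√T) together with its source T."""

    theta: float
    source_t: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.source_t <= 1.0:
            raise DomainError(f"source_t must lie in [0, 1], got {self.source_t}")
        if not -1e-12 <= self.theta <= math.pi + 1e-12:
            raise DomainError(f"theta must lie in [0, pi], got {self.theta}")


@dataclass(frozen=True)
class Gate:
    """One gate in a circuit: name, parameters, qubit indices."""

    name: str  # "ry" | "cx" | "h" | "measure"
    params: tuple[float, ...] = ()
    qubits: tuple[int, ...] = ()


@dataclass(frozen=True)
class CircuitSpec:
    """Ordered gate list for the 3-qubit encoding circuit.

    Exactly one parameterized RY on qubit 0, CNOTs fanning out from
    qubit 0 to qubits 1 and 2, optional Hadamards realizing X-basis
    measurement, then measurement of all three qubits.
    """

    gates: tuple[Gate, ...]
    n_qubits: int = N_QUBITS
    measure_basis: str = "ZZZ"  # per-qubit, leftmost char = qubit 0

    def to_json(self) -> str:
        payload = {
            "n_qubits": self.n_qubits,
            "measure_basis": self.measure_basis,
            "label_convention": "leftmost character = qubit 0",
            "gates": [
                {"name": g.name, "params": list(g.params), "qubits": list(g.qubits)}
                for g in self.gates
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class PureStateAmplitudes:
    """Real amplitudes of the ideal encoded state over "000"…"111"."""

    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.amplitudes) != 8:
            raise ValueError("need exactly 8 amplitudes")
        norm = sum(a * a for a in self.amplitudes)
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"squared amplitudes sum to {norm}, expected 1")

    def probabilities(self) -> dict[str, float]:
        return {lbl: a * a for lbl, a in zip(BASIS_LABELS, self.amplitudes)}


def angle_from_similarity(t: float) -> EncodingAngle:
    """Map a similarity T ∈ [0, 1] to the rotation angle θ = 2·arccos(√T)."""
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"similarity must lie in [0, 1], got {t}")
    theta = 2.0 * math.acos(math.sqrt(t))
    return EncodingAngle(theta=theta, source_t=t)


def similarity_from_angle(theta: float) -> float:
    """Inverse map: T = cos²(θ/2) for θ ∈ [0, π]."""
    if not 0.0 <= theta <= math.pi:
        raise DomainError(f"theta must lie in [0, pi], got {theta}")
    return math.cos(theta / 2.0) ** 2


def build_circuit(angle: EncodingAngle, measure_basis: str = "ZZZ") -> CircuitSpec:
    """RY(θ) on qubit 0 then CNOTs 0→1 and 0→2, plus measurement plan.

    X-basis measurement on a qubit is realized by a Hadamard on that
    qubit immediately before measurement; every other character in
    ``measure_basis`` (Z or I) means a plain computational-basis
    measurement of that qubit.
    """
    if len(measure_basis) != N_QUBITS:
        raise ValueError("measure_basis must have one character per qubit")
    gates = [
        Gate("ry", (angle.theta,), (0,)),
        Gate("cx", (), (0, 1)),
        Gate("cx", (), (0, 2)),
    ]
    for q, ch in enumerate(measure_basis):
        if ch.upper() == "X":
            gates.append(Gate("h", (), (q,)))
    gates.append(Gate("measure", (), (0, 1, 2)))
    return CircuitSpec(gates=tuple(gates), measure_basis=measure_basis.upper())


def ideal_state(angle: EncodingAngle) -> PureStateAmplitudes:
    """Noiseless output state √T|000⟩ + √(1−T)|111⟩ of the circuit."""
    t = angle.source_t
    amps = [0.0] * 8
    amps[0] = math.sqrt(t)
    amps[7] = math.sqrt(1.0 - t)
    return PureStateAmplitudes(amplitudes=tuple(amps))
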