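"""Pauli-observable expectation values from counts or exact states.

A three-character label over {I, Z, X} (leftmost character = qubit 0)
names a tensor-product observable.  From shot counts the estimate is a
signed average over outcomes,

    ⟨O⟩ = (1/S) Σ_i s_i C_i,

where the sign s_i = (−1)^(parity of outcome i restricted to the
observable's support) — the unique convention under which ⟨ZZZ⟩ equals
P(even parity) − P(odd parity) and reproduces ⟨ZZZ⟩ = 2T−1 on the
encoded state.  The standard error of a ±1-valued estimator over S
shots is √((1−⟨O⟩²)/S).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import BASIS_LABELS, N_QUBITS
from .errors import BasisMismatchError
from .simulator import ShotCounts

_PAULI = {
    "I": np.eye(2, dtype=complex),
    "Z": np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex),
    "X": np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
}


@dataclass(frozen=True)
class PauliObservable:
    """Tensor-product observable named by a label such as ZZZ, IIZ, XIX."""

    label: str

    def __post_init__(self) -> None:
        if len(self.label) != N_QUBITS or any(c not in _PAULI for c in self.label):
            raise ValueError(
                f"label must be {N_QUBITS} characters over I/Z/X, got {self.label!r}"
            )

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(q for q, c in enumerate(self.label) if c != "I")

    def matrix(self) -> np.ndarray:
        full = _PAULI[self.label[0]]
        for c in self.label[1:]:
            full = np.kron(full, _PAULI[c])
        return full


@dataclass(frozen=True)
class ObservableEstimate:
    """An expectation value with its provenance (counts vs exact trace)."""

    value: float
    stderr: float
    shots: int
    source: str  # "counts" | "exact" | "product_approx"
    observable: str = ""

    def __post_init__(self) -> None:
        if abs(self.value) > 1.0 + 1e-12:
            raise ValueError(f"|value| must be <= 1, got {self.value}")
        if self.stderr < 0.0:
            raise ValueError("stderr must be non-negative")


@dataclass(frozen=True)
class OutcomeDelta:
    label: str
    p_ideal: float
    p_noisy: float
    delta: float


def _parity_sign(label: str, support: tuple[int, ...]) -> int:
    ones = sum(int(label[q]) for q in support)
    return -1 if ones % 2 else 1


def expectation_from_counts(
    counts: ShotCounts, obs: PauliObservable
) -> ObservableEstimate:
    """Signed parity average of counts for one Pauli observable.

    The counts must have been measured in a compatible basis: every
    qubit in the observable's support must carry the observable's own
    basis character in ``counts.basis`` (an X estimate needs counts
    taken after the Hadamard basis change, never raw Z counts).
    """
    if counts.shots <= 0:
        raise ValueError("counts must contain at least one shot")
    for q in obs.support:
        measured = counts.basis[q].upper()
        if measured != obs.label[q]:
            raise BasisMismatchError(
                f"observable {obs.label} needs qubit {q} measured in "
                f"{obs.label[q]}, but counts basis is {counts.basis}"
            )
    total = 0
    for lbl, c in counts.counts.items():
        total += _parity_sign(lbl, obs.support) * c
    value = total / counts.shots
    stderr = float(np.sqrt(max(0.0, 1.0 - value**2) / counts.shots))
    return ObservableEstimate(
        value=value, stderr=stderr, shots=counts.shots,
        source="counts", observable=obs.label,
    )


def exact_expectation(rho: np.ndarray, obs: PauliObservable) -> ObservableEstimate:
    """Tr(ρO) for the labeled Pauli tensor; exact, zero standard error."""
    val = np.trace(rho @ obs.matrix())
    if abs(val.imag) > 1e-10:
        raise ValueError(f"expectation has imaginary part {val.imag}")
    value = float(np.clip(val.real, -1.0, 1.0))
    return ObservableEstimate(
        value=value, stderr=0.0, shots=0, source="exact", observable=obs.label
    )


def probability_deltas(
    ideal: ShotCounts, noisy: ShotCounts
) -> tuple[OutcomeDelta, ...]:
    """Per-outcome ideal/noisy probabilities and ΔP = P_ideal − P_noisy.

    Covers all eight outcome labels, including zero-count ones; both
    count sets must be computational-basis (Z) measurements.
    """
    for counts in (ideal, noisy):
        if counts.shots <= 0:
            raise ValueError("counts must contain at least one shot")
        if "X" in counts.basis.upper():
            raise BasisMismatchError(
                "probability deltas are defined for Z-basis counts only"
            )
    records = []
    for lbl in BASIS_LABELS:
        p_i = ideal.probability(lbl)
        p_n = noisy.probability(lbl)
        records.append(
            OutcomeDelta(label=lbl, p_ideal=p_i, p_noisy=p_n, delta=p_i - p_n)
        )
    return tuple(records)


def product_approx_zzz(
    z_estimates: dict[str, ObservableEstimate],
    composition: str = "ziz_izi",
) -> ObservableEstimate:
    """Product approximation of ⟨ZZZ⟩ from single-circuit Z observables.

    Default composition multiplies the disjoint-support pair
    ⟨ZIZ⟩·⟨IZI⟩ (their supports tile all three qubits, so the product
    equals ⟨ZZZ⟩ under an independence assumption); the alternative
    ``iiz_izi_ziz`` multiplies all three measured Z observables.  The
    result is clipped to the physically allowed range [−1, 1] and
    flagged as approximate.
    """
    if composition == "ziz_izi":
        needed = ("ZIZ", "IZI")
    elif composition == "iiz_izi_ziz":
        needed = ("IIZ", "IZI", "ZIZ")
    else:
        raise ValueError(f"unknown composition: {composition!r}")
    missing = [lbl for lbl in needed if lbl not in z_estimates]
    if missing:
        raise KeyError(f"missing required Z estimates: {missing}")
    value = 1.0
    var = 0.0
    for lbl in needed:
        est = z_estimates[lbl]
        # first-order error propagation through the product
        var = var * est.value**2 + est.stderr**2 * value**2
        value *= est.value
    value = float(np.clip(value, -1.0, 1.0))
    shots = max(z_estimates[lbl].shots for lbl in needed)
    return ObservableEstimate(
        value=value, stderr=float(np.sqrt(var)), shots=shots,
        source="product_approx", observable="ZZZ",
    )
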