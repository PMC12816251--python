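"""Binary molecular fingerprints and the Tanimoto (Jaccard) coefficient.

Morgan/ECFP fingerprints are computed through RDKit's fingerprint
generator; the Tanimoto coefficient

    T(A, B) = |A ∩ B| / |A ∪ B|

is taken over the on-bits of two equal-length binary vectors.  A
``direct`` entry path (a user-supplied similarity in [0, 1]) is also
supported so the quantum layers can be exercised without any chemistry
toolkit in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, SmilesParseError, UndefinedSimilarityError

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length binary fingerprint of one molecule.

    Parameters
    ----------
    bits
        Ordered 0/1 sequence of length ``n_bits``.
    n_bits
        Fingerprint length (default convention: 2048).
    provenance
        Free-text tag recording toolkit, version and radius.
    """

    bits: tuple[int, ...]
    n_bits: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.bits) != self.n_bits:
            raise DimensionError(
                f"bits has length {len(self.bits)}, expected n_bits={self.n_bits}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("fingerprint bits must be 0 or 1")

    @property
    def popcount(self) -> int:
        return int(sum(self.bits))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.uint8)

    @classmethod
    def from_bits(cls, bits, provenance: str = "") -> "FingerprintVector":
        bits = tuple(int(b) for b in bits)
        return cls(bits=bits, n_bits=len(bits), provenance=provenance)


@dataclass(frozen=True)
class MoleculePair:
    """Two molecules given as SMILES, plus a human-readable label."""

    smiles_a: str
    smiles_b: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.smiles_a or not self.smiles_b:
            raise ValueError("both SMILES strings must be non-empty")


@dataclass(frozen=True)
class SimilarityRecord:
    """A similarity value together with how it was obtained."""

    t_value: float
    label: str = ""
    method: str = "direct"  # "morgan_tanimoto" or "direct"
    radius: int | None = None
    n_bits: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_value <= 1.0:
            raise ValueError(f"t_value must lie in [0, 1], got {self.t_value}")


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two binary fingerprints.

    Raises
    ------
    DimensionError
        If the fingerprints have different lengths.
    UndefinedSimilarityError
        If both fingerprints are all-zero (the ratio is 0/0).
    """
    if a.n_bits != b.n_bits:
        raise DimensionError(
            f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}"
        )
    va, vb = a.as_array(), b.as_array()
    inter = int(np.sum(va & vb))
    union = int(np.sum(va | vb))
    if union == 0:
        raise UndefinedSimilarityError(
            "Tanimoto is undefined for two all-zero fingerprints"
        )
    return inter / union


def morgan_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> FingerprintVector:
    """Binary Morgan (ECFP-style) fingerprint of a SMILES string.

    Deterministic for a fixed RDKit version and fixed parameters.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    import rdkit
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = tuple(int(fp.GetBit(i)) for i in range(n_bits))
    prov = f"rdkit={rdkit.__version__} morgan radius={radius} n_bits={n_bits}"
    return FingerprintVector(bits=bits, n_bits=n_bits, provenance=prov)


def similarity_from_pair(
    pair: MoleculePair,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> SimilarityRecord:
    """Morgan fingerprints for both molecules, then their Tanimoto value."""
    fa = morgan_fingerprint(pair.smiles_a, radius=radius, n_bits=n_bits)
    fb = morgan_fingerprint(pair.smiles_b, radius=radius, n_bits=n_bits)
    t = tanimoto(fa, fb)
    return SimilarityRecord(
        t_value=t,
        label=pair.label or f"{pair.smiles_a}|{pair.smiles_b}",
        method="morgan_tanimoto",
        radius=radius,
        n_bits=n_bits,
        provenance=fa.provenance,
    )
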