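"""Exception types shared across the package."""


class QTanimotoError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(QTanimotoError, ValueError):
    """Fingerprints (or operators) of incompatible sizes were combined."""


class UndefinedSimilarityError(QTanimotoError, ValueError):
    """Tanimoto of two all-zero fingerprints is 0/0 and has no value."""


class SmilesParseError(QTanimotoError, ValueError):
    """A SMILES string could not be parsed by the chemistry toolkit."""


class DomainError(QTanimotoError, ValueError):
    """A numeric argument fell outside its mathematical domain."""


class BasisMismatchError(QTanimotoError, ValueError):
    """Counts were measured in a basis incompatible with the observable."""


class NumericalStateError(QTanimotoError, ValueError):
    """A density matrix drifted outside physicality tolerances."""


class UndefinedErrorReductionError(QTanimotoError, ZeroDivisionError):
    """Relative error reduction is undefined when the unmitigated error is 0."""
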