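"""Exception and warning types shared across the package."""


class PermuteDDSError(Exception):
    """Base class for package errors."""


class InvalidSmilesError(PermuteDDSError):
    """Raised when a SMILES string cannot be parsed into a molecule.

    When raised by batch featurization, ``offenders`` maps drug id -> bad
    SMILES for every failing entry.
    """

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = dict(offenders) if offenders else {}


class DomainError(PermuteDDSError, ValueError):
    """A numeric parameter is outside its mathematical domain."""


class ShapeMismatchError(PermuteDDSError, ValueError):
    """Two arrays that must share a shape do not."""


class ShapeError(PermuteDDSError, ValueError):
    """An array has a shape incompatible with the requested operation."""


class EmptyIntersectionError(PermuteDDSError, ValueError):
    """A gene-set intersection came out empty."""


class InsufficientEntitiesError(PermuteDDSError, ValueError):
    """Too few distinct entities (cell lines / drug pairs) for the requested folds."""


class DataCoverageError(PermuteDDSError, KeyError):
    """A synergy record references a drug or cell line without features."""


class UnknownVariantError(PermuteDDSError, ValueError):
    """An ablation variant name is not recognised."""


class VocabularyExhaustedError(PermuteDDSError, ValueError):
    """More synthetic drugs were requested than the SMILES vocabulary holds."""


class DegenerateInputError(PermuteDDSError, ValueError):
    """An input is degenerate for the requested statistic (e.g. constant labels)."""


class DegenerateMoleculeWarning(UserWarning):
    """The molecule is too small to contain the fragments a fingerprint encodes."""
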