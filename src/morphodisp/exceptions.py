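"""Exception hierarchy for landmark I/O, superimposition and disparity testing."""


class MorphodispError(Exception):
    """Base class for all package errors."""


class ParseError(MorphodispError):
    """A landmark/metadata/scheme file could not be parsed.

    Carries ``line`` (1-based) when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DatasetError(MorphodispError):
    """Structural inconsistency across specimens (e.g. landmark-count mismatch)."""


class VocabularyError(MorphodispError):
    """A closed-vocabulary metadata field received an unknown token."""


class MetadataConflictError(MorphodispError):
    """Duplicate species rows carry conflicting metadata values."""


class SchemeError(MorphodispError):
    """A landmark scheme file violates the scheme schema."""


class DegenerateRegionError(MorphodispError):
    """A landmark subset is too small to define shape (fewer than 3 landmarks)."""


class DegenerateConfigurationError(MorphodispError):
    """A configuration is rank-deficient or has coincident landmarks."""


class ZeroSizeError(DegenerateConfigurationError):
    """All landmarks coincide, so centroid size is zero."""


class ContractError(MorphodispError):
    """A documented precondition (centering, unit size, group sizes) was violated."""
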