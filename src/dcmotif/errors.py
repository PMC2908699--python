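"""Exception hierarchy shared across the package."""


class DcmotifError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(DcmotifError):
    """A sequence contains characters outside the ACGT alphabet."""


class LengthMismatchError(DcmotifError):
    """Sequences (or profiles) that must share a common length do not."""


class EmptyInputError(DcmotifError):
    """An operation received an empty collection where data is required."""


class ValidationError(DcmotifError):
    """Structured input failed a consistency check (ids, coordinates, ...)."""


class ConfigurationError(DcmotifError):
    """A parameter combination is inconsistent or out of range."""


class SeparationZeroError(DcmotifError):
    """Cluster-validity index undefined: two centroids coincide."""


class DegenerateFitError(DcmotifError):
    """Too few distinct values to fit the requested number of fuzzy sets."""
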