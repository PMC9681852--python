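"""Typed exceptions shared across the package."""


class SermError(Exception):
    """Base class for all package errors."""


class MatrixParseError(SermError):
    """A matrix file could not be parsed (malformed header, negative value, NaN, ...)."""


class ParameterError(SermError):
    """An argument is outside its documented range."""


class TrainingError(SermError):
    """Autoencoder optimization produced a non-finite loss."""


class FitError(SermError):
    """Distribution fitting failed for every candidate family."""


class ContractError(SermError):
    """An internal numerical contract was violated (e.g. a CDF exceeding 1)."""


class AlignmentError(SermError):
    """Batches do not share a common gene axis."""
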