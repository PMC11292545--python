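"""Exception hierarchy for pepiso.

Every error raised on user input derives from :class:`PepisoError`, so callers
(and the CLI) can distinguish bad data from programming errors.
"""


class PepisoError(Exception):
    """Base class for all pepiso errors."""


class FormatError(PepisoError):
    """A file does not conform to the expected tabular dialect."""


class DuplicateKeyError(FormatError):
    """Two rows carry the same (sequence, modification) key or accession."""


class ConflictError(FormatError):
    """The same peptide is listed with two different accession sets."""


class LabelError(PepisoError):
    """A cohort label is outside the recognised alias table."""


class DesignError(PepisoError):
    """The sample design violates an invariant (e.g. a singleton cohort)."""


class AlphabetError(PepisoError):
    """A sequence contains a residue outside the 20 standard amino acids."""


class UnknownAccessionError(PepisoError):
    """An accession is not present in the isoform catalog."""


class EmptyInputError(PepisoError):
    """No usable rows remain after joining inputs."""


class DomainError(PepisoError):
    """A value is outside the mathematical domain of an operation."""


class EmptyColumnError(PepisoError):
    """A sample column holds no observed values."""


class DegenerateVarianceError(PepisoError):
    """Both groups have zero variance but different means; t is undefined."""


class InsufficientDataError(PepisoError):
    """Too few complete features or zero total variance for the analysis."""


class ConfigError(PepisoError):
    """A configuration value is invalid or internally inconsistent."""
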