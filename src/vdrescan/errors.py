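"""Exception hierarchy shared across the package."""


class VdrescanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VdrescanError):
    """A file or stream does not conform to the expected text format."""


class DegenerateMatrixError(VdrescanError):
    """A count/weight matrix cannot support the requested operation
    (zero-total column without pseudocount, or max_score == min_score)."""


class WindowLengthError(VdrescanError):
    """A scoring window does not match the motif length, or contains
    characters outside the DNA alphabet."""


class VariantParseError(VdrescanError):
    """A variant string is not in the supported coding-coordinate dialect."""


class CoordinateRangeError(VdrescanError):
    """A mapped coordinate or requested region falls outside the contig
    or the gene model."""


class ReferenceMismatchError(VdrescanError):
    """Bases stated in a variant do not match the reference at the mapped
    interval."""


class InsufficientDataError(VdrescanError):
    """Not enough observations to carry out a statistical computation."""


class CollinearityError(VdrescanError):
    """The design matrix of a regression is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class PlantingError(VdrescanError):
    """A motif instance at the requested relative score cannot be
    constructed within tolerance."""

    def __init__(self, message: str, closest: float | None = None):
        super().__init__(message)
        self.closest = closest


class ConsistencyError(VdrescanError):
    """Bookkeeping arithmetic does not add up (e.g. exclusions exceed
    recruitment)."""


class StageError(VdrescanError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(VdrescanError):
    """A pipeline configuration is malformed."""
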