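"""Exception hierarchy shared across the package."""


class NirfermError(Exception):
    """Base class for all package-specific errors."""


class AxisError(NirfermError, ValueError):
    """Invalid spectral axis (nonpositive, non-monotonic, too short, wrong unit)."""


class SchemaError(NirfermError, ValueError):
    """A table does not conform to the expected CSV schema."""


class DuplicateIdError(SchemaError):
    """Duplicate sample_id within a dataset."""


class ParseError(SchemaError):
    """Non-numeric value where a number was expected; carries row/column context."""


class EmptyJoinError(NirfermError):
    """Inner join of spectra and concentrations produced zero matched samples."""


class EmptySpectrumError(NirfermError):
    """A truncation/removal step left no spectral channels."""


class DegenerateSpectrumError(NirfermError):
    """A spectrum row has zero spread, so SNV is undefined."""


class DegenerateDataError(NirfermError):
    """A matrix has no variance (e.g. all rows identical) where variance is required."""


class DegenerateRangeError(NirfermError):
    """A constituent's calibration range is zero or negative."""


class DegenerateResponseError(NirfermError):
    """A response column has zero variance and cannot be modeled."""


class ParameterError(NirfermError, ValueError):
    """An argument is outside its documented domain."""


class SampleSizeError(ParameterError):
    """Too few samples for the requested operation."""


class DimensionError(NirfermError, ValueError):
    """Shape mismatch between arrays that must align."""


class DesignFailureError(NirfermError):
    """Rejection sampling could not satisfy a design constraint."""


class LibraryMismatchError(NirfermError):
    """A constituent required for rendering is missing from the band library."""


class RangeError(NirfermError, ValueError):
    """A requested spectral interval falls outside the available axis."""


class UndefinedStatisticError(NirfermError):
    """A statistic is undefined for the given input (e.g. constant predictions)."""


class ConfigError(NirfermError, ValueError):
    """Pipeline configuration failed validation."""


class StageError(NirfermError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
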