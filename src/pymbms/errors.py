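"""Exception hierarchy shared across the package."""


class PymbmsError(Exception):
    """Base class for all package errors."""


class InvalidSpectrumError(PymbmsError):
    """Spectrum violates its invariants (e.g. all-zero, negative intensity)."""


class InconsistentNormalizationError(PymbmsError):
    """Operation mixing spectra with different normalization states."""


class ParseError(PymbmsError):
    """Delimited-text input could not be parsed; message names the offending row."""


class UndefinedRatioError(PymbmsError):
    """S/G ratio requested but the guaiacyl ion sum is zero."""


class InvalidStandardError(PymbmsError):
    """Reference standard has zero diagnostic-ion sum."""


class DegenerateResponseError(PymbmsError):
    """PLS response vector has zero variance."""


class RankDeficientError(PymbmsError):
    """NIPALS ran out of rank before reaching the requested factor count.

    Attributes
    ----------
    achieved : int
        Number of factors successfully extracted.
    """

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


class InvalidFoldsError(PymbmsError):
    """Cross-validation fold count incompatible with the sample count."""


class DegenerateGeometryError(PymbmsError):
    """Spatial correction requested but field coordinates are degenerate."""


class NonEstimableError(PymbmsError):
    """Variance components not estimable (e.g. no clonal replication)."""


class ConfigError(PymbmsError):
    """Invalid configuration (generator, pipeline, or ion-set definition)."""
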