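"""Exception hierarchy.

Every error raised by the library derives from :class:`NitrifluxError`,
so callers (and the command-line layer, which maps them to nonzero exit
codes) can catch a single base class.
"""


class NitrifluxError(Exception):
    """Base class for all nitriflux errors."""


class InputError(NitrifluxError):
    """Malformed or insufficient input data (too few standards, empty group...)."""


class SchemaError(InputError):
    """A tabular input does not match its declared schema.

    The message names the offending column and, where known, the row.
    """


class MetadataError(InputError):
    """Sample metadata required by a normalization is missing or invalid."""


class NormalizationError(NitrifluxError):
    """A normalization cannot be computed (e.g. an all-zero sample column)."""


class CalibrationQualityError(NitrifluxError):
    """Isotope calibration regression fell below the required R²."""

    def __init__(self, r_squared: float, r2_min: float):
        self.r_squared = float(r_squared)
        self.r2_min = float(r2_min)
        super().__init__(
            f"calibration R²={r_squared:.6f} below required minimum {r2_min}"
        )


class BaselineError(NitrifluxError):
    """Tracer time series lacks the t=0 blank needed for baseline correction."""


class DesignError(NitrifluxError):
    """Experimental design unsupported (unbalanced ANOVA, <2 timepoints...)."""


class SimSpecError(NitrifluxError):
    """A simulation specification is internally inconsistent."""
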