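"""Exception hierarchy shared across the package."""


class DrsError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(DrsError, ValueError):
    """Spectra that must share a wavelength grid do not."""


class WavelengthRangeError(DrsError, ValueError):
    """Requested wavelengths fall outside the supported 400-1700 nm range."""


class OpticsDomainError(DrsError, ValueError):
    """Optical coefficients outside their physical domain."""


class DegenerateReferenceError(DrsError, ValueError):
    """White and dark reference coincide somewhere; calibration undefined."""


class StitchError(DrsError, ValueError):
    """The two spectrometer bands do not overlap; cross-fade impossible."""


class NormalizationError(DrsError, ValueError):
    """Spectrum value at the 800 nm anchor is not positive."""


class ConfigError(DrsError, ValueError):
    """A simulation or run configuration field is invalid."""


class TrainingError(DrsError, ValueError):
    """A class required to train the cascade is absent."""


class FoldError(DrsError, ValueError):
    """Cross-validation folds cannot be formed (class smaller than k)."""


class CountError(DrsError, ValueError):
    """Empty label lists passed to a confusion-count reduction."""


class RocError(DrsError, ValueError):
    """ROC analysis needs both classes present."""


class InputError(DrsError, ValueError):
    """Mismatched keys or malformed tabular input."""


class DataError(DrsError, ValueError):
    """A measurement location is missing required annotation."""


class CalibrationError(DrsError, ValueError):
    """Threshold calibration subset contains no true tumor location."""


class EvaluationError(DrsError, ValueError):
    """Evaluation subset is empty."""
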