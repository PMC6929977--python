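"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class SersmethError(Exception):
    """Base class for all package errors."""


class ConfigError(SersmethError):
    """Invalid configuration value or key."""


class DataError(SersmethError):
    """Invalid input data (alphabet, file format, shapes, labels)."""


class InvalidAlphabetError(DataError):
    """Sequence contains characters outside A/C/G/T."""


class DegenerateCalibrationError(DataError):
    """Amplicon without CpG sites: the methylation-to-CG map has zero slope."""


class SpectrumFormatError(DataError):
    """Unparseable or invalid spectrum file/values."""


class NumericalError(SersmethError):
    """Numerical failure (ill-conditioning, non-physical fit)."""


class ConditioningError(NumericalError):
    """Reference spectra are (near-)collinear."""


class NonPhysicalFitError(NumericalError):
    """Deconvolution produced coefficients with non-positive sum."""


class CapacityError(SersmethError):
    """Exact-enumeration budget exceeded; caller should bin categories."""
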