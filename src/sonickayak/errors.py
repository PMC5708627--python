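"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`SonicKayakError`,
split into data errors (bad or empty input content) and usage errors
(bad parameters or configuration).  The CLI maps data errors to exit
code 1 and usage errors to exit code 2.
"""


class SonicKayakError(Exception):
    """Base class for all package errors."""


class DataError(SonicKayakError):
    """Input data is unusable (empty, silent, out of coverage...)."""


class UsageError(SonicKayakError):
    """Parameters or configuration are invalid."""


class SchemaError(DataError):
    """A required column or field is missing from an input file."""


class EmptyLogError(DataError):
    """A sensor log contains no valid records."""


class SilenceError(DataError):
    """An audio signal is digitally silent where a level is required."""


class BandError(UsageError):
    """A frequency band is invalid for the clip being analysed."""


class CoverageError(DataError):
    """A segment lies outside the time span of the audio clip."""


class UnitError(UsageError):
    """Mixed calibration modes or bands where uniformity is required."""


class SensorRangeError(UsageError):
    """A temperature lies outside the DS18B20 operating range."""


class AssetError(DataError):
    """A referenced audio sample id cannot be resolved."""


class ParameterError(UsageError):
    """A numeric parameter is out of its valid domain."""


class OverlapError(DataError):
    """Two grids share no occupied cells."""


class FieldDomainError(UsageError):
    """A position lies outside the synthetic field's bounding box."""
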