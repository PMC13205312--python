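"""Exception hierarchy shared across the package."""


class BowelperfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BowelperfError):
    """An object violates one of its invariants."""


class FormatError(BowelperfError):
    """A file does not conform to its declared format."""


class ShapeError(FormatError):
    """Binary payload size disagrees with the declared shape."""


class RangeError(BowelperfError):
    """A requested coordinate/wavelength/window lies outside the data."""


class ConfigError(BowelperfError):
    """An invalid or contradictory configuration was supplied."""


class DegenerateProfileError(BowelperfError):
    """A line profile has no resolvable high/low plateau structure."""


class NoInflowDetectedError(BowelperfError):
    """The fluorescence signal never rises above the background noise."""


class IndicatorUnreadableError(BowelperfError):
    """No laser-indicator template scores above the matching floor."""


class DegenerateSampleError(BowelperfError):
    """A statistical sample is constant or otherwise untestable."""


class InsufficientCasesError(BowelperfError):
    """Fewer complete cases than the analysis requires."""
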