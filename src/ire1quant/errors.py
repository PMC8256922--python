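"""Exception hierarchy for the Ire1 quantification pipeline."""


class Ire1QuantError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(Ire1QuantError):
    """Invalid simulation or analysis configuration."""


class PlacementError(Ire1QuantError):
    """Non-overlapping cell placement failed within the attempt budget."""


class FormatError(Ire1QuantError):
    """Unsupported image file format (e.g. RGB input where grayscale is required)."""


class MetadataError(Ire1QuantError):
    """Required physical calibration (pixel size, z-step) missing."""


class DegenerateImageError(Ire1QuantError):
    """Image cannot be thresholded (fewer than two distinct intensities)."""


class CalibrationMismatchError(Ire1QuantError):
    """Two inputs that must share pixel calibration do not."""


class EmptyFieldError(Ire1QuantError):
    """A per-field statistic was requested on zero cells."""


class EmptyInputError(Ire1QuantError):
    """An aggregation was requested on an empty collection."""


class InsufficientDataError(Ire1QuantError):
    """A statistical test was requested on too few observations."""


class RectOutOfBoundsError(Ire1QuantError):
    """A lane rectangle extends outside the gel image."""


class ZeroSignalError(Ire1QuantError):
    """Both densitometry band integrals are zero."""


class SchemaError(Ire1QuantError):
    """A coordinate table is missing required columns."""


class LeafletError(Ire1QuantError):
    """A bilayer frame lacks one of the two leaflets."""


class EmptyGridError(Ire1QuantError):
    """No thickness-map bin ever received phosphates from both leaflets."""
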