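"""Exception hierarchy shared across the package."""


class NicheTrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NicheTrackError):
    """A file could not be parsed into the expected on-disk schema."""


class DimensionError(NicheTrackError):
    """Arrays that must share a pixel grid (movie, masks, drift table) do not."""


class SchemaError(NicheTrackError):
    """A tabular file violates its column/ordering contract."""


class ValidationError(NicheTrackError):
    """A parameter value or combination is outside its admissible range."""


class RegionUndefinedError(NicheTrackError):
    """A distance query was issued against an empty region mask."""
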