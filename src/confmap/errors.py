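"""Exception hierarchy for confmap.

Every failure mode that callers may want to catch separately gets its own
class; all inherit from :class:`ConfmapError` so ``except ConfmapError``
catches anything raised deliberately by this package.
"""


class ConfmapError(Exception):
    """Base class for all confmap errors."""


class MapFormatError(ConfmapError):
    """The file is not a readable MRC2014/CCP4 volume."""


class NonFiniteMapError(ConfmapError):
    """The map contains NaN or infinite voxel values."""


class EmptyModelError(ConfmapError):
    """A coordinate file contains no ATOM/HETATM records."""


class CoordinateParseError(ConfmapError):
    """An ATOM/HETATM record has an unparseable coordinate field."""


class WindowPlacementError(ConfmapError):
    """A background window cannot be placed inside the map."""


class DegenerateNoiseError(ConfmapError):
    """The background has zero (or undefined) variance."""


class ConfigError(ConfmapError):
    """Invalid or contradictory pipeline configuration."""
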