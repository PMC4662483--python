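"""Exception hierarchy for woundquant."""


class WoundQuantError(Exception):
    """Base class for all woundquant errors."""


class BandGeometryError(WoundQuantError):
    """The requested synthetic wound band does not fit inside the image."""


class DegenerateImageError(WoundQuantError):
    """Image appearance is degenerate (e.g. constant): cell/wound split undefined."""


class EmptyWoundError(WoundQuantError):
    """An operation that requires a nonempty wound was given an empty mask."""


class IsotropyError(WoundQuantError):
    """The wound mask is isotropic: no well-defined main axis."""


class ContourError(WoundQuantError):
    """Boundary contours cannot be separated into two sides."""


class ConfigError(WoundQuantError):
    """A run configuration is malformed or references missing files."""


class DegenerateControlError(WoundQuantError):
    """Control wound did not move (a == b): relative migration undefined."""
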