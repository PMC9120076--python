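"""Exception hierarchy for rspat.

All configuration and input problems raise subclasses of :class:`RspatError`
so callers can catch one base type at pipeline boundaries.
"""


class RspatError(Exception):
    """Base class for all rspat errors."""


class FormatError(RspatError, ValueError):
    """A file or table does not match the expected layout."""


class ConfigError(RspatError, ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


class GeometryError(RspatError, ValueError):
    """Requested objects cannot be placed within the simulation grid."""


class RangeError(RspatError, ValueError):
    """A lookup falls outside the tabulated domain."""


class ReconstructionError(RspatError, RuntimeError):
    """The sinogram does not cover the requested reconstruction grid."""


class UnmixingError(RspatError, ValueError):
    """The spectral system is rank deficient or otherwise unsolvable."""


class InputError(RspatError, ValueError):
    """Invalid runtime input to an analysis operation (empty mask, etc.)."""
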