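"""Exception hierarchy.

Every error raised by the package derives from :class:`EnvlinkError` so
callers can catch the whole family; the CLI maps configuration/usage errors
to exit code 2 and partial pipeline failures to exit code 1.
"""


class EnvlinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EnvlinkError):
    """A workflow or source configuration document is invalid."""


class ValidationError(EnvlinkError):
    """A value violates a domain invariant (bad bbox, coordinate, radius...)."""


class FormatError(EnvlinkError):
    """An input file does not have the expected structure."""


class NamingError(EnvlinkError):
    """An identifier contains characters not allowed in store paths."""


class ParameterError(EnvlinkError):
    """A numeric parameter is out of its valid range."""


class LookupError_(EnvlinkError):
    """A key is absent from a registry; the message lists what is available."""


class ProjectionError(EnvlinkError):
    """A coordinate transformation is unsupported or no engine is available."""


class FetchError(EnvlinkError):
    """A provider could not deliver the requested layer (retryable)."""


class StitchError(EnvlinkError):
    """Tiles are incompatible (CRS/resolution/alignment) or conflict."""


class EmptyExtentError(EnvlinkError):
    """A spatial subset contains no pixels."""


class StoreIOError(EnvlinkError):
    """A store file is unreadable or corrupt; the message names the file."""
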