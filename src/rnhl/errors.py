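"""Exception hierarchy shared across the toolkit."""


class RnhlError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(RnhlError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(RnhlError, ValueError):
    """Malformed or inconsistent user-supplied data."""


class BoundsError(RnhlError, IndexError):
    """An index (column, site, cluster count ...) is out of range."""


class FormatError(RnhlError, ValueError):
    """Data cannot be represented in the requested output format."""
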