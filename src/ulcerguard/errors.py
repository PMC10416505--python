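"""Exception hierarchy.

All ulcerguard errors derive from :class:`UlcerGuardError`; the value-like
ones also derive from :class:`ValueError` so callers that only know the
standard library still catch them.
"""


class UlcerGuardError(Exception):
    """Base class for all ulcerguard errors."""


class DomainError(UlcerGuardError, ValueError):
    """An argument is outside its physical/mathematical domain."""


class ConfigurationError(UlcerGuardError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class DataError(UlcerGuardError, ValueError):
    """An input data stream or file violates its contract."""


class FitError(UlcerGuardError, ValueError):
    """A model fit cannot be performed on the given observations."""
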