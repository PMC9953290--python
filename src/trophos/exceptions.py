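"""Exception hierarchy.

All errors raised by this package derive from :class:`TrophosError` so that
pipeline stages can catch package errors without masking programming bugs.
"""


class TrophosError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrophosError, ValueError):
    """A scenario or pipeline configuration is internally inconsistent."""


class DomainError(TrophosError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class EmptyGroupError(TrophosError, ValueError):
    """A group required to contain data is empty (e.g. all stomachs empty)."""


class DegenerateDesignError(TrophosError, ValueError):
    """A statistical design cannot be tested (e.g. a group of size one)."""


class DegenerateGeometryError(TrophosError, ValueError):
    """A geometric statistic is undefined for the given point set."""
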