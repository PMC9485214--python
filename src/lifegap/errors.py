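"""Exception hierarchy shared across the package."""


class LifegapError(Exception):
    """Base class for all package errors."""


class ParseError(LifegapError):
    """A data file violates the expected schema or vocabulary."""


class IntegrityError(LifegapError):
    """Structurally valid input contradicts itself (e.g. duplicated cells)."""


class MappingError(LifegapError):
    """A lookup (county merge, urbanicity crosswalk) cannot be resolved."""


class ConfigError(LifegapError):
    """An invalid run or scenario configuration."""


class DataError(LifegapError):
    """Counts that cannot be turned into rates (e.g. deaths with zero exposure)."""


class DomainError(LifegapError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class ClosureError(LifegapError):
    """The open-ended age interval cannot be closed (non-positive terminal rate)."""
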