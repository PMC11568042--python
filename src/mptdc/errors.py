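"""Exception types shared across the package."""


class MPTDCError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MPTDCError, ValueError):
    """Unknown model family/variant or an invalid run configuration."""


class DomainError(MPTDCError, ValueError):
    """A numeric input lies outside its mathematically valid domain."""


class InsufficientDataError(MPTDCError, ValueError):
    """Too few observations to carry out the requested computation."""


class ValidationError(MPTDCError, ValueError):
    """Structured input (trial table, count table) failed validation."""
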