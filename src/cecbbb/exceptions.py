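"""Exception hierarchy.

Everything derives from :class:`CecBbbError` and, where sensible, from the
matching builtin so callers can catch either.
"""


class CecBbbError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CecBbbError, ValueError):
    """A value violates a precondition (non-positive time, non-finite number...)."""


class InsufficientDataError(CecBbbError, ValueError):
    """Too few observations for the requested computation."""


class RangeError(CecBbbError, ValueError):
    """A value falls outside the supported table/interpolation range."""


class SingularDesignError(CecBbbError, ValueError):
    """Rank-deficient regression design matrix."""


class ConfigError(CecBbbError, ValueError):
    """Inconsistent or unsupported configuration."""


class StratificationError(CecBbbError, ValueError):
    """A class is too small for the requested stratified fold count."""
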