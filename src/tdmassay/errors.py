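"""Exception hierarchy shared across the package.

Every error raised by tdmassay derives from :class:`AssayError`, so callers
can catch one base class at pipeline boundaries while tests can assert the
specific failure mode.
"""


class AssayError(Exception):
    """Base class for all tdmassay errors."""


class InvalidParameterError(AssayError, ValueError):
    """A model parameter violates its physical constraints (e.g. CL <= 0)."""


class InvalidInputError(AssayError, ValueError):
    """An input value is outside the operation's domain (e.g. negative time)."""


class InsufficientSampleError(AssayError, ValueError):
    """Too few observations for the requested statistic."""


class InvalidRegionError(AssayError, ValueError):
    """A baseline region is too short or overlaps a configured peak window."""


class SingularDesignError(AssayError, ValueError):
    """A regression design matrix is singular (e.g. all levels identical)."""


class NonInvertibleError(AssayError, ValueError):
    """A calibration curve with zero slope cannot be inverted."""


class DegenerateSimulationError(AssayError, ValueError):
    """A simulation produced non-positive percentiles; no range can be derived."""


class DesignError(AssayError, ValueError):
    """A replicate/day design is unbalanced or missing labels."""


class ConfigError(AssayError, ValueError):
    """A run configuration failed validation; message carries the field path."""
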