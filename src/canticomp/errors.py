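"""Exception hierarchy for canticomp.

All package-specific failures derive from :class:`CanticompError` so callers
can catch one base class at the CLI boundary.
"""


class CanticompError(Exception):
    """Base class for all canticomp errors."""


class IdentifiabilityError(CanticompError, ValueError):
    """Calibration data cannot identify a quadratic (rank deficient / short span)."""


class MonotonicityError(CanticompError, ValueError):
    """A fitted or loaded calibration curve is not strictly monotonic on its band."""


class OutOfRangeError(CanticompError, ValueError):
    """A resistance (or temperature) falls outside the admissible calibration band."""


class AmbiguityError(CanticompError, ValueError):
    """Both quadratic roots are admissible; inversion refuses to choose silently."""


class ConfigError(CanticompError, ValueError):
    """Invalid bridge/filter/scenario configuration."""


class SchemaError(CanticompError, ValueError):
    """A CSV or JSON file does not match the expected schema."""
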