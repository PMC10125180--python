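"""Exception hierarchy.

All package errors derive from :class:`PompesimError` so callers can catch
one type; they also subclass ``ValueError`` to behave sanely in plain code.
"""


class PompesimError(ValueError):
    """Base class for all pompesim errors."""


class ConfigError(PompesimError):
    """Invalid plan, scheme, or run configuration."""


class SchemaError(PompesimError):
    """A cohort table is missing columns or contains invalid rows."""
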