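"""Exception and warning types shared across the pipeline."""


class SeaOmegaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SeaOmegaError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class InsufficientDataError(SeaOmegaError, ValueError):
    """Too few usable observations to carry out the requested computation."""


class SchemaError(SeaOmegaError, ValueError):
    """An input table does not match the documented column schema."""


class DegenerateDesignError(SeaOmegaError, ValueError):
    """A statistical design with no usable contrast (e.g. a single ANOVA group)."""


class DegenerateTableWarning(UserWarning):
    """A 2x2 table with a zero margin; the chi-square statistic is defined as 0."""
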