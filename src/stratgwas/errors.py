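"""Exception hierarchy for the stratified-GWAS pipeline.

Every stage raises a subclass of :class:`StratGwasError` so the pipeline
driver can abort with the failing stage's name and cause.
"""


class StratGwasError(Exception):
    """Base class for all package errors."""


class ParseError(StratGwasError):
    """A file could not be parsed; the message names the offending line/record."""


class SchemaError(StratGwasError):
    """A table is missing required columns; the message lists what is available."""


class ConfigError(StratGwasError):
    """Invalid configuration value or inconsistent simulation spec."""


class DomainError(StratGwasError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class CollinearityError(StratGwasError):
    """The regression design matrix is rank deficient; message names columns."""


class InsufficientDataError(StratGwasError):
    """Not enough observations to fit the requested model."""


class StratificationError(StratGwasError):
    """The cohort cannot be split into the requested number of age strata."""


class UnsupportedRecordError(ParseError):
    """A VCF record is outside the supported dialect (e.g. multi-allelic)."""
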