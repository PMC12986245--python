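"""Exception hierarchy for the rfharmonize pipeline."""


class RFHarmonizeError(Exception):
    """Base class for all package errors."""


class SchemaError(RFHarmonizeError):
    """A required column is missing or a table violates its schema."""


class ValidationError(RFHarmonizeError):
    """A row-level value violates an invariant (e.g. negative peak area)."""


class ConfigurationError(RFHarmonizeError):
    """The analysis configuration is inconsistent or infeasible."""
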