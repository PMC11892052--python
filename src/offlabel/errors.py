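"""Exception hierarchy shared across the pipeline stages."""


class OffLabelError(Exception):
    """Base class for all package errors."""


class ValidationError(OffLabelError):
    """A value fails a domain invariant (bad ICD code, bad category, ...)."""


class SchemaError(OffLabelError):
    """An input file is missing required columns or has the wrong layout."""


class IntegrityError(OffLabelError):
    """Cross-table referential integrity is broken (dangling identifiers)."""


class ConfigError(OffLabelError):
    """A configuration object is inconsistent or infeasible."""


class EstimationError(OffLabelError):
    """A model cannot be fit (rank deficiency, degenerate outcome, ...)."""
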