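"""Exception hierarchy for dataset validation and model fitting."""


class EcosirError(Exception):
    """Base class for all package errors."""


class SchemaError(EcosirError):
    """An input table is missing required columns or has wrong dtypes."""


class IntegrityError(EcosirError):
    """Referential integrity violated (e.g. unresolvable municipality id)."""


class ValidationError(EcosirError):
    """A field value violates a documented invariant."""


class ConfigurationError(EcosirError):
    """A run configuration or category scheme cannot be realised on the data."""


class DataError(EcosirError):
    """Internally inconsistent data (e.g. observed cases with zero person-time)."""


class FitError(EcosirError):
    """Model fitting failed (rank deficiency, non-convergence)."""


class UsageError(EcosirError):
    """An operation was invoked on incompatible inputs (e.g. non-nested fits)."""
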