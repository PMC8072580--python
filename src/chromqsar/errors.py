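"""Exception hierarchy for chromqsar."""


class ChromQsarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ChromQsarError):
    """A tabular input does not match the expected column schema."""


class DataValidationError(ChromQsarError):
    """A value violates a domain invariant (e.g. non-positive retention factor)."""


class InsufficientDataError(ChromQsarError):
    """Too few observations for the requested fit."""


class DegenerateFitError(ChromQsarError):
    """A fit produced parameters outside their physically meaningful range."""


class CollinearityError(ChromQsarError):
    """The regression design matrix is rank deficient."""


class MissingPredictorError(ChromQsarError):
    """A model requires a descriptor column that the table does not provide."""
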