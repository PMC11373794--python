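"""Exception hierarchy for anthrobias."""


class AnthrobiasError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AnthrobiasError, ValueError):
    """A distribution, noise or grid parameter is out of its valid domain."""


class InvalidInputError(AnthrobiasError, ValueError):
    """An input collection violates a structural precondition (empty, mismatched)."""


class SchemaError(AnthrobiasError, ValueError):
    """A survey file does not conform to the expected column schema."""


class InsufficientDataError(AnthrobiasError, ValueError):
    """Too few non-missing observations to compute the requested statistic."""


class UndefinedCorrelationError(AnthrobiasError, ValueError):
    """Correlation requested on data with (near-)zero variance in one variable."""
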