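"""Exception hierarchy shared across the pipeline stages."""


class MeetSemgError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MeetSemgError, ValueError):
    """A parameter value is outside its valid domain."""


class FormatError(MeetSemgError, ValueError):
    """A delimited-text file does not match the documented dialect."""


class SchemaError(MeetSemgError, ValueError):
    """Feature columns do not match the schema a model was trained with."""


class InputError(MeetSemgError, ValueError):
    """Invalid runtime input (lengths, labels, non-finite values...)."""


class TrainingError(MeetSemgError, ValueError):
    """The training data cannot support the requested model."""


class DegenerateVarianceError(InputError):
    """Paired differences have zero variance; the t statistic is undefined."""
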