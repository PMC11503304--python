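"""Exception hierarchy shared by all pipeline stages."""


class StressPipeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(StressPipeError):
    """A file could not be parsed (names the offending line where known)."""


class EmptyInputError(StressPipeError):
    """An input file or sequence contained no data."""


class ChannelMismatchError(StressPipeError):
    """Recording does not contain the expected electrode labels."""


class SchemaError(StressPipeError):
    """Feature rows are not homogeneous / do not match the fixed schema."""


class InsufficientDataError(StressPipeError):
    """Too few valid samples or intervals to compute the requested quantity."""


class NyquistError(StressPipeError):
    """A requested filter edge is at or above half the sampling rate."""


class DegenerateSignalError(StressPipeError):
    """Signal has no power/variance so the feature is undefined."""


class InfeasibleLabelingError(StressPipeError):
    """Requested number of labelled blocks exceeds the session length."""


class DegenerateTrainingError(StressPipeError):
    """Training set contains a single class; the scorer cannot be fit."""


class EmptyBlockError(StressPipeError):
    """A block contains no epoch scores to vote over."""


class ResponseMismatchError(StressPipeError):
    """Number of responses does not match the number of trials."""
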