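"""Exception hierarchy for the pipeline.

Rejections that are part of normal operation (e.g. a dendrite too short for
ROI placement) are returned as result objects, not raised; these exceptions
mark genuinely invalid inputs or parameters.
"""


class StriacalError(Exception):
    """Base class for all package errors."""


class ParameterError(StriacalError, ValueError):
    """A configuration value violates its contract (e.g. cutoff >= Nyquist)."""


class InputError(StriacalError, ValueError):
    """Input data are missing or malformed (e.g. no dark frames)."""


class ProtocolError(StriacalError, ValueError):
    """A stimulus protocol is inconsistent with the recording."""


class ProcessingError(StriacalError, RuntimeError):
    """A processing stage could not produce a valid result."""


class FitError(StriacalError, RuntimeError):
    """A model fit could not be performed on the given data."""
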