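"""Exception hierarchy.

Validation errors (bad input data or parameters) and computation errors
(a method cannot run on otherwise valid data) are kept distinct so the
command line can map them to different exit codes.
"""


class RefstabError(Exception):
    """Base class for all package errors."""


class InputValidationError(RefstabError, ValueError):
    """Input data violates a documented contract (bad cell, duplicate id...)."""


class FormatError(InputValidationError):
    """A file could not be parsed as the expected table layout."""


class ParameterError(InputValidationError):
    """A user-supplied parameter is out of its valid range."""


class DesignError(InputValidationError):
    """The sample-to-group design is unusable (unlabeled sample, group too small)."""


class ComputationError(RefstabError):
    """A method cannot be computed on the given (valid) input."""


class InsufficientDataError(ComputationError):
    """Too few genes, samples, or points for the requested statistic."""


class InvalidCurveError(ComputationError):
    """A standard-curve fit produced a physically impossible slope."""
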