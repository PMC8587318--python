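"""Exception types raised across the package."""


class ClustharError(ValueError):
    """Base class for all package-specific errors."""


class InvalidSpecError(ClustharError):
    """A partition/classifier/synthetic spec is internally inconsistent."""


class DataError(ClustharError):
    """Input data violates a precondition (non-finite values, constant rows...)."""


class ConsistencyError(ClustharError):
    """Two inputs that must describe the same samples or labels disagree."""


class EmptyClusterError(ClustharError):
    """A cluster with no members was passed where members are required."""


class InvalidThresholdError(ClustharError):
    """Confusion threshold outside the half-open interval (0, 1]."""


class DegenerateDataError(ClustharError):
    """A training set with fewer than two classes."""


class FormatError(ClustharError):
    """A file on disk does not match the declared layout."""
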