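"""Exception hierarchy for craniomorph."""


class CraniomorphError(Exception):
    """Base class for all craniomorph errors."""


class FormatError(CraniomorphError):
    """A file could not be read in the expected format."""


class DimensionalityError(FormatError):
    """A volume did not have the expected number of dimensions."""


class ParameterError(CraniomorphError, ValueError):
    """An invalid parameter value was supplied."""


class SingularTransformError(CraniomorphError):
    """An affine transform is not invertible."""


class DomainError(CraniomorphError):
    """Input outside the mathematical domain of an operation."""


class DesignError(CraniomorphError):
    """A statistical design matrix is unusable (rank-deficient, constant)."""


class PairingError(CraniomorphError):
    """Two landmark sets could not be put into correspondence."""


class ConfigurationError(CraniomorphError):
    """A pipeline or mask configuration is inconsistent with the data."""
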