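"""Exception hierarchy shared across the package."""


class NetfluxError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(NetfluxError):
    """Array shapes are inconsistent; the message names the offending axis."""


class SingularModelError(NetfluxError):
    """A static model's (I - C) is singular or too ill-conditioned to invert."""


class UnknownNodeError(NetfluxError):
    """A node, input, or inhibitor name does not resolve against the model."""


class DataError(NetfluxError):
    """Malformed input data: missing values, duplicate ids, non-numeric cells."""


class SolverError(NetfluxError):
    """The gain computation failed; carries the underlying solver status."""
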