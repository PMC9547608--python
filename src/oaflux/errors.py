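"""Exception hierarchy shared across the toolkit."""


class OafluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OafluxError):
    """A configuration value is invalid or inconsistent."""


class DegenerateInputError(OafluxError):
    """An input is formally valid but degenerate for the requested operation
    (all-constant image, empty mask class, all-zero sinogram, ...)."""


class SolverError(OafluxError):
    """An iterative solver failed to reach the requested tolerance."""


class StabilityError(OafluxError):
    """A time-stepping configuration violates its stability condition."""


class GeometryError(OafluxError):
    """Detector or source geometry falls outside the valid region."""


class ShapeError(OafluxError):
    """Array shapes are inconsistent with the operation's contract."""
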