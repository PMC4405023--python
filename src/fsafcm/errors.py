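"""Exception types shared across the package."""


class FsafcmError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FsafcmError, ValueError):
    """An argument is outside its documented range or names an unknown option."""


class ConsistencyError(FsafcmError, ValueError):
    """Two inputs that must describe the same image disagree (shape, radius)."""


class DegenerateCentersError(FsafcmError, ValueError):
    """Two cluster centers coincide exactly; memberships are undefined."""


class DegenerateClusterError(FsafcmError, ValueError):
    """A cluster has zero total membership mass; its center is undefined."""


class EmptyParenchymaError(FsafcmError, ValueError):
    """No interior dark component was found when extracting the lung fields."""


class GeometryError(FsafcmError, ValueError):
    """A requested phantom shape does not fit inside the image frame."""


class MissingTraceError(FsafcmError, ValueError):
    """A per-iteration trace was requested from a run that did not record one."""
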