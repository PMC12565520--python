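"""Exception hierarchy for the cwhto package."""


class CwhtoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CwhtoError, ValueError):
    """Invalid phantom, plan, or configuration parameter."""


class ValidationError(CwhtoError):
    """A mesh failed a structural check (watertightness, orientation, volume)."""


class SchemaError(CwhtoError):
    """A landmark, record, or config file does not match the documented schema."""


class FrameError(CwhtoError):
    """Anatomical frame could not be built from the given landmarks."""


class GeometryError(CwhtoError):
    """A geometric construction failed (empty section, plane missing the mesh, ...)."""


class StatError(CwhtoError, ValueError):
    """A statistical comparison was requested on unsuitable samples."""


class BatchError(CwhtoError):
    """Every cell of a cohort batch failed."""
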