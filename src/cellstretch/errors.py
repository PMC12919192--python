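"""Exception hierarchy for cellstretch."""


class CellStretchError(Exception):
    """Base class for all cellstretch errors."""


class InvalidParameterError(CellStretchError, ValueError):
    """A scalar parameter violates its stated bounds."""


class InvalidShapeError(CellStretchError, ValueError):
    """A waveform shape table is malformed (non-normalizable, non-periodic, ...)."""


class GeometryError(CellStretchError, ValueError):
    """Cell/nucleus geometry violates a containment or positivity constraint."""


class MeshingError(CellStretchError, RuntimeError):
    """The mesher failed to produce a valid labeled tetrahedral mesh."""


class ConfigurationError(CellStretchError, ValueError):
    """A configuration block is inconsistent or incomplete."""


class SolverError(CellStretchError, RuntimeError):
    """The linear viscoelastic solve failed (singular system, missing constraints)."""
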