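"""Exception hierarchy shared across the package."""


class CraniosymError(Exception):
    """Base class for all package errors."""


class MeshFormatError(CraniosymError):
    """Unknown or unparseable mesh format."""


class LandmarkError(CraniosymError):
    """Invalid, duplicated or incomplete landmark data."""


class AlignmentError(CraniosymError):
    """Canonical head frame could not be estimated."""


class DegenerateGeometryError(CraniosymError):
    """Coincident points, zero-length segments or singular control sets."""


class MeshError(CraniosymError):
    """Mesh does not satisfy a geometric precondition (e.g. watertightness)."""


class GenerationError(CraniosymError):
    """Synthetic subject could not be realised from the drawn targets."""
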