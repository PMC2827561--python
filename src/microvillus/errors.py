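"""Exception hierarchy shared across the package."""


class MicrovillusError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MicrovillusError, ValueError):
    """An input parameter is outside its valid domain."""


class DegenerateSymmetryError(ParameterError):
    """Zero twist (or otherwise degenerate) helical symmetry."""


class UnsupportedSymmetryError(MicrovillusError):
    """Operation requires a closed (u/t) symmetry but none was detected."""


class GeometryError(MicrovillusError, ValueError):
    """Geometrically impossible configuration (overlap, negative gap...)."""


class PlacementError(MicrovillusError):
    """No admissible placement survived the selection criteria."""


class StructureIOError(MicrovillusError):
    """Structure file could not be parsed or written."""


class InsufficientDataError(MicrovillusError):
    """Too few observations for the requested fit or estimate."""
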