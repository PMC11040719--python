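"""Exception hierarchy for interface search and scoring."""


class IfaceSearchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(IfaceSearchError):
    """A structure file could not be read or understood."""


class EmptyStructureError(ParseError):
    """A parsed file contained no polymer protein chains."""


class NoInterfaceError(IfaceSearchError):
    """No interface atoms remain (chains too far apart, or reduction emptied a side)."""


class TooSmallInterfaceError(IfaceSearchError):
    """Fewer than four interface points; no tetrahedron can be built."""


class DegenerateGeometryError(IfaceSearchError):
    """Matched points are collinear/coplanar; superposition is unreliable."""


class ConfigurationError(IfaceSearchError):
    """Database and query parameters are inconsistent (e.g. hierarchy level mismatch)."""


class UndefinedMetricError(IfaceSearchError):
    """A benchmark metric is undefined for the given labels (e.g. single-class input)."""
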