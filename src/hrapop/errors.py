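"""Exception hierarchy.

Every error raised by this package derives from :class:`HrapopError` so
callers can catch the whole family with one clause.
"""


class HrapopError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(HrapopError):
    """A geometric primitive violates its preconditions (e.g. non-positive
    cuboid dimension, degenerate face)."""


class NotClosedError(InvalidGeometryError):
    """An operation requiring a watertight mesh received an open one."""


class RepairFailedError(InvalidGeometryError):
    """Hole filling could not produce a closed, manifold mesh."""


class InvalidParameterError(HrapopError):
    """A numeric parameter is out of its documented range."""


class OrganMismatchError(HrapopError):
    """An extraction site targets a different reference organ than the one
    it is being collided against."""


class InfeasibleDomainError(HrapopError):
    """The corridor search domain is empty: the target structures are too
    far apart for the fixed-size tissue block to reach all of them."""


class NoCollisionError(HrapopError):
    """Corridor computation requires at least one mesh collision."""


class EmptyInputError(HrapopError):
    """An operation requiring at least one record received none."""


class DuplicateCellError(HrapopError):
    """A cell table contains a repeated cell id; upstream splitting bug."""


class NoContrastError(HrapopError):
    """Marker ranking requires at least two cell-type groups."""


class ProvenanceError(HrapopError):
    """An aggregation input is missing its required provenance record
    (e.g. a site population without a collision record for the AS)."""
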