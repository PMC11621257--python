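"""Exception hierarchy.

Distinct classes so the CLI can map failures to distinct exit codes:
I/O and format problems, geometry refusals, and statistics preconditions.
"""


class PulmofatError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(PulmofatError):
    """Unreadable, ambiguous, or invalid image/mask input (I/O stage)."""


class GeometryMismatchError(PulmofatError):
    """Image and mask do not share an identical voxel grid; never resampled."""


class EmptyMaskError(PulmofatError):
    """An operation requires a non-empty (or non-full) mask."""


class PlacementError(PulmofatError):
    """Phantom inclusion placement constraint infeasible after bounded sampling."""


class StatisticsPreconditionError(PulmofatError):
    """A statistical test's sample-size or grouping precondition is violated."""
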