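"""Typed failure taxonomy.

Every stage raises a distinct exception so callers (and the CLI exit-code
mapping) can classify outcomes without string matching.
"""


class FragstitchError(Exception):
    """Base class for all pipeline failures."""


class ParseError(FragstitchError):
    """Input file or SMILES could not be parsed."""


class MappingFailure(FragstitchError):
    """No hit yielded any atom correspondence; placement cannot proceed."""


class PlacementFailure(FragstitchError):
    """Conformer generation or coordinate stitching failed."""


class LinkFailure(FragstitchError):
    """No substitutable atom pair available to bridge disconnected parts."""


class DistanceFailure(FragstitchError):
    """A hit remained beyond the join cutoff after deferral."""

    def __init__(self, hit_id: str, min_distance: float):
        self.hit_id = hit_id
        self.min_distance = min_distance
        super().__init__(
            f"hit {hit_id!r} is {min_distance:.2f} A from the accumulated "
            "merger, beyond the join cutoff"
        )


class RectificationFailure(FragstitchError):
    """Chemical repair did not reach a valid fixpoint."""


class MinimisationFailure(FragstitchError):
    """Force-field setup or minimisation failed."""


class CovalentConflict(FragstitchError):
    """A merge would modify a protected warhead atom."""
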