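"""Exception hierarchy shared by all treegrid modules."""


class TreeGridError(Exception):
    """Base class for all treegrid errors."""


class SchemaError(TreeGridError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(TreeGridError):
    """A value violates a documented invariant (bad coordinate, negative trait...)."""


class LookupError_(TreeGridError):
    """A species or taxon could not be resolved in the trait database."""


class DegenerateDistributionError(TreeGridError):
    """A statistic needs spread the data does not have (e.g. < 2 distinct heights)."""


class PlacementConflictError(TreeGridError):
    """Strict placement rejected a tree; carries the ConflictResult."""

    def __init__(self, message, conflict):
        super().__init__(message)
        self.conflict = conflict


class RasterError(TreeGridError):
    """A raster file is unreadable, multi-band, or lacks georeferencing."""
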