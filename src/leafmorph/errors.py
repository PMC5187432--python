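"""Exception hierarchy for the leafmorph pipeline.

Every stage raises a subclass of :class:`LeafmorphError` carrying a short
machine-readable ``code`` so the CLI can abort with the stage name and code.
"""


class LeafmorphError(Exception):
    """Base class for all pipeline errors."""

    code = "error"


class ConfigurationError(LeafmorphError):
    """Invalid configuration; the message names the offending field."""

    code = "config"


class DataError(LeafmorphError):
    """Invalid or insufficient input data."""

    code = "data"


class TableLoadError(DataError):
    """Species-table validation failure with row/column coordinates."""

    code = "table_load"


class GeometryError(LeafmorphError):
    """Invalid outline geometry (self-intersection, too few vertices...)."""

    code = "geometry"


class TopologyError(GeometryError):
    """Split polyline does not partition the outline into two fields."""

    code = "topology"


class InfeasibleShapeError(LeafmorphError):
    """Requested shape descriptors unreachable for the outline family.

    ``achievable`` holds the (lo, hi) range the family can reach.
    """

    code = "infeasible_shape"

    def __init__(self, message, achievable=None):
        super().__init__(message)
        self.achievable = achievable


class ExtrapolationError(GeometryError):
    """No admissible completion arc exists for the open outline."""

    code = "extrapolation"


class FitError(LeafmorphError):
    """Nonlinear least-squares fit failed; message carries diagnostics."""

    code = "fit"


class InsufficientReferenceError(FitError):
    """Too few reference (Pterochrozinae) rows to fit the frozen component."""

    code = "insufficient_reference"
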