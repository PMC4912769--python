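"""Exception hierarchy used across the pipeline."""


class GliamorphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GliamorphError):
    """Invalid archetype / algorithm parameters."""


class ConfigError(GliamorphError):
    """Invalid pipeline configuration (caught before any computation)."""


class DataError(GliamorphError):
    """Missing or inconsistent input data."""


class GeometryError(GliamorphError):
    """Impossible raster geometry (ragged tiles, too few planes, ...)."""


class PlacementError(GliamorphError):
    """Cell placement at the requested spacing is infeasible.

    Carries ``achievable`` — how many cells could actually be placed.
    """

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"could only place {achievable} of {requested} cells at the "
            "requested spacing; reduce n_cells, spacing, or enlarge the field"
        )


class OrderingError(GliamorphError):
    """Branch ordering requested on an unrooted / unattributed tree."""


class UndefinedCIError(GliamorphError):
    """Complexity index undefined (cell has no primary ramification)."""
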