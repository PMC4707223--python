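"""Exception hierarchy for pepcoord."""


class PepcoordError(Exception):
    """Base class for all pepcoord errors."""


class ChainNotFoundError(PepcoordError):
    """Requested chain is absent from the file, or empty after filtering."""


class EmptySelectionError(PepcoordError):
    """A selection (species pair, residue, environment) matched nothing."""


class DuplicateAtomError(PepcoordError):
    """Two atoms occupy the same position (zero interatomic distance)."""


class DegenerateVolumeError(PepcoordError):
    """Bounding box of the coordinates has zero volume."""


class GridMismatchError(PepcoordError):
    """Two curves/profiles were built on different r grids."""


class ProtonationError(PepcoordError):
    """Structure cannot be protonated (unknown residue, existing H, ...)."""


class GeometryError(PepcoordError):
    """Synthetic chain construction failed (clash tolerance exceeded)."""


class DegenerateDeviationError(PepcoordError):
    """Total coordination deviation is zero; percentages are undefined."""
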