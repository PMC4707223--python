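"""Pair-correlation numerics: distance histograms, PDF, RDF and coordination.

Conventions
-----------
* Distances are binned half-open, ``[i*dr, (i+1)*dr)``; a distance exactly on
  a boundary goes to the bin whose lower edge it is.  The partition is
  exhaustive and deterministic.
* The pair distribution function is
  ``g(r) = counts / (2 pi N r_c^2 rho0 dr)`` with ``r_c`` the bin center;
  partials are normalized with the *same* ``N`` and ``rho0`` as the total, so
  the species-pair partials sum bin-by-bin to the total curve.
* The radial distribution function is ``R(r) = 4 pi r_c^2 rho0 g(r)``.  With
  the bin-center convention this collapses to ``R * dr = 2 * counts / N``
  exactly, which makes coordination integrals independent of the prefactor
  convention: integrating R over the full range returns ``N - 1``.
* Coordination over a window ``[r1, r2)`` sums ``R * dr`` over bins lying
  fully inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import (
    DuplicateAtomError,
    EmptySelectionError,
    GridMismatchError,
)
from .structure_io import StructureModel

_EDGE_TOL = 1e-9


def parse_selector(selector: str) -> tuple[str, str] | None:
    """``"total"`` -> None; ``"C-N"`` -> ("C", "N") (order-normalized)."""
    sel = selector.strip()
    if sel.lower() == "total":
        return None
    parts = sel.split("-")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"bad pair selector {selector!r}; expected 'total' or 'X-Y'")
    a, b = sorted(p.strip().upper() for p in parts)
    return a, b


def canonical_selector(selector: str) -> str:
    pair = parse_selector(selector)
    return "total" if pair is None else f"{pair[0]}-{pair[1]}"


@dataclass
class PairHistogram:
    """Binned unordered interatomic-distance counts for one species selector."""

    bin_size: float
    counts: np.ndarray  # integer counts per bin
    pair_selector: str
    n_atoms: int
    rho0: float
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def r_max(self) -> float:
        return self.n_bins * self.bin_size

    @property
    def r_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_size

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


@dataclass
class CorrelationCurve:
    """g(r) (kind='PDF', dimensionless) or R(r) (kind='RDF', atoms/A)."""

    r_grid: np.ndarray  # bin centers, A
    values: np.ndarray
    kind: str
    bin_size: float
    n_atoms: int
    rho0: float
    pair_selector: str = "total"
    label: str = ""

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("PDF", "RDF"):
            raise ValueError(f"kind must be 'PDF' or 'RDF', got {self.kind!r}")
        if self.r_grid.shape != self.values.shape:
            raise ValueError("r_grid and values must have the same shape")


@dataclass
class CoordinationProfile:
    """Cumulative coordination n(0, r) per atom, on the histogram grid.

    ``n_cum[i]`` is the coordination accumulated up to the *upper edge* of
    bin i (the grid stores bin centers).
    """

    r_grid: np.ndarray
    n_cum: np.ndarray
    bin_size: float
    pair_selector: str = "total"
    label: str = ""

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.n_cum = np.asarray(self.n_cum, dtype=float)


@dataclass
class CoordinationDelta:
    """Per-bin cumulative-coordination difference, variant minus index."""

    r_grid: np.ndarray
    delta: np.ndarray
    index_label: str = "index"
    variant_label: str = "variant"
    bin_size: float = 0.1
    pair_selector: str = "total"


# ---------------------------------------------------------------------------
# histogram construction
# ---------------------------------------------------------------------------

def _selected_distances(s: StructureModel, selector: str) -> np.ndarray:
    pair = parse_selector(selector)
    elements = np.char.upper(s.elements.astype("U2"))
    if pair is None:
        if s.n_atoms < 2:
            raise EmptySelectionError("need at least 2 atoms for a histogram")
        return pdist(s.coords)
    a, b = pair
    if a == b:
        sub = s.coords[elements == a]
        if len(sub) < 2:
            raise EmptySelectionError(
                f"fewer than 2 {a} atoms; cannot build {a}-{b} histogram"
            )
        return pdist(sub)
    ca = s.coords[elements == a]
    cb = s.coords[elements == b]
    if len(ca) == 0 or len(cb) == 0:
        raise EmptySelectionError(
            f"selector {a}-{b} matches no atom pairs in {s.label!r}"
        )
    return cdist(ca, cb).ravel()


def _check_duplicates(s: StructureModel) -> None:
    d = pdist(s.coords)
    if d.size and d.min() == 0.0:
        n = s.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        bad = np.nonzero(d == 0.0)[0][:5]
        pairs = ", ".join(
            f"{s.atom_names[iu[k]]}(res {s.residue_indices[iu[k]]})/"
            f"{s.atom_names[ju[k]]}(res {s.residue_indices[ju[k]]})"
            for k in bad
        )
        raise DuplicateAtomError(f"zero-distance atom pairs: {pairs}")


def build_histogram(
    s: StructureModel,
    pair_selector: str = "total",
    bin_size: float = 0.1,
    r_max: float | None = None,
) -> PairHistogram:
    """Histogram of unordered selected-pair distances below ``r_max``.

    ``r_max`` defaults to the structure's maximum interatomic distance
    rounded up to a whole bin, so every pair is counted.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    _check_duplicates(s)
    d = _selected_distances(s, pair_selector)
    if r_max is None:
        dmax = float(pdist(s.coords).max())
        r_max = (np.floor(dmax / bin_size + _EDGE_TOL) + 1.0) * bin_size
    if r_max < bin_size:
        raise ValueError("r_max must be at least one bin")
    n_bins = int(np.ceil(r_max / bin_size - _EDGE_TOL))
    idx = np.floor(d / bin_size + _EDGE_TOL).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return PairHistogram(
        bin_size=bin_size,
        counts=counts,
        pair_selector=canonical_selector(pair_selector),
        n_atoms=s.n_atoms,
        rho0=s.rho0,
        label=s.label,
    )


# ---------------------------------------------------------------------------
# PDF / RDF / coordination
# ---------------------------------------------------------------------------

def pdf_from_histogram(h: PairHistogram) -> CorrelationCurve:
    """g(r) = counts / (2 pi N r_c^2 rho0 dr), on bin centers."""
    if h.rho0 <= 0:
        raise ValueError("rho0 must be positive")
    r_c = h.r_centers
    norm = 2.0 * np.pi * h.n_atoms * r_c**2 * h.rho0 * h.bin_size
    g = h.counts / norm
    return CorrelationCurve(
        r_grid=r_c, values=g, kind="PDF", bin_size=h.bin_size,
        n_atoms=h.n_atoms, rho0=h.rho0, pair_selector=h.pair_selector,
        label=h.label,
    )


def rdf_from_pdf(c: CorrelationCurve) -> CorrelationCurve:
    """R(r) = 4 pi r_c^2 rho0 g(r)."""
    if c.kind != "PDF":
        raise ValueError(f"expected a PDF curve, got kind={c.kind!r}")
    values = 4.0 * np.pi * c.r_grid**2 * c.rho0 * c.values
    return CorrelationCurve(
        r_grid=c.r_grid, values=values, kind="RDF", bin_size=c.bin_size,
        n_atoms=c.n_atoms, rho0=c.rho0, pair_selector=c.pair_selector,
        label=c.label,
    )


def _window_bins(r_grid: np.ndarray, bin_size: float, r1: float, r2: float) -> np.ndarray:
    lo = r_grid - bin_size / 2.0
    hi = r_grid + bin_size / 2.0
    return (lo >= r1 - _EDGE_TOL) & (hi <= r2 + _EDGE_TOL)


def coordination(c: CorrelationCurve, r1: float, r2: float) -> float:
    """Coordination number over [r1, r2): sum of R*dr over fully-inside bins."""
    if c.kind != "RDF":
        raise ValueError("coordination requires an RDF curve")
    if not (0.0 <= r1 < r2):
        raise ValueError(f"need 0 <= r1 < r2, got ({r1}, {r2})")
    grid_max = c.r_grid[-1] + c.bin_size / 2.0 if len(c.r_grid) else 0.0
    if r2 > grid_max + _EDGE_TOL:
        raise ValueError(
            f"window upper bound {r2} exceeds computed grid ({grid_max:.3f} A)"
        )
    mask = _window_bins(c.r_grid, c.bin_size, r1, r2)
    return float(np.sum(c.values[mask]) * c.bin_size)


def cumulative_profile(c: CorrelationCurve) -> CoordinationProfile:
    """Running integral n(0, r) of the RDF; non-decreasing by construction."""
    if c.kind != "RDF":
        raise ValueError("cumulative_profile requires an RDF curve")
    n_cum = np.cumsum(c.values) * c.bin_size
    return CoordinationProfile(
        r_grid=c.r_grid, n_cum=n_cum, bin_size=c.bin_size,
        pair_selector=c.pair_selector, label=c.label,
    )


def coordination_delta(
    variant: CoordinationProfile, index: CoordinationProfile
) -> CoordinationDelta:
    """Per-bin difference of cumulative coordination, variant minus index."""
    if len(variant.r_grid) != len(index.r_grid) or not np.allclose(
        variant.r_grid, index.r_grid, atol=1e-9
    ):
        raise GridMismatchError(
            "profiles are on different r grids; rebuild with a common "
            "bin_size and r_max"
        )
    return CoordinationDelta(
        r_grid=variant.r_grid.copy(),
        delta=variant.n_cum - index.n_cum,
        index_label=index.label,
        variant_label=variant.label,
        bin_size=variant.bin_size,
        pair_selector=variant.pair_selector,
    )


# ---------------------------------------------------------------------------
# conveniences
# ---------------------------------------------------------------------------

def cumulative_coordination(
    s: StructureModel,
    pair_selector: str = "total",
    bin_size: float = 0.1,
    r_max: float | None = None,
) -> CoordinationProfile:
    """Histogram -> PDF -> RDF -> cumulative coordination, in one call."""
    h = build_histogram(s, pair_selector, bin_size, r_max)
    return cumulative_profile(rdf_from_pdf(pdf_from_histogram(h)))


def first_shell_peak(c: CorrelationCurve, r_limit: float = 2.0) -> float:
    """Position of the maximum of the curve below ``r_limit``.

    Reported as the bin *lower edge* to one decimal, matching the convention
    of labelling a bin [1.5, 1.6) as 1.5.
    """
    mask = c.r_grid < r_limit
    if not mask.any() or not np.any(c.values[mask] > 0):
        raise EmptySelectionError(f"no occupied bins below {r_limit} A")
    sub = np.where(mask, c.values, -np.inf)
    i = int(np.argmax(sub))
    lower_edge = c.r_grid[i] - c.bin_size / 2.0
    return float(round(lower_edge, 1))
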