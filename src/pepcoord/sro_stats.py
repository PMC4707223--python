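"""Short-range-order statistics for atomic clusters centered on one species."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptySelectionError
from .structure_io import ATOMIC_MASSES, DA_PER_A3_TO_G_PER_CM3, StructureModel


@dataclass
class SpeciesClusterStats:
    """Average cluster statistics for clusters centered on one species.

    Cluster volume is the sphere of radius ``cutoff``; the central atom is
    counted in the densities (hence mean_cn + 1).
    """

    central_species: str
    cutoff: float
    n_central: int
    mean_cn: float
    cluster_number_density: float  # atoms/A^3
    cluster_mass_density: float  # g/cm^3
    weighted_mean_distance: float  # A


def cluster_stats(
    s: StructureModel,
    central: str,
    cutoff: float = 4.0,
    bin_size: float = 0.1,
) -> SpeciesClusterStats:
    """Mean coordination number, cluster densities and the distance-weighted
    mean neighbor separation for clusters centered on ``central`` atoms.

    The weighted mean is ``sum(x_i * N_i) / sum(N_i)`` over distance-histogram
    bins up to the cutoff, with ``x_i`` the bin center and ``N_i`` the count
    of central-to-neighbor distances in that bin.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    central = central.upper()
    elements = np.char.upper(s.elements.astype("U2"))
    mask = elements == central
    if not mask.any():
        raise EmptySelectionError(f"no {central} atoms in {s.label!r}")
    centers = s.coords[mask]
    tree = cKDTree(s.coords)
    masses = np.array([ATOMIC_MASSES[str(e)] for e in elements])
    sphere_volume = 4.0 / 3.0 * np.pi * cutoff**3

    neighbor_lists = tree.query_ball_point(centers, r=cutoff)
    center_idx = np.nonzero(mask)[0]
    cns = np.empty(len(centers))
    cluster_masses = np.empty(len(centers))
    dists: list[np.ndarray] = []
    for k, (ci, nbrs) in enumerate(zip(center_idx, neighbor_lists)):
        nbrs = np.array([j for j in nbrs if j != ci], dtype=int)
        cns[k] = len(nbrs)
        cluster_masses[k] = masses[ci] + masses[nbrs].sum()
        if len(nbrs):
            dists.append(np.linalg.norm(s.coords[nbrs] - centers[k], axis=1))
    mean_cn = float(cns.mean())
    number_density = (mean_cn + 1.0) / sphere_volume
    mass_density = float(cluster_masses.mean()) / sphere_volume * DA_PER_A3_TO_G_PER_CM3

    if dists:
        d = np.concatenate(dists)
        n_bins = int(np.ceil(cutoff / bin_size))
        idx = np.floor(d / bin_size + 1e-9).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        x = (np.arange(n_bins) + 0.5) * bin_size
        weighted = float((x * counts).sum() / counts.sum())
    else:
        weighted = float("nan")

    return SpeciesClusterStats(
        central_species=central,
        cutoff=cutoff,
        n_central=len(centers),
        mean_cn=mean_cn,
        cluster_number_density=float(number_density),
        cluster_mass_density=float(mass_density),
        weighted_mean_distance=weighted,
    )
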