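"""Reading PDB structures, chain/environment selection and bulk properties.

The central container is :class:`StructureModel`, a column-oriented set of
atoms (element, residue identity, backbone/side-chain role, coordinates).
Volume is, by convention, the axis-aligned bounding box of the coordinates
(zero margin unless requested); the number density ``rho0 = N / V`` is what
normalizes every pair-correlation function downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ChainNotFoundError, DegenerateVolumeError, EmptySelectionError

#: Heavy-atom names forming the peptide backbone.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Hydrogen names attached to backbone heavy atoms (PDB v3 naming).
BACKBONE_HYDROGENS = frozenset(
    {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT", "HN"}
)

#: IUPAC standard atomic weights (Da) for the species handled here.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

#: 1 Da/A^3 expressed in g/cm^3.
DA_PER_A3_TO_G_PER_CM3 = 1.66054

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def atom_role(atom_name: str, element: str) -> str:
    """Classify an atom name as ``backbone`` or ``sidechain``."""
    name = atom_name.strip().upper()
    if element.upper() == "H":
        return "backbone" if name in BACKBONE_HYDROGENS else "sidechain"
    return "backbone" if name in BACKBONE_ATOMS else "sidechain"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: species, residue identity, role and position (Angstrom)."""

    element: str
    atom_name: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    role: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {pos}")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError("element must not be empty")
        if self.role not in ("backbone", "sidechain"):
            raise ValueError(f"invalid role {self.role!r}")


class StructureModel:
    """A set of atoms with a bounding volume and derived densities.

    Atom attributes are stored as parallel numpy arrays; ``atoms`` iterates
    over :class:`AtomRecord` views.  ``volume`` defaults to the axis-aligned
    bounding-box volume but may be fixed explicitly (e.g. for a known
    simulation box).
    """

    def __init__(
        self,
        elements: Sequence[str],
        atom_names: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        roles: Sequence[str] | None = None,
        label: str = "",
        volume: float | None = None,
    ) -> None:
        self.elements = np.asarray(elements, dtype="U2")
        self.atom_names = np.asarray(atom_names, dtype="U4")
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U3")
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if roles is None:
            roles = [
                atom_role(n, e) for n, e in zip(self.atom_names, self.elements)
            ]
        self.roles = np.asarray(roles, dtype="U9")
        self.label = label
        self._explicit_volume = volume
        n = len(self.coords)
        if not (
            len(self.elements) == len(self.atom_names) == len(self.residue_indices)
            == len(self.residue_names) == len(self.chain_ids) == len(self.roles) == n
        ):
            raise ValueError("attribute arrays have inconsistent lengths")
        if n < 1:
            raise EmptySelectionError("a StructureModel needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                element=str(self.elements[i]),
                atom_name=str(self.atom_names[i]),
                residue_index=int(self.residue_indices[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i].copy(),
                role=str(self.roles[i]),
            )

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            self.elements[mask],
            self.atom_names[mask],
            self.residue_indices[mask],
            self.residue_names[mask],
            self.chain_ids[mask],
            self.coords[mask],
            self.roles[mask],
            label=self.label if label is None else label,
        )

    def sequence(self) -> str:
        """One-letter sequence of the residues, in residue-index order."""
        letters = []
        seen: set[int] = set()
        for idx, name in zip(self.residue_indices, self.residue_names):
            if idx not in seen:
                seen.add(idx)
                letters.append(THREE_TO_ONE.get(str(name), "X"))
        return "".join(letters)

    # -- bulk properties ---------------------------------------------------
    def bounding_box_volume(self, margin: float = 0.0) -> float:
        span = self.coords.max(axis=0) - self.coords.min(axis=0) + 2.0 * margin
        return float(np.prod(span))

    @property
    def volume(self) -> float:
        if self._explicit_volume is not None:
            return self._explicit_volume
        return self.bounding_box_volume()

    @property
    def rho0(self) -> float:
        return self.n_atoms / self.volume

    @property
    def total_mass(self) -> float:
        masses = [ATOMIC_MASSES[str(e).upper()] for e in self.elements]
        return float(sum(masses))

    @property
    def mass_density(self) -> float:
        """Mass density in g/cm^3 (1 Da/A^3 = 1.66054 g/cm^3)."""
        return self.total_mass / self.volume * DA_PER_A3_TO_G_PER_CM3

    def max_pair_distance(self) -> float:
        # diameter of the point set; O(N^2) is fine at these sizes
        from scipy.spatial.distance import pdist

        if self.n_atoms < 2:
            return 0.0
        return float(pdist(self.coords).max())


class BulkProperties(NamedTuple):
    n_atoms: int
    volume: float
    rho0: float
    mass_density: float


def bulk_properties(s: StructureModel, margin: float = 0.0) -> BulkProperties:
    """Atom count, bounding-box volume, number density and mass density.

    ``margin`` pads the bounding box on every side before the volume is
    computed; the default (0) is the plain axis-aligned bounding box.
    """
    if margin > 0.0 or s._explicit_volume is None:
        volume = s.bounding_box_volume(margin)
    else:
        volume = s.volume
    if volume <= 0.0:
        raise DegenerateVolumeError(
            "bounding box has zero volume (collinear/coplanar atoms)"
        )
    rho0 = s.n_atoms / volume
    mass_density = s.total_mass / volume * DA_PER_A3_TO_G_PER_CM3
    return BulkProperties(s.n_atoms, volume, rho0, mass_density)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _model_from_atom_array(arr, label: str) -> StructureModel:
    """Build a StructureModel from a biotite AtomArray, re-indexing residues
    1..n within each chain in order of appearance."""
    n = arr.array_length()
    residue_indices = np.zeros(n, dtype=int)
    counter: dict[str, int] = {}
    last_key = None
    for i in range(n):
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i] if hasattr(arr, "ins_code") else "")
        if key != last_key:
            chain = str(arr.chain_id[i])
            counter[chain] = counter.get(chain, 0) + 1
            last_key = key
        residue_indices[i] = counter[str(arr.chain_id[i])]
    elements = [str(e).upper() for e in arr.element]
    return StructureModel(
        elements=elements,
        atom_names=[str(a) for a in arr.atom_name],
        residue_indices=residue_indices,
        residue_names=[str(r) for r in arr.res_name],
        chain_ids=[str(c) for c in arr.chain_id],
        coords=np.asarray(arr.coord, dtype=float),
        label=label,
    )


def read_pdb(
    path: str | Path,
    chain: str | None,
    include_hydrogens: bool = False,
    include_hetero: bool = False,
    label: str | None = None,
) -> StructureModel:
    """Read one chain (or all chains when ``chain`` is None) from a PDB file.

    Alternate locations are resolved to the first conformer; HETATM records
    (waters, ligands) are dropped unless ``include_hetero`` is set; hydrogens
    are dropped unless ``include_hydrogens`` is set.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except ValueError as exc:
        raise ChainNotFoundError(f"no coordinate records in {path.name}") from exc
    mask = np.ones(arr.array_length(), dtype=bool)
    if not include_hetero:
        mask &= ~arr.hetero
    if chain is not None:
        chain_mask = arr.chain_id == chain
        if not chain_mask.any():
            present = sorted(set(arr.chain_id))
            raise ChainNotFoundError(
                f"chain {chain!r} absent from {path.name}; present: {present}"
            )
        mask &= chain_mask
    if not include_hydrogens:
        mask &= ~(np.char.upper(arr.element.astype("U2")) == "H")
    if not mask.any():
        raise ChainNotFoundError(
            f"no atoms left in {path.name} for chain {chain!r} after filtering"
        )
    if label is None:
        label = path.stem if chain is None else f"{path.stem}:{chain}"
    return _model_from_atom_array(arr[mask], label)


def write_pdb(s: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = s.n_atoms
    if n > 9999:
        raise ValueError(f"PDB serial overflow: {n} atoms > 9999")
    arr = struc.AtomArray(n)
    arr.coord = np.round(s.coords, 3)
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.residue_indices
    arr.res_name = s.residue_names
    arr.atom_name = s.atom_names
    arr.element = s.elements
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections and simple measurements
# ---------------------------------------------------------------------------

def extract_environment(
    complex_model: StructureModel,
    peptide: StructureModel,
    cutoff: float,
    label: str | None = None,
) -> StructureModel:
    """Peptide plus every other complex atom within ``cutoff`` of any peptide atom.

    Complex atoms coinciding with a peptide atom position (within 1e-6 A) are
    treated as the peptide itself and never duplicated.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if peptide.n_atoms == 0:
        raise EmptySelectionError("empty peptide selection")
    tree = cKDTree(peptide.coords)
    dmin, _ = tree.query(complex_model.coords, k=1)
    is_peptide = dmin < 1e-6
    in_shell = (dmin <= cutoff) & ~is_peptide
    shell = complex_model.subset(in_shell) if in_shell.any() else None
    if label is None:
        label = f"{peptide.label}+shell{cutoff:g}"
    if shell is None:
        out = peptide.subset(np.ones(peptide.n_atoms, dtype=bool), label=label)
        return out
    return StructureModel(
        np.concatenate([peptide.elements, shell.elements]),
        np.concatenate([peptide.atom_names, shell.atom_names]),
        np.concatenate([peptide.residue_indices, shell.residue_indices]),
        np.concatenate([peptide.residue_names, shell.residue_names]),
        np.concatenate([peptide.chain_ids, shell.chain_ids]),
        np.vstack([peptide.coords, shell.coords]),
        np.concatenate([peptide.roles, shell.roles]),
        label=label,
    )


def terminal_ca_distance(s: StructureModel) -> float:
    """Distance (A) between the C-alpha atoms of the first and last residues."""
    first = s.residue_indices.min()
    last = s.residue_indices.max()
    ca = s.atom_names == "CA"
    first_ca = ca & (s.residue_indices == first)
    last_ca = ca & (s.residue_indices == last)
    if not first_ca.any() or not last_ca.any():
        raise EmptySelectionError("terminal residue lacks a CA atom")
    p = s.coords[first_ca][0]
    q = s.coords[last_ca][0]
    return float(np.linalg.norm(p - q))


def transformed(
    s: StructureModel, rotation: np.ndarray | None = None, translation=None
) -> StructureModel:
    """Rigid-body transform (rotation then translation) of the coordinates."""
    coords = s.coords
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    if translation is not None:
        coords = coords + np.asarray(translation, dtype=float)
    return StructureModel(
        s.elements, s.atom_names, s.residue_indices, s.residue_names,
        s.chain_ids, coords, s.roles, label=s.label,
        volume=s._explicit_volume,
    )
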