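"""Geometric hydrogen saturation of heavy-atom peptide structures.

Hydrogens are placed at ideal sp2/sp3 geometry with fixed bond lengths;
heavy atoms are never moved.  This is a deterministic geometric stand-in
for quantum-chemical H relaxation, so H-species partials downstream are
qualitative.  Rotatable hydrogens (methyl, hydroxyl, ammonium) are placed
staggered/anti relative to the heavy-atom frame, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_internal, unit
from ._residues import SIDE_CHAIN_BONDS, SIDE_CHAIN_H, SP2_ATOMS, STANDARD_RESIDUES
from .errors import ProtonationError
from .structure_io import StructureModel

TETRAHEDRAL = 109.4712206


@dataclass
class ProtonationScheme:
    """How to saturate a structure with hydrogens.

    zwitterion: NH3+ N-terminus and bare COO- C-terminus (the default);
    deprotonate_phenols: drop the tyrosine hydroxyl hydrogen ("u" variants);
    bond_lengths: X-H distances per heavy element, Angstrom.
    """

    zwitterion: bool = True
    deprotonate_phenols: bool = False
    bond_lengths: dict[str, float] = field(
        default_factory=lambda: {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
    )

    def __post_init__(self) -> None:
        for elem, b in self.bond_lengths.items():
            if not (0.0 < b < 1.5):
                raise ValueError(f"unphysical {elem}-H bond length {b}")


class _Residue:
    def __init__(self, name: str, index: int):
        self.name = name
        self.index = index
        self.atoms: dict[str, int] = {}  # atom name -> global index


def _build_residues(s: StructureModel) -> list[_Residue]:
    residues: dict[int, _Residue] = {}
    for i in range(s.n_atoms):
        idx = int(s.residue_indices[i])
        res = residues.get(idx)
        if res is None:
            res = _Residue(str(s.residue_names[i]), idx)
            residues[idx] = res
        name = str(s.atom_names[i]).strip().upper()
        if name in res.atoms:
            raise ProtonationError(
                f"duplicate atom {name} in residue {res.name}{idx}"
            )
        res.atoms[name] = i
    return [residues[k] for k in sorted(residues)]


def _neighbor_map(s: StructureModel, residues: list[_Residue]) -> dict[int, list[int]]:
    nbrs: dict[int, list[int]] = {i: [] for i in range(s.n_atoms)}

    def bond(i: int | None, j: int | None) -> None:
        if i is None or j is None:
            return
        nbrs[i].append(j)
        nbrs[j].append(i)

    for k, res in enumerate(residues):
        a = res.atoms
        bond(a.get("N"), a.get("CA"))
        bond(a.get("CA"), a.get("C"))
        bond(a.get("C"), a.get("O"))
        bond(a.get("C"), a.get("OXT"))
        for x, y in SIDE_CHAIN_BONDS[res.name]:
            bond(a.get(x), a.get(y))
        if k + 1 < len(residues):
            bond(a.get("C"), residues[k + 1].atoms.get("N"))
    return nbrs


def _h_counts(res: _Residue, is_nterm: bool, is_cterm: bool,
              scheme: ProtonationScheme) -> dict[str, int]:
    counts: dict[str, int] = {}
    if "N" in res.atoms:
        if is_nterm:
            if scheme.zwitterion:
                counts["N"] = 2 if res.name == "PRO" else 3
            else:
                counts["N"] = 1 if res.name == "PRO" else 2
        else:
            counts["N"] = 0 if res.name == "PRO" else 1
    if "CA" in res.atoms:
        counts["CA"] = 2 if res.name == "GLY" else 1
    for atom, n in SIDE_CHAIN_H[res.name].items():
        if atom in res.atoms:
            counts[atom] = n
    if scheme.deprotonate_phenols and res.name == "TYR":
        counts["OH"] = 0
    if is_cterm and not scheme.zwitterion and "OXT" in res.atoms:
        counts["OXT"] = 1
    return {k: v for k, v in counts.items() if v > 0}


def _h_names(res: _Residue, parent: str, n: int, is_nterm: bool) -> list[str]:
    if parent == "N":
        return ["H"] if (n == 1 and not is_nterm) else [f"H{k}" for k in range(1, n + 1)]
    stem = parent[1:] if len(parent) > 1 else ""
    if parent == "CA":
        return ["HA"] if n == 1 else ["HA2", "HA3"]
    if n == 1:
        return [f"H{stem}"]
    return [f"H{stem}{k}" for k in range(1, n + 1)]


def _pick_reference(
    nbrs: dict[int, list[int]], parent: int, neighbor: int, s: StructureModel
) -> int | None:
    candidates = [j for j in nbrs[neighbor] if j != parent]
    if not candidates:
        return None
    # deterministic: alphabetical atom name, then index
    return min(candidates, key=lambda j: (str(s.atom_names[j]), j))


def _place_hydrogens(
    s: StructureModel,
    parent: int,
    n_h: int,
    sp2: bool,
    bond: float,
    nbrs: dict[int, list[int]],
) -> list[np.ndarray]:
    x = s.coords[parent]
    heavy = nbrs[parent]
    nb_pos = [s.coords[j] for j in heavy]
    k = len(heavy)
    name = str(s.atom_names[parent])

    if k == 0:
        raise ProtonationError(f"atom {name} has no heavy neighbors")
    if k == 3 and n_h == 1:
        u = -unit(sum(unit(p - x) for p in nb_pos))
        return [x + bond * u]
    if k == 2 and n_h == 1:
        # works for both sp2 (in-plane) and sp3 methine-like cases
        u = -unit(unit(nb_pos[0] - x) + unit(nb_pos[1] - x))
        return [x + bond * u]
    if k == 2 and n_h == 2:
        u1, u2 = unit(nb_pos[0] - x), unit(nb_pos[1] - x)
        d = -unit(u1 + u2)
        p = unit(np.cross(u1, u2))
        alpha = np.deg2rad(TETRAHEDRAL / 2.0)
        return [
            x + bond * (np.cos(alpha) * d + np.sin(alpha) * p),
            x + bond * (np.cos(alpha) * d - np.sin(alpha) * p),
        ]
    if k == 1:
        j = heavy[0]
        ref = _pick_reference(nbrs, parent, j, s)
        if ref is None:
            raise ProtonationError(
                f"cannot orient hydrogens on {name}: no reference atom"
            )
        a, b = s.coords[ref], s.coords[j]
        if sp2 and n_h == 2:
            # in-plane NH2 at 120 degrees (e.g. amide, guanidinium)
            return [
                place_internal(a, b, x, bond, 120.0, 0.0),
                place_internal(a, b, x, bond, 120.0, 180.0),
            ]
        if n_h == 1:
            # hydroxyl/thiol/aromatic: anti to the reference
            angle = 120.0 if sp2 else TETRAHEDRAL
            return [place_internal(a, b, x, bond, angle, 180.0)]
        torsions = {2: (60.0, 300.0), 3: (60.0, 180.0, 300.0)}.get(n_h)
        if torsions is None:
            raise ProtonationError(f"cannot place {n_h} hydrogens on {name}")
        return [
            place_internal(a, b, x, bond, TETRAHEDRAL, t) for t in torsions
        ]
    raise ProtonationError(
        f"unsupported geometry on {name}: {k} heavy neighbors, {n_h} H"
    )


def protonate(s: StructureModel, scheme: ProtonationScheme | None = None) -> StructureModel:
    """Add hydrogens to a heavy-atom structure of standard residues.

    Heavy-atom coordinates are preserved bit-for-bit; hydrogens are appended
    after the heavy atoms, grouped by residue.  Raises on unknown residues
    or pre-existing hydrogens.
    """
    if scheme is None:
        scheme = ProtonationScheme()
    if np.any(np.char.upper(s.elements.astype("U2")) == "H"):
        raise ProtonationError("structure already contains hydrogens")
    if len(set(map(str, s.chain_ids))) > 1:
        raise ProtonationError("protonate one chain at a time")
    unknown = set(map(str, s.residue_names)) - STANDARD_RESIDUES
    if unknown:
        raise ProtonationError(f"unknown residues: {sorted(unknown)}")

    residues = _build_residues(s)
    nbrs = _neighbor_map(s, residues)

    h_elements: list[str] = []
    h_names: list[str] = []
    h_resix: list[int] = []
    h_resname: list[str] = []
    h_chain: list[str] = []
    h_roles: list[str] = []
    h_coords: list[np.ndarray] = []

    for k, res in enumerate(residues):
        is_nterm = k == 0
        is_cterm = k == len(residues) - 1
        for parent_name, n_h in _h_counts(res, is_nterm, is_cterm, scheme).items():
            parent = res.atoms[parent_name]
            elem = str(s.elements[parent]).upper()
            bond = scheme.bond_lengths.get(elem)
            if bond is None:
                raise ProtonationError(f"no H bond length for element {elem}")
            sp2 = parent_name in SP2_ATOMS.get(res.name, set()) or (
                parent_name == "N" and not is_nterm
            )
            positions = _place_hydrogens(s, parent, n_h, sp2, bond, nbrs)
            names = _h_names(res, parent_name, n_h, is_nterm)
            for nm, pos in zip(names, positions):
                h_elements.append("H")
                h_names.append(nm)
                h_resix.append(res.index)
                h_resname.append(res.name)
                h_chain.append(str(s.chain_ids[parent]))
                h_roles.append(str(s.roles[parent]))
                h_coords.append(pos)

    return StructureModel(
        np.concatenate([s.elements, np.array(h_elements, dtype="U2")]),
        np.concatenate([s.atom_names, np.array(h_names, dtype="U4")]),
        np.concatenate([s.residue_indices, np.array(h_resix, dtype=int)]),
        np.concatenate([s.residue_names, np.array(h_resname, dtype="U3")]),
        np.concatenate([s.chain_ids, np.array(h_chain, dtype="U4")]),
        np.vstack([s.coords, np.array(h_coords)]),
        np.concatenate([s.roles, np.array(h_roles, dtype="U9")]),
        label=s.label + ("+Hu" if scheme.deprotonate_phenols else "+H"),
    )


def count_hydrogens(s: StructureModel) -> int:
    return int(np.sum(np.char.upper(s.elements.astype("U2")) == "H"))
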