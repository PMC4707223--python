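"""Seeded generators for download-free test inputs.

Peptide-like chains with realistic first-shell bond lengths (C-C near 1.5 A,
C-N near 1.3 A), dilated/perturbed variants with a planted coordination
sign, ideal-gas clouds for the g(r) = 1 limit, simple lattices, decoy
environment shells and toy PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import place_internal, unit
from .errors import GeometryError
from .structure_io import StructureModel, write_pdb

DEFAULT_BACKBONE_LENGTHS = {"N-CA": 1.46, "CA-C": 1.52, "C-N": 1.33, "C-O": 1.23}

_SIDE_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH", "CI", "CK", "CL", "CM"]

_CLASH_FLOOR = 2.4
_MAX_RETRIES = 60


@dataclass
class SyntheticSpec:
    """Parameters for one synthetic peptide-like chain."""

    n_residues: int = 9
    seed: int = 0
    backbone_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKBONE_LENGTHS)
    )
    sidechain_sizes: list[int] | int = 3
    scale_factor: float = 1.0
    decoy_shell: tuple[int, float, float] | None = None  # (count, r_lo, r_hi)

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    def side_sizes(self) -> list[int]:
        if isinstance(self.sidechain_sizes, int):
            return [self.sidechain_sizes] * self.n_residues
        if len(self.sidechain_sizes) != self.n_residues:
            raise ValueError("sidechain_sizes length must match n_residues")
        return list(self.sidechain_sizes)


def _residue_name(side: int) -> str:
    return {0: "GLY", 1: "ALA"}.get(side, "UNK")


class _Builder:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.coords: list[np.ndarray] = []
        self.bonded: list[set[int]] = []

    def add(self, pos: np.ndarray, bonded_to: list[int]) -> int:
        i = len(self.coords)
        for j in bonded_to:
            if np.linalg.norm(pos - self.coords[j]) > 2.0:
                raise GeometryError("bond length blew up during construction")
        # non-bonded clash check (1-2, 1-3 and 1-4 interactions are exempt)
        exempt = set(bonded_to)
        for j in bonded_to:
            exempt |= self.bonded[j]
            for k in self.bonded[j]:
                exempt |= self.bonded[k]
        for j, q in enumerate(self.coords):
            if j in exempt:
                continue
            if np.linalg.norm(pos - q) < _CLASH_FLOOR:
                raise GeometryError(f"clash with atom {j}")
        self.coords.append(np.asarray(pos, dtype=float))
        self.bonded.append(set(bonded_to))
        for j in bonded_to:
            self.bonded[j].add(i)
        return i

    def snapshot(self) -> int:
        return len(self.coords)

    def restore(self, n: int) -> None:
        del self.coords[n:]
        del self.bonded[n:]
        for s in self.bonded:
            s.difference_update({j for j in s if j >= n})


def make_chain(spec: SyntheticSpec) -> StructureModel:
    """Self-avoiding peptide-like chain with idealized bond lengths.

    Backbone atoms N/CA/C/O per residue plus a linear carbon side chain of
    the requested size; torsions are drawn from the seeded generator and
    re-drawn (bounded retries) on steric clashes below the 2.4 A floor.
    """
    rng = np.random.default_rng(spec.seed)
    bl = spec.backbone_lengths
    sides = spec.side_sizes()

    for attempt in range(_MAX_RETRIES):
        try:
            return _try_chain(spec, np.random.default_rng(rng.integers(2**63)), bl, sides)
        except GeometryError:
            continue
    raise GeometryError(
        f"could not build a clash-free chain after {_MAX_RETRIES} attempts"
    )


def _try_chain(spec, rng, bl, sides) -> StructureModel:
    b = _Builder(rng)
    meta: list[tuple[str, str, str, int, str]] = []

    def register(name: str, element: str, role: str, res: int, resname: str):
        meta.append((name, element, role, res, resname))

    prev_c = prev_ca = prev_n = None
    prev_resname = ""
    for r in range(1, spec.n_residues + 1):
        resname = _residue_name(sides[r - 1])
        for res_attempt in range(40):
            snap = b.snapshot()
            meta_len = len(meta)
            try:
                n_i, ca_i, c_i = _build_residue(
                    b, rng, bl, sides, r, resname, prev_n, prev_ca, prev_c,
                    prev_resname, register,
                )
                break
            except GeometryError:
                b.restore(snap)
                del meta[meta_len:]
        else:
            raise GeometryError(f"residue {r} could not be placed")
        prev_n, prev_ca, prev_c = n_i, ca_i, c_i
        prev_resname = resname

    # terminal carbonyl O (no next N to orient against)
    _place_retry(
        b, rng, b.coords[prev_n], b.coords[prev_ca], b.coords[prev_c],
        bl["C-O"], 121.0, None, [prev_c],
    )
    register("O", "O", "backbone", spec.n_residues, prev_resname)

    coords = np.array(b.coords)
    names, elements, roles, resix, resnames = (
        [m[0] for m in meta], [m[1] for m in meta], [m[2] for m in meta],
        [m[3] for m in meta], [m[4] for m in meta],
    )
    # carbonyl O atoms are placed after the next residue's N; restore
    # residue-contiguous order so PDB round-trips re-index identically
    order = np.argsort(np.asarray(resix), kind="stable")
    coords = coords[order]
    names = [names[i] for i in order]
    elements = [elements[i] for i in order]
    roles = [roles[i] for i in order]
    resnames = [resnames[i] for i in order]
    resix = [resix[i] for i in order]
    model = StructureModel(
        elements, names, resix, resnames,
        ["A"] * len(elements), coords, roles,
        label=f"synthetic(seed={spec.seed},n={spec.n_residues})",
    )
    if spec.scale_factor != 1.0:
        model = make_variant(model, spec.scale_factor)
    if spec.decoy_shell is not None:
        count, r_lo, r_hi = spec.decoy_shell
        model = add_decoy_shell(model, count, r_lo, r_hi, seed=spec.seed)
    return model


def _build_residue(b, rng, bl, sides, r, resname, prev_n, prev_ca, prev_c,
                   prev_resname, register):
    angle_nca_c = 111.0
    angle_cac_n = 116.5
    angle_cn_ca = 121.5
    if r == 1:
        n_i = b.add(np.zeros(3), [])
        register("N", "N", "backbone", r, resname)
        ca_i = b.add(np.array([bl["N-CA"], 0.0, 0.0]), [n_i])
        register("CA", "C", "backbone", r, resname)
        # first C: fixed angle, arbitrary plane
        c_pos = place_internal(
            np.array([0.0, 0.0, 1.0]), b.coords[n_i], b.coords[ca_i],
            bl["CA-C"], angle_nca_c, rng.uniform(0, 360),
        )
        c_i = b.add(c_pos, [ca_i])
        register("C", "C", "backbone", r, resname)
    else:
        # psi is the random torsion drawn for the new N
        n_i = _place_retry(
            b, rng, b.coords[prev_n], b.coords[prev_ca], b.coords[prev_c],
            bl["C-N"], angle_cac_n, None, [prev_c],
        )
        register("N", "N", "backbone", r, resname)
        # carbonyl O of the previous residue: sp2 plane, anti to both
        u1 = unit(b.coords[prev_ca] - b.coords[prev_c])
        u2 = unit(b.coords[n_i] - b.coords[prev_c])
        o_pos = b.coords[prev_c] - bl["C-O"] * unit(u1 + u2)
        b.add(o_pos, [prev_c])
        register("O", "O", "backbone", r - 1, prev_resname)
        ca_i = _place_retry(
            b, rng, b.coords[prev_ca], b.coords[prev_c], b.coords[n_i],
            bl["N-CA"], angle_cn_ca, 180.0, [n_i],  # omega trans
        )
        register("CA", "C", "backbone", r, resname)
        c_i = _place_retry(
            b, rng, b.coords[prev_c], b.coords[n_i], b.coords[ca_i],
            bl["CA-C"], angle_nca_c, None, [ca_i],  # phi random
        )
        register("C", "C", "backbone", r, resname)

    # side chain off CA: CB at a fixed torsion offset from C so the two
    # CA substituents never eclipse; the rest on a rolling random frame
    a_p, b_p, c_p = b.coords[c_i], b.coords[n_i], b.coords[ca_i]
    anchor = ca_i
    for k in range(sides[r - 1]):
        torsion = -120.0 if k == 0 else None
        idx = _place_retry(b, rng, a_p, b_p, c_p, 1.52, 111.0, torsion, [anchor])
        register(_SIDE_NAMES[k], "C", "sidechain", r, resname)
        a_p, b_p, c_p = b_p, c_p, b.coords[idx]
        anchor = idx
    return n_i, ca_i, c_i


def _place_retry(b, rng, a, p, q, bond, angle, torsion, bonded):
    for _ in range(50):
        t = rng.uniform(-180, 180) if torsion is None else torsion
        pos = place_internal(a, p, q, bond, angle, t)
        try:
            return b.add(pos, bonded)
        except GeometryError:
            if torsion is not None:
                raise  # fixed-torsion atom cannot be re-drawn
            continue
    raise GeometryError("atom placement exhausted retries")


def make_variant(
    base: StructureModel,
    scale_factor: float = 1.0,
    perturb_residue: int | None = None,
    seed: int = 0,
) -> StructureModel:
    """Variant with planted over-/under-coordination.

    Without ``perturb_residue`` the whole structure is dilated about its
    centroid by ``scale_factor`` (f > 1 plants under-coordination, f < 1
    over-coordination).  With ``perturb_residue`` only that residue's
    side-chain atoms are scaled about the residue's CA, so only interaction
    groups containing that (residue, S) key change.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    coords = base.coords.copy()
    if perturb_residue is None:
        if scale_factor != 1.0:
            centroid = coords.mean(axis=0)
            coords = centroid + scale_factor * (coords - centroid)
        label = f"{base.label}*f{scale_factor:g}"
    else:
        res_mask = base.residue_indices == perturb_residue
        if not res_mask.any():
            raise ValueError(f"residue {perturb_residue} out of range")
        side = res_mask & (base.roles == "sidechain")
        ca = res_mask & (base.atom_names == "CA")
        if not side.any() or not ca.any():
            raise ValueError(
                f"residue {perturb_residue} lacks side-chain or CA atoms"
            )
        origin = base.coords[ca][0]
        coords[side] = origin + scale_factor * (coords[side] - origin)
        label = f"{base.label}*r{perturb_residue}f{scale_factor:g}"
    return StructureModel(
        base.elements, base.atom_names, base.residue_indices,
        base.residue_names, base.chain_ids, coords, base.roles, label=label,
    )


def make_ideal_gas(
    n: int, box: float, seed: int = 0, element: str = "C"
) -> StructureModel:
    """Uniform i.i.d. points in a cubic box; volume fixed to box^3."""
    if n < 2:
        raise ValueError("need at least 2 atoms")
    if box <= 0:
        raise ValueError("box must be positive")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    return StructureModel(
        [element] * n, [element] * n, np.ones(n, dtype=int), ["UNK"] * n,
        ["A"] * n, coords, ["sidechain"] * n,
        label=f"idealgas(n={n},box={box:g},seed={seed})",
        volume=box**3,
    )


def make_cubic_lattice(n_side: int, spacing: float = 1.0,
                       element: str = "C") -> StructureModel:
    """Simple cubic lattice, n_side^3 atoms."""
    ax = np.arange(n_side) * spacing
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    n = len(grid)
    return StructureModel(
        [element] * n, [element] * n, np.ones(n, dtype=int), ["UNK"] * n,
        ["A"] * n, grid, ["sidechain"] * n,
        label=f"lattice(n={n_side},a={spacing:g})",
    )


def add_decoy_shell(
    s: StructureModel,
    n_decoys: int,
    r_lo: float,
    r_hi: float,
    seed: int = 0,
    element: str = "C",
) -> StructureModel:
    """Append decoy atoms at distances in [r_lo, r_hi] from random chain atoms.

    Each decoy's nearest chain atom lies in the band, making cutoff-selection
    behaviour easy to assert.
    """
    if not (0 < r_lo <= r_hi):
        raise ValueError("need 0 < r_lo <= r_hi")
    rng = np.random.default_rng(seed)
    decoys = []
    while len(decoys) < n_decoys:
        anchor = s.coords[rng.integers(s.n_atoms)]
        direction = unit(rng.normal(size=3))
        radius = rng.uniform(r_lo, r_hi)
        pos = anchor + radius * direction
        d = np.linalg.norm(s.coords - pos, axis=1).min()
        if r_lo <= d <= r_hi:
            decoys.append(pos)
    m = len(decoys)
    return StructureModel(
        np.concatenate([s.elements, [element] * m]),
        np.concatenate([s.atom_names, [element] * m]),
        np.concatenate([s.residue_indices, np.arange(1, m + 1)]),
        np.concatenate([s.residue_names, ["UNK"] * m]),
        np.concatenate([s.chain_ids, ["E"] * m]),
        np.vstack([s.coords, np.array(decoys)]),
        np.concatenate([s.roles, ["sidechain"] * m]),
        label=f"{s.label}+decoys{m}",
    )


def write_toy_pdb(s: StructureModel, path: str | Path) -> Path:
    """Write a synthetic structure as a standards-conformant PDB file."""
    path = Path(path)
    write_pdb(s, path)
    return path
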