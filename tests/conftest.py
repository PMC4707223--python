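"""Shared fixtures: synthetic structures, a hand-built tyrosine, PDB data dir."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from pepcoord import SyntheticSpec, StructureModel, make_chain
from pepcoord._geometry import place_internal, unit

REPO_ROOT = Path(__file__).resolve().parents[1]
PDB_DIR = REPO_ROOT / "data" / "pdb"

#: peptide chain ID of the study entries (antigen chain)
PEPTIDE_CHAIN = "C"


def pdb_path(entry_id: str) -> Path:
    """Path to a crystal-structure file, skipping the test when absent."""
    p = PDB_DIR / f"{entry_id.upper()}.pdb"
    if not p.exists():
        pytest.skip(
            f"crystal structure {entry_id} not available offline "
            f"(place it at {p} to enable this test)"
        )
    return p


@pytest.fixture(scope="session")
def chain9() -> StructureModel:
    return make_chain(SyntheticSpec(n_residues=9, seed=11))


@pytest.fixture(scope="session")
def polyala() -> StructureModel:
    return make_chain(SyntheticSpec(n_residues=3, seed=2, sidechain_sizes=1))


def random_structure(rng: np.random.Generator, n: int, span: float = 12.0,
                     elements=("C", "N", "O")) -> StructureModel:
    """Random labeled point cloud for oracle tests."""
    coords = rng.uniform(0.0, span, size=(n, 3))
    elem = rng.choice(elements, size=n)
    return StructureModel(
        elem, [str(e) for e in elem], np.arange(1, n + 1), ["UNK"] * n,
        ["A"] * n, coords, ["sidechain"] * n, label=f"random(n={n})",
    )


def pair_structure(d: float, volume: float = 1000.0) -> StructureModel:
    """Two carbon atoms a known distance apart, with a fixed box volume so
    densities stay finite despite the collinear geometry."""
    return StructureModel(
        ["C", "C"], ["C", "C"], [1, 2], ["UNK"] * 2, ["A"] * 2,
        [[0.0, 0.0, 0.0], [d, 0.0, 0.0]], ["sidechain"] * 2, volume=volume,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tyr_peptide() -> StructureModel:
    """Single-residue TYR 'peptide' with an idealized planar phenol ring."""
    n_pos = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.46, 0.0, 0.0])
    u = np.array([np.cos(np.deg2rad(69.0)), np.sin(np.deg2rad(69.0)), 0.0])
    c = ca + 1.52 * u

    def rotz(v, deg):
        t = np.deg2rad(deg)
        R = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0],
                      [0, 0, 1.0]])
        return R @ v

    o = c + 1.23 * rotz(u, 121.0)
    oxt = c + 1.36 * rotz(u, -121.0)
    cb = place_internal(c, n_pos, ca, 1.52, 111.0, -120.0)
    cg = place_internal(n_pos, ca, cb, 1.52, 113.0, 175.0)
    ring_dir = unit(cg - cb)
    center = cg + 1.39 * ring_dir
    helper = ca - cb
    e2 = unit(np.cross(ring_dir, np.cross(helper, ring_dir)))
    ring = {}
    for name, theta in [("CG", 0), ("CD1", 60), ("CE1", 120), ("CZ", 180),
                        ("CE2", 240), ("CD2", 300)]:
        t = np.deg2rad(theta)
        ring[name] = center + 1.39 * (-np.cos(t) * ring_dir + np.sin(t) * e2)
    oh = ring["CZ"] + 1.36 * ring_dir

    names = ["N", "CA", "C", "O", "OXT", "CB", "CG", "CD1", "CD2",
             "CE1", "CE2", "CZ", "OH"]
    coords = np.array([
        n_pos, ca, c, o, oxt, cb, ring["CG"], ring["CD1"], ring["CD2"],
        ring["CE1"], ring["CE2"], ring["CZ"], oh,
    ])
    elements = [nm[0] for nm in names]
    return StructureModel(
        elements, names, [1] * 13, ["TYR"] * 13, ["A"] * 13, coords,
        label="tyr-toy",
    )
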