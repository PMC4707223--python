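import numpy as np
import pytest

from pepcoord import (
    StructureModel,
    bulk_properties,
    extract_environment,
    make_chain,
    read_pdb,
    terminal_ca_distance,
    transformed,
    write_pdb,
    SyntheticSpec,
)
from pepcoord._geometry import random_rotation
from pepcoord.errors import (
    ChainNotFoundError,
    DegenerateVolumeError,
    EmptySelectionError,
)
from pepcoord.structure_io import ATOMIC_MASSES, DA_PER_A3_TO_G_PER_CM3, atom_role

from conftest import PEPTIDE_CHAIN, pdb_path, random_structure


def _point_structure(coords, elements=None, names=None):
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or ["C"] * n
    return StructureModel(
        elements, names, np.arange(1, n + 1), ["UNK"] * n, ["A"] * n,
        np.asarray(coords, dtype=float),
    )


class TestBulkProperties:
    def test_unit_cube(self):
        corners = [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        s = _point_structure(corners)
        props = bulk_properties(s)
        assert props.volume == pytest.approx(1.0)
        assert props.rho0 == pytest.approx(8.0)
        assert props.n_atoms == 8

    def test_rho0_times_v_equals_n(self, chain9):
        props = bulk_properties(chain9)
        assert props.rho0 * props.volume == pytest.approx(chain9.n_atoms, rel=1e-12)

    def test_mass_density_ratio_matches_composition(self, chain9):
        # density / number density == mean atomic mass * conversion factor,
        # independently of the box convention
        props = bulk_properties(chain9)
        mean_mass = np.mean(
            [ATOMIC_MASSES[str(e)] for e in chain9.elements]
        )
        assert props.mass_density / props.rho0 == pytest.approx(
            mean_mass * DA_PER_A3_TO_G_PER_CM3, rel=1e-9
        )

    def test_coplanar_atoms_raise(self):
        s = _point_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])
        with pytest.raises(DegenerateVolumeError):
            bulk_properties(s)

    def test_margin_grows_volume(self, chain9):
        assert bulk_properties(chain9, margin=1.0).volume > bulk_properties(chain9).volume


class TestTerminalCaDistance:
    def test_3_4_5_triangle(self):
        s = StructureModel(
            ["C", "C"], ["CA", "CA"], [1, 2], ["GLY", "GLY"], ["A", "A"],
            [(0, 0, 0), (3, 4, 0)],
        )
        assert terminal_ca_distance(s) == pytest.approx(5.0)

    def test_rotation_invariant(self, chain9, rng):
        rot = random_rotation(rng)
        moved = transformed(chain9, rot, (5.0, -2.0, 1.0))
        assert terminal_ca_distance(moved) == pytest.approx(
            terminal_ca_distance(chain9), rel=1e-9
        )

    def test_missing_ca_raises(self):
        s = _point_structure([(0, 0, 0), (1, 1, 1)])
        with pytest.raises(EmptySelectionError):
            terminal_ca_distance(s)


class TestExtractEnvironment:
    def test_decoys_at_known_distances(self, chain9):
        # plant decoys whose nearest-peptide distances are 6.9 and 7.1
        anchor = chain9.coords[0]
        far_dir = anchor - chain9.coords.mean(axis=0)
        far_dir /= np.linalg.norm(far_dir)
        decoys = [anchor + 6.9 * far_dir, anchor + 7.1 * far_dir]
        full = StructureModel(
            np.concatenate([chain9.elements, ["C", "C"]]),
            np.concatenate([chain9.atom_names, ["C", "C"]]),
            np.concatenate([chain9.residue_indices, [1, 2]]),
            np.concatenate([chain9.residue_names, ["UNK", "UNK"]]),
            np.concatenate([chain9.chain_ids, ["E", "E"]]),
            np.vstack([chain9.coords, decoys]),
        )
        shell = extract_environment(full, chain9, cutoff=7.0)
        # brute-force check of each decoy's min distance to the peptide
        for decoy in decoys:
            dmin = np.linalg.norm(chain9.coords - decoy, axis=1).min()
            included = any(
                np.allclose(decoy, c) for c in shell.coords[chain9.n_atoms:]
            )
            assert included == (dmin <= 7.0)
        assert shell.n_atoms == chain9.n_atoms + 1

    def test_empty_shell_is_peptide(self, chain9):
        shell = extract_environment(chain9, chain9, cutoff=5.0)
        assert shell.n_atoms == chain9.n_atoms

    def test_monotone_in_cutoff(self, chain9):
        from pepcoord import add_decoy_shell

        full = add_decoy_shell(chain9, 40, 2.5, 9.0, seed=3)
        sizes = [
            extract_environment(full, chain9, c).n_atoms for c in (3.0, 5.0, 8.0)
        ]
        assert sizes == sorted(sizes)

    def test_bad_cutoff(self, chain9):
        with pytest.raises(ValueError):
            extract_environment(chain9, chain9, cutoff=0.0)


class TestPdbIO:
    def test_round_trip(self, tmp_path, chain9):
        path = tmp_path / "toy.pdb"
        write_pdb(chain9, path)
        back = read_pdb(path, "A")
        assert back.n_atoms == chain9.n_atoms
        assert list(back.elements) == list(chain9.elements)
        assert list(back.roles) == list(chain9.roles)
        np.testing.assert_allclose(back.coords, chain9.coords, atol=5e-4)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "nope.pdb", "A")

    def test_chain_absent(self, tmp_path, chain9):
        path = tmp_path / "toy.pdb"
        write_pdb(chain9, path)
        with pytest.raises(ChainNotFoundError):
            read_pdb(path, "Z")

    def test_no_atom_records(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(ChainNotFoundError):
            read_pdb(path, "A")

    def test_backbone_role_partition(self, chain9):
        roles = set(chain9.roles)
        assert roles <= {"backbone", "sidechain"}
        for r in np.unique(chain9.residue_indices):
            mask = (chain9.residue_indices == r) & (chain9.roles == "backbone")
            assert mask.sum() == 4  # N, CA, C, O

    def test_atom_role_classification(self):
        assert atom_role("CA", "C") == "backbone"
        assert atom_role("OXT", "O") == "backbone"
        assert atom_role("CB", "C") == "sidechain"
        assert atom_role("HA", "H") == "backbone"
        assert atom_role("HB1", "H") == "sidechain"


class TestHistogramRigidInvariance:
    def test_counts_invariant(self, chain9, rng):
        from pepcoord import build_histogram

        rot = random_rotation(rng)
        moved = transformed(chain9, rot, (-3.0, 8.0, 0.5))
        h1 = build_histogram(chain9, "total", 0.1, r_max=25.0)
        h2 = build_histogram(moved, "total", 0.1, r_max=25.0)
        np.testing.assert_array_equal(h1.counts, h2.counts)


@pytest.mark.pdb_data
class TestStudyStructures:
    """Checks against the crystal structures; skipped when the entries are
    not available offline."""

    def test_tax_sequence(self):
        tax = read_pdb(pdb_path("1AO7"), PEPTIDE_CHAIN)
        assert tax.sequence() == "LLFGYPVYV"
        assert len(np.unique(tax.residue_indices)) == 9

    def test_tax_terminal_ca_near_22(self):
        tax = read_pdb(pdb_path("1AO7"), PEPTIDE_CHAIN)
        assert 19.0 < terminal_ca_distance(tax) < 25.0

    def test_tax_number_density(self):
        tax = read_pdb(pdb_path("1AO7"), PEPTIDE_CHAIN)
        props = bulk_properties(tax)
        assert props.rho0 == pytest.approx(0.014175, rel=0.15)

    def test_shell_size_between_peptide_and_complex(self):
        complex_model = read_pdb(pdb_path("1AO7"), None)
        tax = read_pdb(pdb_path("1AO7"), PEPTIDE_CHAIN)
        shell = extract_environment(complex_model, tax, 7.0)
        assert tax.n_atoms < shell.n_atoms < complex_model.n_atoms
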