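"""Configuration container, file round trips, bond perception, atom roles."""

import numpy as np
import pytest

from hygroelast import (
    Atom,
    Box,
    MolecularConfiguration,
    ParseError,
    ValidationError,
    classify_atoms,
    make_water_box,
    perceive_bonds,
    read_structure,
    write_structure,
)
from hygroelast.structures import COVALENT_RADII, assign_molecule_ids, minimum_image

WATER_PDB = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1           1
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.240   0.927   0.000  1.00  0.00           H
CONECT    1    2
CONECT    1    3
END
"""


class TestReading:
    def test_pdb_atom_and_conect_counts(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(WATER_PDB)
        cfg = read_structure(p)
        assert cfg.n_atoms == 3
        assert len(cfg.bonds) == 2
        assert cfg.box is not None and cfg.box.lengths == (10.0, 10.0, 10.0)
        assert list(cfg.elements) == ["O", "H", "H"]

    def test_empty_coordinate_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(ParseError):
            read_structure(p)

    def test_unknown_element_symbol_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text('1\nLattice="5 0 0 0 5 0 0 0 5"\nN 0 0 0\n')
        with pytest.raises(ParseError):
            read_structure(p)

    def test_malformed_coordinates_report_line_number(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text('1\ncomment\nO zero 0 0\n')
        with pytest.raises(ParseError, match=":3"):
            read_structure(p)

    def test_triclinic_lattice_rejected(self, tmp_path):
        p = tmp_path / "tri.xyz"
        p.write_text('1\nLattice="5 1 0 0 5 0 0 0 5"\nO 0 0 0\n')
        with pytest.raises(ParseError, match="triclinic"):
            read_structure(p)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt,coord_tol", [("pdb", 5.1e-4), ("xyz", 1e-9)])
    def test_write_read_identity(self, tmp_path, fmt, coord_tol):
        """Reading a file the package wrote reproduces the configuration to
        the format's printed precision."""
        cfg = make_water_box(10, Box((12.0, 12.0, 12.0)), seed=5)
        p = tmp_path / f"box.{fmt}"
        write_structure(cfg, p)
        back = read_structure(p)
        assert back.n_atoms == cfg.n_atoms
        assert list(back.elements) == list(cfg.elements)
        assert np.abs(back.positions - cfg.positions).max() <= coord_tol
        assert back.box.lengths == pytest.approx(cfg.box.lengths, abs=1e-3)
        if fmt == "pdb":
            assert back.bonds == cfg.bonds
        else:
            assert back.bonds == set()  # xyz carries no connectivity


class TestPerceiveBonds:
    def test_distant_oxygens_stay_unbonded(self):
        cfg = MolecularConfiguration(
            [Atom(0, "O", (0, 0, 0)), Atom(1, "O", (5, 0, 0))], set(), [], Box((20, 20, 20))
        )
        assert perceive_bonds(cfg).bonds == set()

    def test_oh_pair_bonds_at_covalent_distance(self):
        # cutoff = 1.2 x (0.66 + 0.31) = 1.164 Å > 0.96 Å
        cfg = MolecularConfiguration(
            [Atom(0, "O", (0, 0, 0)), Atom(1, "H", (0.96, 0, 0))], set(), [], Box((20, 20, 20))
        )
        assert perceive_bonds(cfg, scale=1.2).bonds == {(0, 1)}

    def test_water_box_matches_brute_force_oracle(self):
        cfg = make_water_box(15, Box((12.0, 12.0, 12.0)), seed=9)
        bare = MolecularConfiguration(list(cfg.atoms), set(), [], cfg.box)
        perceived = perceive_bonds(bare)
        # independent O(n^2) oracle
        pos, elems = cfg.positions, cfg.elements
        L = np.array(cfg.box.lengths)
        expected = set()
        for i in range(cfg.n_atoms):
            for j in range(i + 1, cfg.n_atoms):
                d = pos[j] - pos[i]
                d -= L * np.round(d / L)
                cut = 1.2 * (COVALENT_RADII[elems[i]] + COVALENT_RADII[elems[j]])
                if np.linalg.norm(d) <= cut:
                    expected.add((i, j))
        assert perceived.bonds == expected
        assert len(perceived.bonds) == 2 * 15  # two covalent bonds per water

    def test_refuses_configurations_with_bonds(self, water_box20):
        with pytest.raises(Exception, match="already has bonds"):
            perceive_bonds(water_box20)

    def test_bond_set_invariant_under_atom_reordering(self):
        cfg = make_water_box(8, Box((10.0, 10.0, 10.0)), seed=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(cfg.n_atoms)
        shuffled = MolecularConfiguration(
            [Atom(int(perm[a.id]), a.element, a.position) for a in cfg.atoms],
            set(),
            [],
            cfg.box,
        )
        bare = MolecularConfiguration(
            [Atom(a.id, a.element, a.position) for a in cfg.atoms], set(), [], cfg.box
        )
        direct = perceive_bonds(bare).bonds
        via_perm = {
            tuple(sorted((int(np.argwhere(perm == i)[0, 0]), int(np.argwhere(perm == j)[0, 0]))))
            for i, j in perceive_bonds(shuffled).bonds
        }
        assert direct == via_perm


class TestClassifyAtoms:
    def test_pure_water_box_is_all_water(self, water_box20):
        roles = classify_atoms(water_box20)
        assert len(roles.water_oxygens) == 20
        assert len(roles.water_hydrogens) == 40
        assert roles.polymer_atoms == frozenset()
        assert roles.hydroxyl_oxygens == frozenset()
        assert roles.donor_oxygens == roles.water_oxygens
        assert roles.acceptor_oxygens == roles.water_oxygens

    def test_coh_fragment_is_a_polymer_hydroxyl(self):
        cfg = MolecularConfiguration(
            [Atom(0, "C", (0, 0, 0)), Atom(1, "O", (1.43, 0, 0)), Atom(2, "H", (2.39, 0, 0))],
            {(0, 1), (1, 2)},
            [],
            Box((10, 10, 10)),
        )
        roles = classify_atoms(cfg)
        assert roles.hydroxyl_oxygens == {1}
        assert roles.polymer_atoms == {0, 1, 2}
        assert not roles.water_oxygens
        assert roles.donor_oxygens == {1}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generator_labels_are_recovered(self, seed):
        """Role classification agrees with the generator's own ground truth:
        inserted waters are water, the chain is polymer, and the hydroxyl
        count matches the template arithmetic."""
        from hygroelast import hydrate, make_toy_polymer

        dry = make_toy_polymer("xylan_like", 4, seed=seed, box=Box((18.0, 10.0, 8.0)))
        wet = hydrate(dry, 12.0, seed=seed, min_dist=1.8)
        roles = classify_atoms(wet)
        dry_ids = set(dry.ids)
        inserted = set(wet.ids) - dry_ids
        assert roles.polymer_atoms == dry_ids
        assert roles.water_atoms == inserted
        assert len(roles.hydroxyl_oxygens) == 2 * 4

    def test_partition_is_total_and_exclusive(self, lignin3, water_box20):
        for cfg in (lignin3, water_box20):
            roles = classify_atoms(cfg)
            all_ids = set(cfg.ids)
            assert roles.water_atoms | roles.polymer_atoms == all_ids
            assert roles.water_atoms & roles.polymer_atoms == set()
            # idempotence: classification is a pure function of topology
            assert classify_atoms(cfg) == roles

    def test_valence_impossible_hydrogen_rejected(self):
        cfg = MolecularConfiguration(
            [Atom(0, "O", (0, 0, 0)), Atom(1, "H", (1, 0, 0)), Atom(2, "O", (2, 0, 0))],
            {(0, 1), (1, 2)},
            [],
            Box((10, 10, 10)),
        )
        with pytest.raises(ValidationError, match=r"\[1\]"):
            classify_atoms(cfg)


class TestInvariants:
    def test_bonds_must_reference_existing_atoms(self):
        with pytest.raises(ValidationError):
            MolecularConfiguration([Atom(0, "O", (0, 0, 0))], {(0, 5)}, [], None)

    def test_self_bonds_rejected(self):
        with pytest.raises(ValidationError):
            MolecularConfiguration([Atom(0, "O", (0, 0, 0))], {(0, 0)}, [], None)

    def test_molecule_ids_follow_connectivity(self, water_box20):
        relabelled = assign_molecule_ids(water_box20)
        mol_of = {a.id: a.molecule_id for a in relabelled.atoms}
        for i, j in relabelled.bonds:
            assert mol_of[i] == mol_of[j]
        assert len({a.molecule_id for a in relabelled.atoms}) == 20

    def test_minimum_image_halves_the_box(self):
        d = minimum_image(np.array([9.0, -9.0, 0.5]), np.array([10.0, 10.0, 10.0]))
        assert d == pytest.approx([-1.0, 1.0, 0.5])
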