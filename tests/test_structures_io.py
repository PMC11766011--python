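import math

import numpy as np
import pytest

from vsdgate import structures_io as sio

from conftest import rotate_about_z

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
"""


class TestReadPDB:
    def test_minimal_two_atoms(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        s = sio.read_pdb(p)
        assert len(s) == 2
        assert s.atoms[0].name == "CA"
        assert s.atoms[1].residue_name == "GLY"
        np.testing.assert_allclose(s.atoms[0].xyz, [1.0, 2.0, 3.0])

    def test_bad_coordinate_field_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1         abc   2.000   3.000\n")
        with pytest.raises(sio.PDBFormatError, match="line 1"):
            sio.read_pdb(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(sio.PDBFormatError):
            sio.read_pdb(p)

    def test_multi_model_gives_list(self, tmp_path, toy_wt):
        p = tmp_path / "traj.pdb"
        sio.write_pdb([toy_wt, toy_wt, toy_wt], p)
        models = sio.read_pdb(p)
        assert isinstance(models, list)
        assert len(models) == 3
        assert models[0].annotations == toy_wt.annotations


class TestWritePDB:
    def test_single_atom(self, tmp_path):
        s = sio.Structure([sio.Atom("CA", "ALA", 1, "A", np.zeros(3))], {})
        p = tmp_path / "one.pdb"
        sio.write_pdb(s, p)
        lines = [ln for ln in p.read_text().splitlines() if ln.startswith("ATOM")]
        assert len(lines) == 1

    def test_trajectory_model_blocks(self, tmp_path, toy_wt):
        p = tmp_path / "traj.pdb"
        sio.write_pdb([toy_wt] * 3, p)
        text = p.read_text()
        assert text.count("MODEL") == 3
        assert text.count("ENDMDL") == 3

    def test_empty_structure_raises(self, tmp_path):
        with pytest.raises(ValueError):
            sio.write_pdb(sio.Structure([], {}), tmp_path / "x.pdb")

    def test_round_trip_column_precision(self, tmp_path, toy_wt):
        p = tmp_path / "rt.pdb"
        sio.write_pdb(toy_wt, p)
        back = sio.read_pdb(p)
        assert len(back) == len(toy_wt)
        assert [a.key for a in back.atoms] == [a.key for a in toy_wt.atoms]
        np.testing.assert_allclose(back.coords, toy_wt.coords, atol=1e-3)


class TestToyBuilder:
    def test_wt_contract(self, toy_wt):
        assert set(toy_wt.annotations) == {"S1", "S2", "S3", "S4"}
        sites = [a for a in toy_wt.atoms if a.name in ("CZ", "NZ", "CD", "CG")]
        assert len(sites) >= 5

    def test_ca_chord_length(self, toy_wt):
        # closed form for rise 1.5 A, 100 deg/res, radius 2.3 A:
        # sqrt(1.5^2 + (2*2.3*sin(50 deg))^2) = 3.8298 A
        for helix in ("S1", "S2", "S3", "S4"):
            coords = toy_wt.coords[toy_wt.helix_atom_indices(helix, "CA")]
            chords = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            np.testing.assert_allclose(chords, 3.80, atol=0.05)

    def test_s4_ca_near_axis_and_rise(self, toy_wt):
        coords = toy_wt.coords[toy_wt.helix_atom_indices("S4", "CA")]
        xy = coords[:, :2]
        axis_xy = np.array([0.0, 0.0])
        assert np.all(np.linalg.norm(xy - axis_xy, axis=1) <= 2.4)
        rises = -np.diff(coords[:, 2])
        np.testing.assert_allclose(rises, 1.5, atol=1e-6)

    def test_variant_same_geometry_flipped_charge(self, toy_wt, toy_r1e):
        ca_wt = toy_wt.coords[[i for i, a in enumerate(toy_wt.atoms) if a.name == "CA"]]
        ca_mu = toy_r1e.coords[[i for i, a in enumerate(toy_r1e.atoms) if a.name == "CA"]]
        np.testing.assert_allclose(ca_wt, ca_mu, atol=1e-9)
        assert toy_wt.atom("A", 63, "CA").residue_name == "ARG"
        assert toy_r1e.atom("A", 63, "CA").residue_name == "GLU"

    def test_missing_basic_pattern_raises(self):
        specs, charged = sio.default_toy_specs()
        charged["S4"] = [(63, "ALA"), (66, "ARG"), (69, "ARG"), (72, "LYS")]
        with pytest.raises(ValueError, match="S4 must carry"):
            sio.build_toy_vsd(specs, charged)

    def test_wrong_helix_count(self):
        specs, charged = sio.default_toy_specs()
        with pytest.raises(ValueError, match="4 helix"):
            sio.build_toy_vsd(specs[:3], charged)


class TestSuperpose:
    def test_self_identity(self, toy_wt):
        sup = sio.superpose(toy_wt, toy_wt)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_translation_recovery(self, toy_wt):
        moved = toy_wt.copy()
        moved.set_coords(moved.coords + np.array([5.0, 0.0, 0.0]))
        sup = sio.superpose(moved, toy_wt)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_rotation_angle_recovery(self, toy_wt):
        moved = toy_wt.copy()
        rotate_about_z(moved, np.arange(len(moved)), 30.0, center=np.zeros(2))
        sup = sio.superpose(moved, toy_wt)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        angle = math.degrees(math.acos((np.trace(sup.rotation) - 1.0) / 2.0))
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_too_few_pairs(self, toy_wt):
        sel = [((("A", 1, "CA"))), (("A", 2, "CA"))]
        pairs = [(s, s) for s in sel]
        with pytest.raises(ValueError, match=">= 3"):
            sio.superpose(toy_wt, toy_wt, pairs)

    def test_collinear_selection(self):
        atoms = [sio.Atom("CA", "ALA", i, "A", np.array([0.0, 0.0, float(i)]))
                 for i in range(1, 6)]
        s = sio.Structure(atoms, {})
        with pytest.raises(ValueError, match="collinear"):
            sio.superpose(s, s)

    def test_rmsd_invariant_under_joint_rigid_transform(self, toy_wt):
        rng = np.random.default_rng(5)
        mobile = toy_wt.copy()
        mobile.set_coords(mobile.coords + rng.normal(0, 1.0, mobile.coords.shape))
        base = sio.superpose(mobile, toy_wt).rmsd
        for _ in range(20):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            theta = rng.uniform(0, 2 * np.pi)
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
            shift = rng.uniform(-20, 20, 3)
            a = mobile.copy()
            b = toy_wt.copy()
            a.set_coords(a.coords @ rot.T + shift)
            b.set_coords(b.coords @ rot.T + shift)
            assert sio.superpose(a, b).rmsd == pytest.approx(base, abs=1e-8)
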