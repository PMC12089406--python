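"""Structure I/O, atom selection, oxo identification and superposition."""

import numpy as np
import pytest

import nacsel as ns
from nacsel.errors import GeometryError, InputError, TopologyError
from nacsel.synthetic import _rotation_about

from conftest import make_ensemble, rigid_transform


class TestReadWrite:
    def test_single_model_pdb(self, minimal_pdb):
        ens = ns.read_structure(minimal_pdb)
        assert ens.n_frames == 1
        assert ens.n_atoms == 4
        assert [a.element for a in ens.topology] == ["FE", "O", "C", "H"]

    def test_multi_model_frame_count(self, tmp_path):
        base = minimal = (
            "HETATM    1 FE   FE  A   1       0.000   0.000   {z:7.3f}  1.00  0.00          FE\n"
            "HETATM    2  O1  OXO A   2       0.000   0.000   1.620  1.00  0.00           O\n"
        )
        text = ""
        for m in range(3):
            text += f"MODEL     {m + 1:4d}\n" + base.format(z=0.1 * m) + "ENDMDL\n"
        p = tmp_path / "multi.pdb"
        p.write_text(text + "END\n")
        ens = ns.read_structure(p)
        assert ens.n_frames == 3
        assert ens.coords(2)[0, 2] == pytest.approx(0.2)

    def test_inconsistent_model_raises_topology_error(self, tmp_path):
        a1 = "HETATM    1 FE   FE  A   1       0.000   0.000   0.000  1.00  0.00          FE\n"
        a2 = "HETATM    2  O1  OXO A   2       0.000   0.000   1.620  1.00  0.00           O\n"
        text = "MODEL        1\n" + a1 + a2 + "ENDMDL\nMODEL        2\n" + a1 + "ENDMDL\nEND\n"
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        with pytest.raises(TopologyError, match="model 2"):
            ns.read_structure(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            ns.read_structure(tmp_path / "nope.pdb")

    def test_altloc_highest_occupancy_tie_to_a(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      3  CB BALA A   1       9.000   0.000   0.000  0.70  0.00           C\n"
            "ATOM      4  CB AALA A   1       7.000   0.000   0.000  0.30  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        ens = ns.read_structure(p)
        assert ens.n_atoms == 2
        xyz = {a.name: ens.coords(0)[i] for i, a in enumerate(ens.topology)}
        assert xyz["CA"][0] == pytest.approx(0.0)  # tie -> altloc A
        assert xyz["CB"][0] == pytest.approx(9.0)  # higher occupancy wins

    def test_write_read_roundtrip_3_decimals(self, tmp_path):
        ens, _, _, _, _ = ns.sample_nac_ensemble("C-7", 0.2, 20, seed=4)
        p = tmp_path / "rt.pdb"
        ns.write_pdb(ens, p)
        back = ns.read_structure(p)
        assert back.n_frames == ens.n_frames
        for fa, fb in zip(ens.frames, back.frames):
            np.testing.assert_allclose(fa, fb, atol=5.1e-4)


class TestSelectAtoms:
    def test_element_filter_finds_single_iron(self, theozyme):
        idx = ns.select_atoms(theozyme, ns.AtomSelector(element="FE"))
        assert len(idx) == 1

    def test_residue_name_filter_matches_brute_force(self, theozyme):
        idx = ns.select_atoms(theozyme, ns.AtomSelector(residue_name="MIM"))
        brute = [i for i, a in enumerate(theozyme.topology) if a.residue_name == "MIM"]
        assert idx == brute
        assert len(idx) == 12  # two 6-atom methylimidazoles

    def test_missing_chain_gives_empty_selection(self, theozyme):
        assert ns.select_atoms(theozyme, ns.AtomSelector(chain="Z")) == []

    def test_selector_requires_a_filter(self):
        with pytest.raises(ns.ValidationError):
            ns.AtomSelector()


class TestIdentifyOxo:
    def test_theozyme_oxo_found_uniquely(self, theozyme):
        fe = ns.select_atoms(theozyme, ns.AtomSelector(element="FE"))[0]
        oxo = ns.identify_oxo(theozyme, fe)
        assert theozyme.topology[oxo].residue_name == "OXO"
        d = np.linalg.norm(theozyme.coords(0)[oxo] - theozyme.coords(0)[fe])
        assert d == pytest.approx(1.62)

    def test_two_free_oxygens_is_ambiguous(self):
        records = [
            ("FE", "FE", "FE", 1, "A", "hetero", (0, 0, 0)),
            ("O1", "O", "OXO", 2, "A", "hetero", (0, 0, 1.6)),
            ("O2", "O", "OXO", 3, "A", "hetero", (0, 0, -1.7)),
        ]
        ens = make_ensemble(records, [[r[-1] for r in records]])
        with pytest.raises(GeometryError, match="ambiguous"):
            ns.identify_oxo(ens, 0)

    def test_water_only_resting_state_reports_no_oxo(self):
        records = [
            ("FE", "FE", "FE", 1, "A", "hetero", (0, 0, 0)),
            ("O", "O", "HOH", 2, "A", "water", (0, 0, 2.2)),
        ]
        ens = make_ensemble(records, [[r[-1] for r in records]])
        with pytest.raises(GeometryError, match="no oxo found"):
            ns.identify_oxo(ens, 0)

    def test_non_iron_index_rejected(self, theozyme):
        with pytest.raises(ns.ValidationError):
            ns.identify_oxo(theozyme, 1)


class TestSuperpose:
    def test_self_superposition_is_zero(self, theozyme):
        xyz = theozyme.coords(0)
        fit = ns.superpose(xyz, xyz, [(i, i) for i in range(len(xyz))])
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_known_transform_recovered(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(15, 3))
        R, t = rigid_transform(rng)
        B = A @ R.T + t
        fit = ns.superpose(B, A, [(i, i) for i in range(15)])
        np.testing.assert_allclose(fit.rotation, R, atol=1e-8)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        A = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 3))
        fit = ns.superpose(A, B, [(i, i) for i in range(30)])
        est, rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
        np.testing.assert_allclose(fit.rotation, est.as_matrix(), atol=1e-8)
        assert fit.rmsd == pytest.approx(rssd / np.sqrt(30), abs=1e-8)

    def test_two_pairs_rejected(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(GeometryError):
            ns.superpose(A, A, [(0, 0), (1, 1)])

    def test_collinear_pairing_rejected(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            ns.superpose(A, A, [(i, i) for i in range(4)])

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(25, 3))
        B = A + rng.normal(scale=0.3, size=(25, 3))
        pairing = [(i, i) for i in range(25)]
        base = ns.superpose(A, B, pairing).rmsd
        for _ in range(5):
            R, t = rigid_transform(rng)
            moved = ns.superpose(A @ R.T + t, B @ R.T + t, pairing).rmsd
            assert moved == pytest.approx(base, abs=1e-8)

    def test_rmsd_symmetric_in_arguments(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(10, 3))
        B = A + rng.normal(scale=0.5, size=(10, 3))
        pairing = [(i, i) for i in range(10)]
        assert ns.superpose(A, B, pairing).rmsd == pytest.approx(
            ns.superpose(B, A, pairing).rmsd, abs=1e-8
        )


class TestCalphaSuperposition:
    def _protein(self, tmp_path, name, seq, coords, offset=0):
        lines = []
        for k, (aa3, xyz) in enumerate(zip(seq, coords)):
            lines.append(
                f"ATOM  {k + 1:5d}  CA  {aa3} A{k + 1 + offset:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\nEND\n")
        return p

    def test_homologue_pairing_ignores_residue_numbering(self, tmp_path):
        rng = np.random.default_rng(21)
        coords = np.cumsum(rng.normal(scale=2.0, size=(30, 3)), axis=0)
        seq = ["ALA", "GLY", "LEU", "VAL", "THR"] * 6
        pa = self._protein(tmp_path, "a.pdb", seq, coords)
        R, t = rigid_transform(rng)
        # same fold, renumbered residues, a few point mutations
        seq_b = list(seq)
        seq_b[4], seq_b[17] = "SER", "PHE"
        pb = self._protein(tmp_path, "b.pdb", seq_b, coords @ R.T + t, offset=100)
        fit = ns.superpose_calpha(ns.read_structure(pa), ns.read_structure(pb))
        assert fit.n_pairs == 30
        assert fit.rmsd == pytest.approx(0.0, abs=1e-3)
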