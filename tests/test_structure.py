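"""Structure post-processing: averages, distances, contact-difference maps."""

import numpy as np
import pandas as pd
import pytest

from twitchlab.structure import (StructureModel, average_structure,
                                 contact_diff_map,
                                 inhibitory_peptide_actin_distance,
                                 ion_coordination_distances)
from twitchlab.synth import synth_toy_structure


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


@pytest.fixture
def arc_and_actin():
    """11-residue cTnI arc, all exactly 20 A from a point-mass actin."""
    return synth_toy_structure({
        "I": {"role": "cTnI", "resstart": 137,
              "arc": {"center": (0.0, 0.0, 0.0), "radius": 20.0, "n": 11}},
        "A": {"role": "actin", "atom": {"position": (0.0, 0.0, 0.0)}},
    })


@pytest.fixture
def tn_pair():
    """Small cTnC/cTnI toy with a tunable inter-chain separation."""
    def build(offset=(0.0, 0.0, 0.0)):
        off = np.asarray(offset)
        return synth_toy_structure({
            "C": {"role": "cTnC",
                  "points": [(0, 0, 0), (4, 0, 0), (40, 40, 0)]},
            "I": {"role": "cTnI",
                  "points": [p + off for p in
                             (np.array([0, 6, 0.0]), np.array([4, 6, 0.0]))]},
        })
    return build


class TestAverageStructure:
    def test_single_frame_identity(self, arc_and_actin):
        avg = average_structure([arc_and_actin])
        assert np.allclose(avg.coords(), arc_and_actin.coords())

    def test_mirrored_frames_cancel_off_plane(self):
        a = synth_toy_structure({"C": {"role": "cTnC",
                                       "points": [(0, 0, 0), (1, 2, 3)]}})
        b = a.transformed(R=np.diag([1.0, 1.0, -1.0]))  # mirror about z=0
        avg = average_structure([a, b])
        # the atom on the plane is unchanged; the other collapses onto it
        assert np.allclose(avg.coords()[0], [0, 0, 0])
        assert np.allclose(avg.coords()[1], [1, 2, 0])

    def test_three_frames_match_centroid_oracle(self, arc_and_actin, rng):
        offsets = rng.normal(0, 1.0, size=(3, 1, 3))
        frames = [arc_and_actin.transformed(t=off[0]) for off in offsets]
        avg = average_structure(frames)
        oracle = np.mean([f.coords() for f in frames], axis=0)
        assert np.allclose(avg.coords(), oracle, atol=1e-12)

    def test_atom_mismatch_rejected(self, arc_and_actin, tn_pair):
        with pytest.raises(ValueError, match="identity"):
            average_structure([arc_and_actin, tn_pair()])


class TestInhibitoryPeptideDistance:
    def test_designed_radius_recovered(self, arc_and_actin):
        assert inhibitory_peptide_actin_distance(arc_and_actin) == \
            pytest.approx(20.0, abs=1e-9)

    def test_closest_monomer_selected(self):
        s = synth_toy_structure({
            "I": {"role": "cTnI", "resstart": 137,
                  "arc": {"center": (0, 0, 0), "radius": 20.0, "n": 11}},
            "A": {"role": "actin", "atom": {"position": (0.0, 0.0, 0.0)}},
            "B": {"role": "actin", "atom": {"position": (35.0, 0.0, 0.0)}},
        })
        d = inhibitory_peptide_actin_distance(s)
        assert d == pytest.approx(20.0, abs=1e-9)

    def test_matches_brute_force_on_random_geometry(self, rng):
        pep = rng.normal(0, 10, size=(11, 3))
        monomer = rng.normal(20, 5, size=(40, 3))
        s = synth_toy_structure({
            "I": {"role": "cTnI", "resstart": 137, "points": pep},
            "A": {"role": "actin", "points": monomer, "atom_name": "CA"},
        })
        com = monomer.mean(axis=0)  # equal masses
        oracle = np.mean([np.linalg.norm(p - com) for p in pep])
        assert inhibitory_peptide_actin_distance(s) == \
            pytest.approx(oracle, abs=1e-9)

    def test_missing_residue_reported(self):
        s = synth_toy_structure({
            "I": {"role": "cTnI", "resstart": 137,
                  "arc": {"center": (0, 0, 0), "radius": 20.0, "n": 8}},
            "A": {"role": "actin", "atom": {"position": (0.0, 0.0, 0.0)}},
        })
        with pytest.raises(KeyError, match=r"145, 146, 147"):
            inhibitory_peptide_actin_distance(s)


class TestIonCoordination:
    def test_axis_aligned_and_coincident(self):
        s = synth_toy_structure({
            "C": {"role": "cTnC",
                  "points": [(0, 0, 0), (3, 0, 0)], "element": "O",
                  "atom_name": "OD1"},
            "X": {"role": "ion", "atom": {"position": (0.0, 0.0, 0.0),
                                          "element": "Ca", "name": "CA"}},
        })
        d = ion_coordination_distances(s, ("X", 1, "CA"),
                                       [("C", 2, "OD1"), ("C", 1, "OD1")])
        assert d[0] == pytest.approx(3.0, abs=1e-12)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_seven_oxygens_match_hand_computation(self, rng):
        pos = rng.normal(0, 3, size=(7, 3))
        ion = np.array([1.0, -2.0, 0.5])
        s = synth_toy_structure({
            "C": {"role": "cTnC", "points": pos, "element": "O",
                  "atom_name": "OD1"},
            "X": {"role": "ion", "atom": {"position": ion, "element": "Ca",
                                          "name": "CA"}},
        })
        d = ion_coordination_distances(
            s, ("X", 1, "CA"), [("C", i, "OD1") for i in range(1, 8)])
        assert np.allclose(d, np.linalg.norm(pos - ion, axis=1), atol=1e-12)

    def test_empty_selector_named_in_error(self, arc_and_actin):
        with pytest.raises(KeyError, match="OD1"):
            ion_coordination_distances(arc_and_actin, ("A", 1, "OD1"), [])


class TestContactDiffMap:
    def test_identical_structures_give_zero(self, tn_pair):
        s = tn_pair()
        cmap = contact_diff_map(s, s, cutoff=10.0)
        assert len(cmap.pairs) == 4  # far cTnC residue 3 is outside cutoff
        assert np.allclose(cmap.pairs["delta"], 0.0)

    def test_rigid_translation_along_separation_axis(self, tn_pair):
        """cTnI sits +y of cTnC residues 1-2; translating it +2 A along y
        increases every in-contact pair distance by exactly 2 A in a
        geometry where pair vectors are y-aligned."""
        wt = synth_toy_structure({
            "C": {"role": "cTnC", "points": [(0, 0, 0), (4, 0, 0)]},
            "I": {"role": "cTnI", "points": [(0, 6, 0), (4, 6, 0)]},
        })
        var = synth_toy_structure({
            "C": {"role": "cTnC", "points": [(0, 0, 0), (4, 0, 0)]},
            "I": {"role": "cTnI", "points": [(0, 8, 0), (4, 8, 0)]},
        })
        cmap = contact_diff_map(wt, var, cutoff=6.5)
        # only the y-aligned pairs are within 6.5 A in WT
        assert set(map(tuple, cmap.pairs[["resC", "resI"]].values)) == \
            {(1, 1), (2, 2)}
        assert np.allclose(cmap.pairs["delta"], 2.0, atol=1e-12)

    def test_zero_cutoff_empty(self, tn_pair):
        s = tn_pair()
        assert contact_diff_map(s, s, cutoff=0.0).pairs.empty

    def test_pair_set_depends_only_on_wt(self, tn_pair):
        wt = tn_pair()
        near = contact_diff_map(wt, tn_pair((0.0, 1.0, 0.0)), cutoff=10.0)
        far = contact_diff_map(wt, tn_pair((0.0, 100.0, 0.0)), cutoff=10.0)
        assert near.pairs[["resC", "resI"]].equals(far.pairs[["resC", "resI"]])

    def test_missing_variant_residue_rejected(self, tn_pair):
        wt = tn_pair()
        var = tn_pair()
        var.atoms = var.atoms[~((var.atoms["chain"] == "I")
                                & (var.atoms["resnum"] == 2))]
        with pytest.raises(KeyError, match="cTnI"):
            contact_diff_map(wt, var)

    def test_matrix_pivot(self, tn_pair):
        s = tn_pair()
        m = contact_diff_map(s, s, cutoff=10.0).to_matrix()
        assert m.shape == (2, 2)


class TestRigidMotionInvariance:
    def test_all_distance_operations(self, rng):
        pep = rng.normal(0, 8, size=(11, 3))
        actin = rng.normal(25, 4, size=(30, 3))
        ctnc = rng.normal(-10, 5, size=(6, 3))
        ion = rng.normal(0, 2, size=3)
        spec = {
            "I": {"role": "cTnI", "resstart": 137, "points": pep},
            "A": {"role": "actin", "points": actin},
            "C": {"role": "cTnC", "points": ctnc, "element": "O",
                  "atom_name": "OD1"},
            "X": {"role": "ion", "atom": {"position": ion, "element": "Ca",
                                          "name": "CA"}},
        }
        s = synth_toy_structure(spec)
        R = rotation_matrix([1.0, 2.0, 0.5], 1.1)
        moved = s.transformed(R=R, t=np.array([5.0, -3.0, 12.0]))

        d0 = inhibitory_peptide_actin_distance(s)
        d1 = inhibitory_peptide_actin_distance(moved)
        assert d1 == pytest.approx(d0, abs=1e-9)

        sel = [("C", i, "OD1") for i in range(1, 7)]
        i0 = ion_coordination_distances(s, ("X", 1, "CA"), sel)
        i1 = ion_coordination_distances(moved, ("X", 1, "CA"), sel)
        assert np.allclose(i0, i1, atol=1e-9)

        # contact map between WT and a rigidly moved copy is identically 0
        # (com metric: the toy cTnC chain carries oxygen atoms, not CA)
        cmap = contact_diff_map(s, moved, cutoff=100.0, metric="com")
        assert len(cmap.pairs) > 0
        assert np.allclose(cmap.pairs["delta"], 0.0, atol=1e-9)


class TestPdbIO:
    def test_round_trip_preserves_geometry(self, tmp_path, arc_and_actin):
        path = tmp_path / "toy.pdb"
        arc_and_actin.to_pdb(path)
        back = StructureModel.from_pdb(
            path, chain_roles=dict(arc_and_actin.chain_roles))
        assert len(back.atoms) == len(arc_and_actin.atoms)
        # PDB fixed-point coordinates carry 3 decimals
        assert np.allclose(back.coords(), arc_and_actin.coords(), atol=5e-4)
        assert inhibitory_peptide_actin_distance(back) == \
            pytest.approx(20.0, abs=1e-3)

    def test_roles_yaml_sidecar(self, tmp_path, arc_and_actin):
        import yaml
        path = tmp_path / "toy.pdb"
        roles = tmp_path / "roles.yaml"
        arc_and_actin.to_pdb(path)
        roles.write_text(yaml.safe_dump(arc_and_actin.chain_roles))
        back = StructureModel.from_pdb(path, roles_yaml=roles)
        assert back.chain_roles == arc_and_actin.chain_roles

    def test_unmapped_chain_rejected(self):
        atoms = pd.DataFrame(
            [("Z", 1, "GLY", "CA", "C", 0.0, 0.0, 0.0, 12.011)],
            columns=["chain", "resnum", "resname", "atom", "element",
                     "x", "y", "z", "mass"])
        with pytest.raises(ValueError, match="without a role"):
            StructureModel(atoms=atoms, chain_roles={"A": "actin"})
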