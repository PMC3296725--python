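"""Structural geometry: parsing, disulfides, prolines, H-bonds, labels."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hxfold as hx
from hxfold.fixtures import build_extended_chain, build_ideal_helix
from hxfold.geometry import angle, distance
from hxfold.structure import StructureError, backbone_torsions

from conftest import synthetic_structure


class TestParsePdb:
    def test_helix_fixture_round_trip(self, helix12):
        assert len(helix12) == 12
        for r in helix12.residues:
            assert r.has("N", "CA", "C", "O")

    def test_no_atom_records_is_an_error(self):
        with pytest.raises(StructureError):
            hx.parse_pdb("HEADER  nothing here\nEND\n")

    def test_malformed_coordinate_names_line(self):
        text = build_ideal_helix(6)
        lines = text.splitlines()
        lines[3] = lines[3][:30] + "  bad3.14" + lines[3][38:]
        with pytest.raises(StructureError, match="line 4"):
            hx.parse_pdb("\n".join(lines))

    def test_waters_and_hetatm_ignored(self):
        text = build_ideal_helix(6)
        text = text.replace(
            "END",
            "HETATM 9991  O   HOH A 501      0.000   0.000   0.000"
            "  1.00  0.00           O\nEND")
        s = hx.parse_pdb(text)
        assert len(s) == 6

    def test_written_subset_reparses(self, helix12):
        subset = [r.key for r in helix12.residues[:4]]
        text = hx.write_pdb(helix12, subset)
        s = hx.parse_pdb(text)
        assert [r.number for r in s.residues] == [1, 2, 3, 4]
        np.testing.assert_allclose(s.residues[0].atoms["CA"],
                                   helix12.residues[0].atoms["CA"], atol=1e-3)


def _cys_pair(d, num_a=1, num_b=2):
    return synthetic_structure(
        {num_a: {"N": (0, 0, 0), "SG": (0, 0, 0)},
         num_b: {"N": (5, 0, 0), "SG": (d, 0, 0)}},
        names={num_a: "CYS", num_b: "CYS"})


class TestDisulfides:
    @pytest.mark.parametrize("d,expect_pair", [
        (2.30, True),    # inclusive boundary
        (2.018, True),
        (2.31, False),
        (8.712, False),
    ])
    def test_cutoff_boundary(self, d, expect_pair):
        ds = hx.detect_disulfides(_cys_pair(d))
        assert bool(ds.pairs) == expect_pair
        if not expect_pair:
            assert [k for k, _ in ds.free_cysteines] == \
                [("A", 1, " "), ("A", 2, " ")]
            assert ds.free_cysteines[0][1] == pytest.approx(d, abs=1e-3)

    def test_pairing_is_involutive_and_exclusive(self):
        # four cysteines, two close pairs; greedy matching must not reuse one
        s = synthetic_structure(
            {1: {"N": (0, 0, 0), "SG": (0.0, 0, 0)},
             2: {"N": (1, 0, 0), "SG": (2.0, 0, 0)},
             3: {"N": (2, 0, 0), "SG": (10.0, 0, 0)},
             4: {"N": (3, 0, 0), "SG": (12.1, 0, 0)}},
            names={i: "CYS" for i in range(1, 5)})
        ds = hx.detect_disulfides(s)
        flat = [k for a, b, _ in ds.pairs for k in (a, b)]
        assert len(flat) == len(set(flat)) == 4

    def test_missing_sg_excluded_with_warning(self):
        s = synthetic_structure(
            {1: {"N": (0, 0, 0)}, 2: {"N": (5, 0, 0), "SG": (5, 0, 0)}},
            names={1: "CYS", 2: "CYS"})
        with pytest.warns(UserWarning, match="SG"):
            ds = hx.detect_disulfides(s)
        assert [k for k, _ in ds.free_cysteines] == [("A", 2, " ")]

    def test_reported_distance_three_decimals(self):
        ds = hx.detect_disulfides(_cys_pair(2.0184))
        assert ds.pairs[0][2] == pytest.approx(2.018, abs=5e-4)


class TestProlines:
    def _xaa_pro(self, d_ca_ca, d_ca_cd):
        return synthetic_structure(
            {1: {"N": (0, 0, 0), "CA": (0, 0, 0)},
             2: {"N": (1, 0, 0), "CA": (d_ca_ca, 0, 0),
                 "CD": (0, d_ca_cd, 0)}},
            names={2: "PRO"})

    @pytest.mark.parametrize("dcaca,dcacd,conf", [
        (3.811, 2.878, "trans"),   # typical trans geometry
        (3.039, 3.883, "cis"),     # typical cis geometry
        (2.9, 3.8, "cis"),
    ])
    def test_conformation_rule(self, dcaca, dcacd, conf):
        (p,) = hx.classify_prolines(self._xaa_pro(dcaca, dcacd))
        assert p.conformation == conf
        assert p.d_ca_ca == pytest.approx(dcaca, abs=1e-3)
        assert p.d_ca_cd == pytest.approx(dcacd, abs=1e-3)

    def test_every_complete_proline_gets_exactly_one_call(self):
        s = self._xaa_pro(3.8, 2.9)
        calls = hx.classify_prolines(s)
        assert len(calls) == 1 and calls[0].conformation in ("cis", "trans")

    def test_n_terminal_proline_skipped_with_warning(self):
        s = synthetic_structure(
            {1: {"N": (0, 0, 0), "CA": (0, 0, 0), "CD": (1, 0, 0)}},
            names={1: "PRO"})
        with pytest.warns(UserWarning, match="N-terminal"):
            assert hx.classify_prolines(s) == []

    def test_missing_cd_is_an_error_naming_residue(self):
        s = synthetic_structure(
            {1: {"N": (0, 0, 0), "CA": (0, 0, 0)},
             2: {"N": (1, 0, 0), "CA": (3.8, 0, 0)}},
            names={2: "PRO"})
        with pytest.raises(StructureError, match="PRO2"):
            hx.classify_prolines(s)


class TestHydrogenBonds:
    def test_ideal_helix_gives_the_i_plus_4_ladder(self, helix12):
        hbonds = hx.detect_backbone_hbonds(helix12)
        ladder = {(b.donor[1], b.acceptor[1]) for b in hbonds
                  if b.donor[1] - b.acceptor[1] == 4}
        assert ladder == {(i + 4, i) for i in range(1, 9)}
        # verify each detected bond against raw-coordinate geometry
        for b in hbonds:
            n = helix12.get(b.donor).atoms["N"]
            o = helix12.get(b.acceptor).atoms["O"]
            c = helix12.get(b.acceptor).atoms["C"]
            ca = helix12.get(b.donor).atoms["CA"]
            assert b.distance == pytest.approx(distance(n, o), abs=1e-9)
            assert b.distance <= 3.28
            assert 90.0 <= angle(n, o, c) <= 180.0
            assert 90.0 <= angle(o, n, ca) <= 180.0

    def test_extended_chain_has_no_bonds(self):
        s = hx.parse_pdb(build_extended_chain(10))
        assert hx.detect_backbone_hbonds(s) == []

    def test_acceptor_angle_window_boundary(self):
        # N...O = 3.2 A but N-O=C angle of 85 degrees: rejected
        s = synthetic_structure({
            1: {"N": (0, 0, 0), "CA": (1.46, 0, 0), "C": (2, 1, 0),
                "O": (2, 2, 0)},
            2: {"N": (9, 0, 0), "CA": (10, 0, 0), "C": (11, 0, 0),
                "O": (12, 0, 0)},
            3: {"N": (20.0, 0, 0), "CA": (20.0, 1.46, 0), "C": (22, 0, 0),
                "O": (23, 0, 0)},
        })
        # acceptor 1 placed near donor 3: N...O = 3.2 A and the donor-side
        # angle is exactly 90 deg, but the N-O=C angle is 85 deg -> reject
        o = np.array([20.0 + 3.2, 0.0, 0.0])
        c = o + 1.23 * np.array([-np.cos(np.radians(85.0)),
                                 np.sin(np.radians(85.0)), 0.0])
        s.residues[0].atoms["O"] = o
        s.residues[0].atoms["C"] = c
        bonds = hx.detect_backbone_hbonds(s)
        assert all(not (b.donor[1] == 3 and b.acceptor[1] == 1)
                   for b in bonds)

    def test_prolines_never_donate(self, helix12):
        text = build_ideal_helix(12).replace("ALA A   6", "PRO A   6")
        s = hx.parse_pdb(text)
        bonds = hx.detect_backbone_hbonds(s)
        assert all(b.donor[1] != 6 for b in bonds)

    def test_one_acceptor_per_donor(self, helix12):
        bonds = hx.detect_backbone_hbonds(helix12)
        donors = [b.donor for b in bonds]
        assert len(donors) == len(set(donors))


class TestSecondaryStructure:
    def test_helix_interior_labelled_alpha(self, helix12):
        ss = hx.assign_secondary_structure(
            helix12, hx.detect_backbone_hbonds(helix12))
        labels = {k[1]: v for k, v in ss.labels.items()}
        assert all(labels[i] == "alpha_helix" for i in range(2, 12))

    def test_hairpin_strands_labelled_antiparallel(self, hairpin):
        ss = hx.assign_secondary_structure(
            hairpin, hx.detect_backbone_hbonds(hairpin))
        labelled = {k for k, v in ss.labels.items()
                    if v == "antiparallel_beta"}
        assert {("A", 3, " "), ("A", 4, " "), ("A", 5, " "),
                ("B", 102, " "), ("B", 103, " "), ("B", 104, " ")} <= labelled

    def test_isolated_hbond_stays_none(self, helix12):
        # a single i->i+4 bond (no run of two) must not label anything
        bonds = hx.detect_backbone_hbonds(helix12)
        single = [b for b in bonds if (b.donor[1], b.acceptor[1]) == (5, 1)]
        ss = hx.assign_secondary_structure(helix12, single)
        assert set(ss.labels.values()) == {"none"}

    def test_labels_invariant_to_rigid_motion(self, helix12):
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        moved = hx.ProteinStructure("moved", [
            hx.Residue(r.chain_id, r.number, r.icode, r.name,
                       {a: rot @ xyz + shift for a, xyz in r.atoms.items()})
            for r in helix12.residues])
        ss0 = hx.assign_secondary_structure(
            helix12, hx.detect_backbone_hbonds(helix12))
        ss1 = hx.assign_secondary_structure(
            moved, hx.detect_backbone_hbonds(moved))
        assert ss0.labels == ss1.labels


class TestBackboneDistance:
    def test_same_residue_zero(self, helix12):
        k = helix12.residues[0].key
        assert hx.backbone_N_distance(helix12, k, k) == 0.0

    def test_pythagorean_triple(self):
        s = synthetic_structure({1: {"N": (0, 0, 0)}, 2: {"N": (3, 4, 0)}})
        keys = [r.key for r in s.residues]
        assert hx.backbone_N_distance(s, keys[0], keys[1]) == pytest.approx(5.0)

    def test_agrees_with_raw_coordinates(self, helix12):
        for a in helix12.residues[:4]:
            for b in helix12.residues[4:8]:
                expected = float(np.sqrt(((a.atoms["N"] - b.atoms["N"]) ** 2).sum()))
                got = hx.backbone_N_distance(helix12, a.key, b.key)
                assert got == pytest.approx(expected, abs=1e-9)

    def test_missing_nitrogen_is_an_error(self):
        s = synthetic_structure({1: {"N": (0, 0, 0)}, 2: {"CA": (1, 0, 0)}})
        keys = [r.key for r in s.residues]
        with pytest.raises(StructureError):
            hx.backbone_N_distance(s, keys[0], keys[1])


def test_torsions_match_fixture_targets(helix12):
    t = backbone_torsions(helix12)
    for key, (phi, psi) in t.items():
        if phi is not None:
            assert phi == pytest.approx(-57.0, abs=0.1)
        if psi is not None:
            assert psi == pytest.approx(-47.0, abs=0.1)
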