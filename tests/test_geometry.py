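import math

import numpy as np
import pytest

from pumpgeom.geometry_core import (
    catalytic_geometry,
    compare_structures,
    kabsch_superpose,
    point_angle,
    residue_pair_distance,
    residue_triplet_angle,
    rmsd,
)
from pumpgeom.segments import SegmentRegistry, default_registry
from pumpgeom.structure_io import Atom, Structure
from pumpgeom.synthetic_data import (
    _rotation_matrix,
    make_hinged_structure,
    make_rigid_pair,
)
from .conftest import poly_ala_chain


def random_rigid(rng):
    axis = rng.normal(size=3)
    rot = _rotation_matrix(axis, rng.uniform(0, 360))
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


def transform_structure(s: Structure, rot, trans) -> Structure:
    return s.with_coords(s.coords() @ rot.T + trans)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        t = kabsch_superpose(x, x)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)
        assert t.fit_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(25, 3))
        rot = _rotation_matrix([0, 0, 1], 90.0)
        y = x @ rot.T + np.array([1.0, 2.0, 3.0])
        t = kabsch_superpose(x, y)
        assert t.fit_rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.translation, [1.0, 2.0, 3.0], atol=1e-9)
        assert t.rotation_angle_deg == pytest.approx(90.0, abs=1e-7)
        assert abs(np.linalg.det(t.rotation) - 1.0) < 1e-9

    def test_optimality_against_random_rotation_oracle(self):
        # No rotation sampled at random may beat the closed-form optimum.
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 3))
        y = x @ _rotation_matrix([1, 1, 0], 40.0).T + rng.normal(scale=0.5, size=(20, 3))
        t = kabsch_superpose(x, y)
        yc = y - y.mean(axis=0)
        xc = x - x.mean(axis=0)
        for _ in range(10_000):
            rot, _ = random_rigid(rng)
            trial = xc @ rot.T
            assert t.fit_rmsd <= rmsd(trial, yc) + 1e-12

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="shape"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestCompareStructures:
    def test_structure_vs_copy_all_zero(self):
        s = poly_ala_chain(n_res=1000, mainchain=False)
        rep = compare_structures(s, s, "M5M10", ["M1M4", "HEADPIECE"], atom_set="CA")
        for name, (value, n) in rep.segments.items():
            assert value == pytest.approx(0.0, abs=1e-12)
            assert n > 0
        assert "M5M10" in rep.segments  # fit segment always reported

    def test_hinged_segment_rmsd_matches_closed_form(self):
        # Segment A unchanged, segment B rotated by a known angle about a
        # known axis: after fitting on A the report rmsd of B must equal the
        # rmsd computed directly from the applied rotation.
        s = poly_ala_chain(n_res=200, seed=5)
        coords = s.coords()
        rot = _rotation_matrix([0, 1, 0], 25.0)
        pivot = coords[99]
        moved = coords.copy()
        moved[100:] = (coords[100:] - pivot) @ rot.T + pivot
        mobile = s.with_coords(moved)
        reg = SegmentRegistry(entries={"front": ((1, 100),), "back": ((101, 200),)})
        rep = compare_structures(s, mobile, "front", ["back"], atom_set="CA",
                                 registry=reg)
        assert rep.segments["front"][0] == pytest.approx(0.0, abs=1e-9)
        expected = rmsd(moved[100:], coords[100:])
        assert rep.segments["back"][0] == pytest.approx(expected, rel=1e-9)

    def test_rigid_pair_fit_rmsd_matches_generator(self):
        ref, mob, truth = make_rigid_pair(n_atoms=500, noise_sd=0.3, seed=7)
        reg = SegmentRegistry(entries={"all": ((1, 500),)})
        rep = compare_structures(ref, mob, "all", [], atom_set="CA", registry=reg)
        assert rep.segments["all"][0] == pytest.approx(
            truth["expected_fit_rmsd"], rel=0.15)

    def test_symmetry_under_swap(self):
        ref, mob, _ = make_rigid_pair(n_atoms=300, noise_sd=0.4, seed=8)
        reg = SegmentRegistry(entries={"all": ((1, 300),)})
        a = compare_structures(ref, mob, "all", [], atom_set="CA", registry=reg)
        b = compare_structures(mob, ref, "all", [], atom_set="CA", registry=reg)
        assert a.segments["all"][0] == pytest.approx(b.segments["all"][0], abs=1e-6)

    def test_missing_segment_is_per_entry_error(self):
        s = poly_ala_chain(n_res=100)
        rep = compare_structures(s, s, "M1", ["M5M10"], atom_set="CA")
        assert "M5M10" in rep.errors
        assert "M1" in rep.segments


class TestAngles:
    def test_collinear_is_180(self):
        assert point_angle([0, 0, 0], [1, 0, 0], [2, 0, 0]) == pytest.approx(180.0)

    def test_right_angle(self):
        assert point_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_matches_direct_formula_on_random_triplets(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p1, p2, p3 = rng.normal(size=(3, 3))
            v1, v2 = p1 - p2, p3 - p2
            expected = math.degrees(math.acos(np.clip(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
            got = point_angle(p1, p2, p3)
            assert got == pytest.approx(expected, abs=1e-9)
            assert 0.0 <= got <= 180.0

    def test_zero_length_arm_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            point_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_triplet_angle_on_hinged_structure(self):
        s, truth = make_hinged_structure(147.0, seed=1)
        got = residue_triplet_angle(s, *truth["triplet"])
        assert got == pytest.approx(147.0, abs=1e-9)

    def test_triplet_angle_missing_atom_names_residue(self):
        s, truth = make_hinged_structure(100.0)
        with pytest.raises(KeyError, match="999"):
            residue_triplet_angle(s, 1, 11, 999)


class TestDistances:
    def test_atom_to_itself_zero(self, polyala):
        assert residue_pair_distance(polyala, 5, 5) == pytest.approx(0.0)

    def test_constructed_3_4_5(self):
        atoms = [
            Atom(1, "CA", "", "ALA", "A", 1, "", 0, 0, 0, 1.0, "C"),
            Atom(2, "CA", "", "ALA", "A", 2, "", 3, 4, 0, 1.0, "C"),
        ]
        s = Structure(atoms=atoms)
        assert residue_pair_distance(s, 1, 2) == pytest.approx(5.0)

    def test_missing_atom_raises(self, polyala):
        with pytest.raises(KeyError):
            residue_pair_distance(polyala, 1, 2, atom_a="OG")


def _catalytic_fixture(od_pos, pg_pos=(0.0, 0.0, 0.0), bridge_pos=(1.6, 0.0, 0.0),
                       resname="ATP", extra_od=None):
    bridge_name = {"ATP": "O3B", "ACP": "C3B"}[resname]
    bridge_elem = "O" if bridge_name == "O3B" else "C"
    atoms = [
        Atom(1, "OD1", "", "ASP", "A", 351, "", *od_pos, 1.0, "O"),
        Atom(2, "PG", "", resname, "A", 900, "", *pg_pos, 1.0, "P", hetero=True),
        Atom(3, bridge_name, "", resname, "A", 900, "", *bridge_pos, 1.0,
             bridge_elem, hetero=True),
    ]
    if extra_od is not None:
        atoms.insert(1, Atom(4, "OD2", "", "ASP", "A", 351, "", *extra_od, 1.0, "O"))
    return Structure(atoms=atoms)


class TestCatalyticGeometry:
    def test_inline_arrangement(self):
        s = _catalytic_fixture(od_pos=(-3.0, 0.0, 0.0))
        g = catalytic_geometry(s)
        assert g.d_od_pg == pytest.approx(3.0)
        assert g.theta_deg == pytest.approx(180.0)

    def test_perpendicular_arrangement(self):
        s = _catalytic_fixture(od_pos=(0.0, 2.5, 0.0))
        g = catalytic_geometry(s)
        assert g.theta_deg == pytest.approx(90.0)
        assert g.d_od_pg == pytest.approx(2.5)

    def test_picks_nearer_carboxyl_oxygen(self):
        s = _catalytic_fixture(od_pos=(-6.0, 0.0, 0.0), extra_od=(-2.0, 0.0, 0.0))
        g = catalytic_geometry(s)
        assert g.od_atom[3] == "OD2"
        assert g.d_od_pg == pytest.approx(2.0)

    def test_amppcp_methylene_bridge_accepted(self):
        s = _catalytic_fixture(od_pos=(-3.0, 0.0, 0.0), resname="ACP")
        g = catalytic_geometry(s)
        assert g.bridge_atom[3] == "C3B"
        assert g.theta_deg == pytest.approx(180.0)

    def test_alfx_uses_adp_bridging_oxygen(self):
        atoms = [
            Atom(1, "OD1", "", "ASP", "A", 351, "", -2.1, 0.0, 0.0, 1.0, "O"),
            Atom(2, "AL", "", "ALF", "A", 901, "", 0.0, 0.0, 0.0, 1.0, "Al",
                 hetero=True),
            Atom(3, "O3B", "", "ADP", "A", 902, "", 1.9, 0.3, 0.0, 1.0, "O",
                 hetero=True),
        ]
        g = catalytic_geometry(Structure(atoms=atoms))
        assert g.pg_atom[3] == "AL"
        assert g.d_od_pg == pytest.approx(2.1)
        assert g.theta_deg == pytest.approx(
            180.0 - math.degrees(math.atan2(0.3, 1.9)), abs=1e-9)

    def test_no_nucleotide_raises(self, polyala):
        with pytest.raises(ValueError, match="no γ-phosphate analogue"):
            catalytic_geometry(polyala)

    def test_multiple_nucleotides_listed(self):
        s1 = _catalytic_fixture(od_pos=(-3.0, 0.0, 0.0))
        atoms = s1.atoms + [
            Atom(10, "PG", "", "ATP", "B", 900, "", 20.0, 0.0, 0.0, 1.0, "P",
                 hetero=True)]
        with pytest.raises(ValueError, match="multiple"):
            catalytic_geometry(Structure(atoms=atoms))


class TestRigidInvariance:
    def test_observables_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(21)
        s, truth = make_hinged_structure(130.0, seed=3)
        cat = _catalytic_fixture(od_pos=(-1.0, 2.0, 0.5))
        for _ in range(5):
            rot, trans = random_rigid(rng)
            s2 = transform_structure(s, rot, trans)
            assert residue_triplet_angle(s2, *truth["triplet"]) == pytest.approx(
                residue_triplet_angle(s, *truth["triplet"]), abs=1e-6)
            assert residue_pair_distance(s2, 1, 21) == pytest.approx(
                residue_pair_distance(s, 1, 21), abs=1e-6)
            cat2 = transform_structure(cat, rot, trans)
            g1, g2 = catalytic_geometry(cat), catalytic_geometry(cat2)
            assert g2.d_od_pg == pytest.approx(g1.d_od_pg, abs=1e-6)
            assert g2.theta_deg == pytest.approx(g1.theta_deg, abs=1e-6)

    def test_compare_structures_invariant_under_transform_of_mobile(self):
        ref, mob, _ = make_rigid_pair(n_atoms=100, noise_sd=0.2, seed=9)
        reg = SegmentRegistry(entries={"all": ((1, 100),)})
        base = compare_structures(ref, mob, "all", [], atom_set="CA", registry=reg)
        rng = np.random.default_rng(22)
        rot, trans = random_rigid(rng)
        mob2 = transform_structure(mob, rot, trans)
        again = compare_structures(ref, mob2, "all", [], atom_set="CA", registry=reg)
        assert again.segments["all"][0] == pytest.approx(
            base.segments["all"][0], abs=1e-6)
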