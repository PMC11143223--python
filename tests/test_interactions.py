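"""Ring perception and the geometric interaction detectors vs independent gates."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinalysis.interactions import (
    AromaticRing,
    HalogenCriteria,
    HBondCriteria,
    PiCriteria,
    detect_halogen_bonds,
    detect_hbonds,
    detect_pi,
    find_rings,
    interaction_profile,
)
from kinalysis.structio import AtomRecord, Structure, truncate_to_alanine
from kinalysis.synth import LigandPoseSpec, ToySpec, make_toy_kinase, plant_ligand_pose

from conftest import make_structure


def hexagon(centroid, normal, radius=1.39, phase=0.0):
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = phase + np.arange(6) * np.pi / 3
    return np.asarray(centroid) + radius * (np.cos(ang)[:, None] * u
                                            + np.sin(ang)[:, None] * v)


def ring_at(centroid, normal, owner="RING", residue_seq=None):
    return AromaticRing(owner=owner, residue_seq=residue_seq,
                        member_names=tuple(f"C{i}" for i in range(6)),
                        centroid=np.asarray(centroid, float),
                        normal=np.asarray(normal, float), size=6)


def independent_pi_gate(ra, rb, crit=PiCriteria()):
    """Re-coded criteria checker, sharing nothing with the detector."""
    sep = rb.centroid - ra.centroid
    dist = float(np.sqrt(np.sum(sep ** 2)))
    cosang = abs(float(np.dot(ra.normal, rb.normal)))
    angle = float(np.degrees(np.arccos(min(1.0, cosang))))
    offs = []
    for n in (ra.normal, rb.normal):
        along = float(np.dot(sep, n))
        offs.append(float(np.sqrt(max(dist ** 2 - along ** 2, 0.0))))
    offset = min(offs)
    if dist <= crit.stack_max_distance and angle <= crit.stack_max_angle \
            and offset <= crit.stack_max_offset:
        return "pi_stack"
    if dist <= crit.t_max_distance and crit.t_min_angle <= angle <= crit.t_max_angle:
        return "pi_t"
    return None


class TestFindRings:
    def test_phe_template(self):
        pts = hexagon([0, 0, 0], [0, 0, 1])
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        st = make_structure(pts, names=names, residues=[7] * 6,
                            elements=["C"] * 6, res_names=["PHE"] * 6)
        rings = find_rings(st)
        assert len(rings) == 1
        assert rings[0].size == 6
        np.testing.assert_allclose(rings[0].centroid, [0, 0, 0], atol=1e-10)

    def test_trp_has_two_fused_rings(self):
        # idealized indole: 5-ring and 6-ring sharing the CD2-CE2 edge
        six = hexagon([0, 0, 0], [0, 0, 1], phase=np.pi / 6)
        six_names = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
        cd2, ce2 = six[0], six[1]
        mid = (cd2 + ce2) / 2
        edge = ce2 - cd2
        out = np.cross([0, 0, 1.0], edge)
        out /= np.linalg.norm(out)
        # rough planar 5-ring on the far side of the shared edge
        cg = mid + 1.9 * out + 0.65 * edge / np.linalg.norm(edge)
        cd1 = mid + 1.9 * out - 0.65 * edge / np.linalg.norm(edge)
        ne1 = mid + 1.1 * out + 1.25 * edge / np.linalg.norm(edge)
        positions = np.vstack([six, cg, cd1, ne1])
        names = six_names + ["CG", "CD1", "NE1"]
        st = make_structure(positions, names=names, residues=[550] * 9,
                            elements=[n[0] for n in names],
                            res_names=["TRP"] * 9)
        rings = find_rings(st)
        sizes = sorted(r.size for r in rings)
        assert sizes == [5, 6]
        shared = set(rings[0].member_names) & set(rings[1].member_names)
        assert shared == {"CD2", "CE2"}

    def test_biphenyl_ligand_two_rings_vs_cycle_oracle(self):
        import networkx as nx

        a = hexagon([0, 0, 0], [0, 0, 1])
        b = hexagon([2.78 + 1.48, 0, 0], [0, 0, 1], phase=np.pi)
        pts = np.vstack([a, b])
        names = [f"C{i + 1}" for i in range(12)]
        st = make_structure(pts, names=names, residues=[1] * 12,
                            elements=["C"] * 12, res_names=["BIP"] * 12,
                            hetero=[True] * 12)
        st = Structure(st.atoms, ligand_codes=frozenset({"BIP"}))
        rings = find_rings(st)
        assert len(rings) == 2 and all(r.size == 6 for r in rings)
        # oracle: exhaustive simple-cycle enumeration on the bond graph
        g = nx.Graph()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        g.add_edges_from(zip(*np.where((d > 0) & (d <= 1.6))))
        cycles56 = [c for c in nx.simple_cycles(g) if len(c) in (5, 6)]
        assert len(cycles56) == 2

    def test_nonplanar_cycle_rejected(self):
        pts = hexagon([0, 0, 0], [0, 0, 1])
        pts[0, 2] += 1.0  # puckered beyond the 0.3 A planarity gate
        st = make_structure(pts, names=[f"C{i}" for i in range(6)],
                            residues=[1] * 6, elements=["C"] * 6,
                            res_names=["LIG"] * 6, hetero=[True] * 6)
        assert find_rings(st) == []


class TestDetectPi:
    def test_canonical_parallel_stack(self):
        ra = ring_at([0, 0, 0], [0, 0, 1])
        rb = ring_at([0, 0, 3.5], [0, 0, 1])
        recs = detect_pi([ra], [rb])
        assert len(recs) == 1
        rec = recs[0]
        assert rec.kind == "pi_stack"
        assert rec.angle == pytest.approx(0.0, abs=1e-10)
        assert rec.offset == pytest.approx(0.0, abs=1e-10)

    def test_canonical_t_shape(self):
        ra = ring_at([0, 0, 0], [0, 0, 1])
        rb = ring_at([0, 0, 5.0], [1, 0, 0])
        recs = detect_pi([ra], [rb])
        assert len(recs) == 1 and recs[0].kind == "pi_t"
        assert recs[0].angle == pytest.approx(90.0, abs=1e-10)

    def test_out_of_range_parallel(self):
        ra = ring_at([0, 0, 0], [0, 0, 1])
        rb = ring_at([0, 0, 8.0], [0, 0, 1])
        assert detect_pi([ra], [rb]) == []

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            ra = ring_at(rng.normal(0, 2, 3), rng.normal(0, 1, 3), owner="A")
            rb = ring_at(rng.normal(0, 2, 3), rng.normal(0, 1, 3), owner="B")
            ab = detect_pi([ra], [rb])
            ba = detect_pi([rb], [ra])
            assert len(ab) == len(ba)
            if ab:
                assert ab[0].kind == ba[0].kind
                assert ab[0].angle == pytest.approx(ba[0].angle, abs=1e-10)

    def test_randomized_sweep_matches_independent_gate(self):
        rng = np.random.default_rng(99)
        n_detected = 0
        for _ in range(1000):
            ra = ring_at(rng.normal(0, 2.0, 3), rng.normal(0, 1, 3))
            rb = ring_at(ra.centroid + rng.normal(0, 3.0, 3), rng.normal(0, 1, 3),
                         owner="B")
            recs = detect_pi([ra], [rb])
            expected = independent_pi_gate(ra, rb)
            got = recs[0].kind if recs else None
            assert got == expected
            n_detected += got is not None
        assert n_detected > 50  # the sweep actually exercises both outcomes

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(17)
        R = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        for _ in range(200):
            ca, cb = rng.normal(0, 2.0, 3), rng.normal(0, 3.0, 3)
            na, nb = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
            before = detect_pi([ring_at(ca, na)], [ring_at(cb, nb, owner="B")])
            after = detect_pi([ring_at(R @ ca + t, R @ na)],
                              [ring_at(R @ cb + t, R @ nb, owner="B")])
            assert len(before) == len(after)
            if before:
                assert before[0].kind == after[0].kind


def hbond_structure(d_no, angle_deg, with_h=True):
    """N-H...O geometry with prescribed N-O distance and N-H...O angle (N-H = 1 A)."""
    n_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([1.0, 0.0, 0.0])
    a = np.radians(angle_deg)
    u = np.array([-np.cos(a), np.sin(a), 0.0])  # makes angle_deg with H->N
    # law of cosines for the H-O distance x: d_no^2 = 1 + x^2 - 2 x cos(a)
    x = np.cos(a) + np.sqrt(np.cos(a) ** 2 - 1.0 + d_no ** 2)
    o_pos = h_pos + x * u
    assert np.isclose(np.linalg.norm(o_pos - n_pos), d_no)
    positions = [n_pos, h_pos, o_pos] if with_h else [n_pos, o_pos]
    names = ["N", "H", "O"] if with_h else ["N", "O"]
    residues = [1, 1, 2] if with_h else [1, 2]
    return make_structure(positions, names=names, residues=residues,
                          elements=[nm[0] for nm in names],
                          res_names=["GLY", "GLY", "SER"][: len(names)])


class TestDetectHbonds:
    def test_canonical_nh_o(self):
        st = hbond_structure(2.9, 165.0)
        recs = detect_hbonds(st)
        assert len(recs) == 1
        assert recs[0].kind == "hbond"
        assert recs[0].distance == pytest.approx(2.9, abs=1e-6)

    def test_distance_gate(self):
        assert detect_hbonds(hbond_structure(4.2, 165.0)) == []

    def test_angle_gate_with_hydrogen(self):
        assert detect_hbonds(hbond_structure(3.0, 95.0)) == []

    def test_distance_only_without_hydrogen(self):
        st = hbond_structure(3.0, 95.0, with_h=False)
        recs = detect_hbonds(st)
        assert len(recs) == 1  # no H, so the angle gate cannot apply


class TestDetectHalogenBonds:
    def _cfo(self, d_fo, angle_deg):
        c = np.array([0.0, 0.0, 0.0])
        f = np.array([1.35, 0.0, 0.0])
        direction = np.array([np.cos(np.radians(180 - angle_deg)),
                              np.sin(np.radians(180 - angle_deg)), 0.0])
        o = f + d_fo * direction
        return make_structure(
            [c, f, o], names=["C1", "F1", "O"],
            residues=[1, 1, 2], elements=["C", "F", "O"],
            res_names=["LIG", "LIG", "SER"], hetero=[True, True, False])

    def test_canonical_cf_o(self):
        recs = detect_halogen_bonds(self._cfo(3.0, 170.0))
        assert len(recs) == 1 and recs[0].kind == "halogen"

    def test_angle_gate(self):
        assert detect_halogen_bonds(self._cfo(3.0, 120.0)) == []

    def test_near_gate_matches_bruteforce(self):
        st = self._cfo(3.4, 150.0)
        recs = detect_halogen_bonds(st)
        # independent brute-force scan
        coords = st.coords
        d = np.linalg.norm(coords[2] - coords[1])
        v1 = coords[0] - coords[1]
        v2 = coords[2] - coords[1]
        ang = np.degrees(np.arccos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)))
        expected = (d <= 3.5) and (ang >= 140.0)
        assert bool(recs) == expected
        assert len(recs) == 1

    def test_randomized_matches_gate_checker(self):
        rng = np.random.default_rng(3)
        crit = HalogenCriteria()
        hits = 0
        for _ in range(1000):
            d_fo = rng.uniform(2.5, 4.0)
            ang = rng.uniform(100.0, 180.0)
            recs = detect_halogen_bonds(self._cfo(d_fo, ang))
            expected = (d_fo <= crit.max_distance + 1e-12
                        and ang >= crit.min_angle - 1e-9)
            assert bool(recs) == expected, (d_fo, ang)
            hits += bool(recs)
        assert 0 < hits < 1000


class TestInteractionProfile:
    def test_planted_stack_at_site(self):
        toy = make_toy_kinase(ToySpec())
        st = plant_ligand_pose(toy, LigandPoseSpec(3.5, 0.0, 0.0))
        prof = interaction_profile(st, "LIG")
        assert 550 in prof
        assert any(r.kind == "pi_stack" for r in prof[550])

    def test_planted_t_shape(self):
        toy = make_toy_kinase(ToySpec())
        st = plant_ligand_pose(toy, LigandPoseSpec(5.0, 90.0, 0.0))
        prof = interaction_profile(st, "LIG")
        assert any(r.kind == "pi_t" for r in prof.get(550, []))

    def test_out_of_gate_distance(self):
        toy = make_toy_kinase(ToySpec())
        st = plant_ligand_pose(toy, LigandPoseSpec(8.0, 0.0, 0.0))
        prof = interaction_profile(st, "LIG")
        assert not any(r.kind.startswith("pi") for r in prof.get(550, []))

    def test_truncation_removes_site_entry(self):
        toy = make_toy_kinase(ToySpec())
        st = plant_ligand_pose(toy, LigandPoseSpec(3.5, 0.0, 0.0))
        mutated = truncate_to_alanine(st, 550)
        prof = interaction_profile(mutated, "LIG")
        assert 550 not in prof

    def test_absent_ligand_errors(self):
        toy = make_toy_kinase(ToySpec())
        with pytest.raises(ValueError, match="absent"):
            interaction_profile(toy, "LIG")
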