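import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from xlassemble.geometry import (RigidTransform, bend_angle, coord_rmsd,
                                 kabsch_superpose, pair_common_ca,
                                 principal_dimensions, random_rotation,
                                 rotation_about_axis)
from xlassemble.synthetic import _helix_trace

from conftest import ca_model


def grid_min_rmsd(P, Q, step_deg=10.0):
    """Brute-force RMSD minimum over a dense zyz-Euler rotation grid.

    Independent oracle for the Kabsch solution: for every grid rotation the
    optimal translation is the centroid match, so only rotations are
    enumerated.
    """
    a = np.arange(0.0, 360.0, step_deg)
    b = np.arange(0.0, 180.0 + step_deg, step_deg)
    euler = np.array(np.meshgrid(a, b, a)).reshape(3, -1).T
    mats = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rotated = np.einsum("mij,nj->mni", mats, Pc)
    rmsd = np.sqrt(np.mean(np.sum((rotated - Qc) ** 2, axis=2), axis=1))
    return float(rmsd.min())


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        reflection = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflection, np.zeros(3))

    def test_compose_and_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        a = RigidTransform(random_rotation(rng), rng.normal(size=3))
        b = RigidTransform(random_rotation(rng), rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
        assert np.allclose(a.compose(a.inverse()).apply(pts), pts, atol=1e-9)


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_identity(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation_and_translation(self):
        pts = np.random.default_rng(2).normal(size=(8, 3)) * 5.0
        R = rotation_about_axis([0.0, 0.0, 1.0], np.pi / 2)
        t = np.array([3.0, -1.0, 7.0])
        moved = pts @ R.T + t
        res = kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        applied = RigidTransform(R, t)
        assert res.transform.almost_equal(applied.inverse(), atol=1e-8)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_rotation_grid_on_4_point_toys(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(4, 3)) * 2.0
        Q = rng.normal(size=(4, 3)) * 2.0
        kab = kabsch_superpose(P, Q).rmsd
        grid = grid_min_rmsd(P, Q, step_deg=10.0)
        assert kab <= grid + 1e-9          # Kabsch is the true optimum
        max_radius = np.linalg.norm(P - P.mean(axis=0), axis=1).max()
        assert grid - kab <= max_radius * np.deg2rad(10.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rmsd_symmetric_and_invariant_under_joint_transform(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(5, 3)) * 4.0
        Q = P + rng.normal(size=(5, 3))
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(
            kabsch_superpose(Q, P).rmsd, abs=1e-9)
        G = RigidTransform(random_rotation(rng), rng.normal(size=3) * 10.0)
        assert kabsch_superpose(G.apply(P), G.apply(Q)).rmsd == pytest.approx(
            kabsch_superpose(P, Q).rmsd, abs=1e-8)

    def test_rejects_bad_inputs(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestPairCommonCa:
    def make_dimers(self):
        """Crystal-like dimer (residues 150-241) vs complex-like (171-237)."""
        trace = _helix_trace(100)
        xtal = ca_model({"A": trace, "B": trace + [12.0, 0.0, 0.0]},
                        start_res=150)
        xtal = xtal.select(residue_ranges={"A": [(150, 241)],
                                           "B": [(150, 241)]})
        em = ca_model({"A": trace, "B": trace + [12.0, 0.0, 0.0]},
                      start_res=150)
        em = em.select(residue_ranges={"A": [(171, 237)], "B": [(171, 237)]})
        return xtal, em

    def test_interval_intersection_gives_134_pairs(self):
        xtal, em = self.make_dimers()
        ca, cb, pairing = pair_common_ca(xtal, em, [("A", "A"), ("B", "B")])
        assert len(pairing) == 2 * 67 == 134
        assert ca.shape == cb.shape == (134, 3)

    def test_disjoint_ranges_raise(self):
        xtal, _ = self.make_dimers()
        other = ca_model({"A": _helix_trace(10)}, start_res=500)
        with pytest.raises(ValueError):
            pair_common_ca(xtal, other, [("A", "A")])

    def test_missing_ca_shrinks_pairing(self):
        xtal, em = self.make_dimers()
        em2 = em.select(residue_ranges={"A": [(171, 236)], "B": [(171, 237)]})
        _, _, pairing = pair_common_ca(xtal, em2, [("A", "A"), ("B", "B")])
        assert len(pairing) == 133

    def test_homodimer_alternative_assignment_keeps_lower_rmsd(self):
        xtal, em = self.make_dimers()
        # Swap the chain labels of the mobile copy: only the swapped
        # assignment superposes exactly.
        relabel = {"A": "B", "B": "A"}
        from dataclasses import replace
        from xlassemble.structio import StructureModel
        swapped = StructureModel([replace(a, chain_id=relabel[a.chain_id])
                                  for a in em.atoms])
        alts = [[("A", "A"), ("B", "B")], [("A", "B"), ("B", "A")]]
        ca, cb, pairing = pair_common_ca(xtal, swapped, alts)
        assert kabsch_superpose(ca, cb).rmsd == pytest.approx(0.0, abs=1e-8)


class TestPrincipalDimensions:
    def cuboid(self):
        xs = np.linspace(0.0, 10.0, 6)
        ys = np.linspace(0.0, 4.0, 4)
        zs = np.linspace(0.0, 2.0, 3)
        return np.array(np.meshgrid(xs, ys, zs)).reshape(3, -1).T

    def test_axis_aligned_cuboid(self):
        d = principal_dimensions(self.cuboid())
        assert np.allclose(d, [10.0, 4.0, 2.0], atol=1e-9)

    def test_rotation_invariance(self):
        pts = self.cuboid()
        rng = np.random.default_rng(6)
        moved = pts @ random_rotation(rng).T + rng.normal(size=3) * 50.0
        assert np.allclose(principal_dimensions(moved), [10.0, 4.0, 2.0],
                           atol=1e-6)

    def test_monotone_under_added_exterior_point(self):
        pts = self.cuboid()
        before = principal_dimensions(pts)
        after = principal_dimensions(np.vstack([pts, [30.0, 0.0, 0.0]]))
        assert after[0] >= before[0] - 1e-9

    def test_degenerate_coplanar_input_allowed(self):
        pts = self.cuboid()
        flat = pts * [1.0, 1.0, 0.0]
        d = principal_dimensions(flat)
        assert d[2] == pytest.approx(0.0, abs=1e-9)


class TestBendAngle:
    def helix_model(self, bend_deg=0.0, hinge=50, n=100):
        trace = _helix_trace(n)
        if bend_deg:
            pivot = trace[hinge].copy()
            R = rotation_about_axis([1.0, 0.0, 0.0], np.deg2rad(bend_deg))
            trace[hinge + 1:] = (trace[hinge + 1:] - pivot) @ R.T + pivot
        return ca_model({"A": trace})

    def test_straight_helix_is_straight(self):
        m = self.helix_model(0.0)
        ang = bend_angle(m, "A", (10, 40), (60, 90))
        assert ang == pytest.approx(0.0, abs=2.0)

    def test_constructed_30_degree_bend_recovered(self):
        m = self.helix_model(30.0)
        ang = bend_angle(m, "A", (10, 40), (60, 90))
        assert ang == pytest.approx(30.0, abs=3.0)

    def test_identical_windows_give_zero(self):
        m = self.helix_model(0.0)
        assert bend_angle(m, "A", (10, 40), (10, 40)) == pytest.approx(0.0,
                                                                       abs=1e-6)

    def test_short_window_rejected(self):
        m = self.helix_model(0.0)
        with pytest.raises(ValueError):
            bend_angle(m, "A", (10, 14), (60, 90))


def test_coord_rmsd_shape_mismatch():
    with pytest.raises(ValueError):
        coord_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
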