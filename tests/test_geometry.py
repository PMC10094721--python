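"""Geometric descriptor unit and property tests.

Every descriptor is checked against an independent brute-force or analytic
oracle, plus rigid-motion invariance with random rotations/translations.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loxtraj.core import DegenerateGeometryError, Frame, Topology, Trajectory
from loxtraj import geometry as g

from conftest import apply_rigid, random_rigid_transform


def frame_of(*points):
    return Frame(coords=np.array(points, dtype=float))


class TestDistance:
    def test_3_4_5_triangle(self):
        assert g.distance(frame_of((0, 0, 0), (3, 4, 0)), 0, 1) == 5.0

    def test_identical_points(self):
        assert g.distance(frame_of((1, 2, 3), (1, 2, 3)), 0, 1) == 0.0

    def test_random_pairs_match_norm_oracle(self, rng):
        pts = rng.normal(size=(50, 3)) * 10
        fr = Frame(coords=pts)
        for _ in range(100):
            i, j = rng.integers(0, 50, 2)
            expected = float(np.sqrt(np.sum((pts[i] - pts[j]) ** 2)))
            assert g.distance(fr, i, j) == pytest.approx(expected, rel=1e-12)

    def test_nan_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Frame(coords=np.array([[0.0, 0.0, np.nan]]))


class TestMinGroupDistance:
    def test_singletons_reduce_to_distance(self):
        fr = frame_of((0, 0, 0), (3, 4, 0))
        d, pair = g.min_group_distance(fr, [0], [1])
        assert d == 5.0 and pair == (0, 1)

    def test_known_minimum(self):
        fr = frame_of((0, 0, 0), (10, 0, 0), (2.41, 0, 0), (9, 9, 9))
        d, pair = g.min_group_distance(fr, [0, 1], [2, 3])
        assert d == pytest.approx(2.41) and pair == (0, 2)

    def test_tie_broken_by_lowest_pair(self):
        fr = frame_of((0, 0, 0), (10, 0, 0), (1, 0, 0), (11, 0, 0))
        d, pair = g.min_group_distance(fr, [0, 1], [2, 3])
        assert d == 1.0 and pair == (0, 2)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            g.min_group_distance(frame_of((0, 0, 0)), [], [0])

    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(12, 3)) * 5
            fr = Frame(coords=pts)
            ga, gb = [0, 3, 5, 7], [1, 2, 8, 11]
            expected = min(np.linalg.norm(pts[i] - pts[j]) for i in ga for j in gb)
            d, _ = g.min_group_distance(fr, ga, gb)
            assert d == pytest.approx(expected, rel=1e-12)


class TestPlaneAngle:
    def test_coplanar_parallel_normals(self):
        fr = frame_of((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 0, 0), (3, 0, 0), (3, 1, 0))
        assert g.plane_angle(fr, (0, 1, 2), (3, 4, 5)) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_planes(self):
        fr = frame_of((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        assert g.plane_angle(fr, (0, 1, 2), (3, 4, 5)) == pytest.approx(90.0)

    def test_not_folded_beyond_90(self):
        # reversing one triple's order flips its normal: angle -> 180 - angle
        fr = frame_of((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 0, 0), (3, 0, 0), (3, 1, 0))
        assert g.plane_angle(fr, (2, 1, 0), (3, 4, 5)) == pytest.approx(180.0, abs=1e-9)

    def test_symmetry(self, rng):
        pts = rng.normal(size=(6, 3))
        fr = Frame(coords=pts)
        assert g.plane_angle(fr, (0, 1, 2), (3, 4, 5)) == pytest.approx(
            g.plane_angle(fr, (3, 4, 5), (0, 1, 2))
        )

    def test_collinear_triple_raises(self):
        fr = frame_of((0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 1, 0), (1, 1, 0), (1, 2, 0))
        with pytest.raises(DegenerateGeometryError):
            g.plane_angle(fr, (0, 1, 2), (3, 4, 5))

    def test_arccos_oracle(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(6, 3))
            n1 = np.cross(pts[1] - pts[0], pts[2] - pts[1])
            n2 = np.cross(pts[4] - pts[3], pts[5] - pts[4])
            if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-3:
                continue
            expected = np.degrees(
                np.arccos(
                    np.clip(
                        n1 @ n2 / np.linalg.norm(n1) / np.linalg.norm(n2), -1, 1
                    )
                )
            )
            got = g.plane_angle(Frame(coords=pts), (0, 1, 2), (3, 4, 5))
            assert got == pytest.approx(float(expected), abs=1e-9)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        fr = frame_of((1, 1, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))
        assert g.dihedral(fr, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        fr = frame_of((1, 1, 0), (1, 0, 0), (2, 0, 0), (2, -1, 0))
        assert abs(g.dihedral(fr, 0, 1, 2, 3)) == pytest.approx(180.0)

    def test_mirror_flips_sign(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            fr = Frame(coords=pts)
            try:
                d = g.dihedral(fr, 0, 1, 2, 3)
            except DegenerateGeometryError:
                continue
            mirrored = pts.copy()
            mirrored[:, 0] *= -1
            dm = g.dihedral(Frame(coords=mirrored), 0, 1, 2, 3)
            if abs(abs(d) - 180.0) > 1e-9:
                assert dm == pytest.approx(-d, abs=1e-9)

    def test_reversal_antisymmetry(self, rng):
        pts = rng.normal(size=(4, 3)) * 2
        fr = Frame(coords=pts)
        d1 = g.dihedral(fr, 0, 1, 2, 3)
        d2 = g.dihedral(fr, 3, 2, 1, 0)
        assert d2 == pytest.approx(d1, abs=1e-9)  # same value under full reversal

    def test_collinear_raises(self):
        fr = frame_of((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            g.dihedral(fr, 0, 1, 2, 3)


class TestSuperposeRmsd:
    def test_identical_frames(self, rng):
        pts = rng.normal(size=(20, 3))
        fr = Frame(coords=pts)
        res = g.superpose_rmsd(fr, fr, range(20))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(30, 3)) * 4
        fr = Frame(coords=pts)
        rot, t = random_rigid_transform(rng)
        moved = apply_rigid(fr, rot, t)
        res = g.superpose_rmsd(fr, moved, range(30))
        assert res.rmsd <= 1e-9

    def test_proper_rotation(self, rng):
        a = Frame(coords=rng.normal(size=(10, 3)))
        b = Frame(coords=rng.normal(size=(10, 3)))
        res = g.superpose_rmsd(a, b, range(10))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_single_displaced_atom_closed_form_bound(self, rng):
        # moving one atom by delta can change optimally-fitted RMSD by at
        # most delta/sqrt(n) (direct-fit upper bound), and must change it
        n = 40
        pts = rng.normal(size=(n, 3)) * 5
        moved = pts.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        res = g.superpose_rmsd(Frame(coords=pts), Frame(coords=moved), range(n))
        assert 0 < res.rmsd <= 1.0 / np.sqrt(n) + 1e-12

    def test_too_few_atoms(self):
        fr = frame_of((0, 0, 0), (1, 0, 0))
        with pytest.raises(ValueError):
            g.superpose_rmsd(fr, fr, [0, 1])


class TestRmsdSeries:
    @staticmethod
    def _static_traj(n_atoms, n_frames, sigma, rng):
        base = rng.normal(size=(n_atoms, 3)) * 8
        topo = Topology(["C"] * n_atoms, ["X"] * n_atoms, [1] * n_atoms)
        frames = [
            Frame(coords=base + rng.normal(0, sigma, base.shape), frame_id=i)
            for i in range(n_frames)
        ]
        return Trajectory(topology=topo, frames=frames)

    def test_static_trajectory_all_zero(self, rng):
        traj = self._static_traj(50, 5, 0.0, rng)
        series = g.rmsd_series(traj, range(50))
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_first_value_zero(self, rng):
        traj = self._static_traj(50, 5, 0.1, rng)
        series = g.rmsd_series(traj, range(50))
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_noise_expectation(self, rng):
        # two independently sigma-noised copies differ per atom by
        # N(0, 2 sigma^2 I3): RMSD -> sigma * sqrt(6) for large n
        sigma = 0.1
        traj = self._static_traj(500, 100, sigma, rng)
        series = g.rmsd_series(traj, range(500))
        mean_rmsd = series.values[1:].mean()
        assert mean_rmsd == pytest.approx(sigma * np.sqrt(6.0), rel=0.10)


class TestCentersAndAxes:
    def test_cube_centroids(self):
        cube = np.array(
            [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        pts = np.vstack([cube, cube + np.array([42.3, 0, 0])])
        fr = Frame(coords=pts)
        d = g.geometric_center_distance(fr, range(8), range(8, 16))
        assert d == pytest.approx(42.3)

    def test_same_set_zero(self, rng):
        fr = Frame(coords=rng.normal(size=(10, 3)))
        assert g.geometric_center_distance(fr, range(10), range(10)) == 0.0

    def test_centroid_oracle(self, rng):
        pts = rng.normal(size=(30, 3)) * 7
        fr = Frame(coords=pts)
        a, b = list(range(12)), list(range(12, 30))
        expected = np.linalg.norm(pts[a].mean(axis=0) - pts[b].mean(axis=0))
        assert g.geometric_center_distance(fr, a, b) == pytest.approx(
            float(expected), rel=1e-12
        )

    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 90.0])
    def test_rod_angles(self, angle, rng):
        n = 400
        rod = rng.normal(size=(n, 3)) * np.array([10.0, 0.5, 0.5])
        a = np.radians(angle)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        rod2 = rng.normal(size=(n, 3)) * np.array([10.0, 0.5, 0.5]) @ rot.T
        fr = Frame(coords=np.vstack([rod, rod2 + 50.0]))
        got = g.principal_axis_angle(fr, range(n), range(n, 2 * n))
        assert got == pytest.approx(angle, abs=2.0)

    def test_degenerate_axis_raises(self):
        # cube corners: exactly isotropic gyration tensor -> ambiguous axis
        cube = np.array(
            [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        fr = Frame(coords=np.vstack([cube, cube + 30.0]))
        with pytest.raises(DegenerateGeometryError):
            g.principal_axis_angle(fr, range(8), range(8, 16))

    def test_reflection_invariance(self, rng):
        n = 100
        pts = np.vstack(
            [rng.normal(size=(n, 3)) * (8, 1, 1), rng.normal(size=(n, 3)) * (1, 8, 1) + 30]
        )
        fr = Frame(coords=pts)
        mirrored = pts.copy()
        mirrored[:, 2] *= -1
        a1 = g.principal_axis_angle(fr, range(n), range(n, 2 * n))
        a2 = g.principal_axis_angle(Frame(coords=mirrored), range(n), range(n, 2 * n))
        assert a2 == pytest.approx(a1, abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_descriptors_rigid_motion_invariant(seed):
    """Distances, plane angles, dihedrals and axis angles are unchanged by
    a random global rotation + translation (relative tolerance 1e-9)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(20, 3)) * 5
    fr = Frame(coords=pts)
    rot, t = random_rigid_transform(rng)
    moved = apply_rigid(fr, rot, t)
    assert g.distance(moved, 0, 1) == pytest.approx(g.distance(fr, 0, 1), rel=1e-9)
    try:
        pa = g.plane_angle(fr, (0, 1, 2), (3, 4, 5))
        assert g.plane_angle(moved, (0, 1, 2), (3, 4, 5)) == pytest.approx(pa, abs=1e-7)
    except DegenerateGeometryError:
        pass
    try:
        dh = g.dihedral(fr, 0, 1, 2, 3)
        assert g.dihedral(moved, 0, 1, 2, 3) == pytest.approx(dh, abs=1e-7)
    except DegenerateGeometryError:
        pass
    d1, p1 = g.min_group_distance(fr, [0, 2, 4], [1, 3, 5])
    d2, p2 = g.min_group_distance(moved, [0, 2, 4], [1, 3, 5])
    assert d2 == pytest.approx(d1, rel=1e-9) and p1 == p2
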