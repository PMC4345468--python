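"""Shape analysis: ovoid tip, orientation, landmarks, GPA mean shape."""
import numpy as np
import pytest

from nucleomap.errors import DataError
from nucleomap.geometry import convex_boundary_from_points
from nucleomap.shape import (
    LandmarkSet,
    find_ovoid_tip,
    gpa_mean_shape,
    orient_nucleus,
    place_landmarks,
    procrustes_distance,
)
from nucleomap.synthetic import ShapeSpec, generate_boundary

from conftest import fibonacci_sphere


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestFindOvoidTip:
    def test_ellipsoid_axis_found_and_deterministic(self, ellipsoid_boundary):
        v1, d1 = find_ovoid_tip(ellipsoid_boundary)
        v2, d2 = find_ovoid_tip(ellipsoid_boundary)
        assert np.array_equal(v1, v2) and np.array_equal(d1, d2)
        assert abs(d1[0]) > 0.99  # major axis is x

    def test_symmetric_ellipsoid_tie_breaks_to_plus_major_axis(self):
        # mirror-symmetric surface sampling makes both ends exactly equally
        # pointed; the tie-break must pick the +major-axis end
        base = fibonacci_sphere(200) * [10.0, 7.0, 3.0]
        sym = np.vstack([base * [sx, sy, 1.0] for sx in (1, -1) for sy in (1, -1)])
        b = convex_boundary_from_points(sym)
        _, d = find_ovoid_tip(b)
        assert d[0] > 0.99

    def test_sphere_output_deterministic(self, unit_sphere_boundary):
        v1, d1 = find_ovoid_tip(unit_sphere_boundary)
        v2, d2 = find_ovoid_tip(unit_sphere_boundary)
        assert np.array_equal(v1, v2) and np.array_equal(d1, d2)
        assert np.linalg.norm(d1) == pytest.approx(1.0)

    def test_direction_is_in_plane(self, ellipsoid_boundary):
        _, d = find_ovoid_tip(ellipsoid_boundary)
        assert d[2] == 0.0

    def test_tip_recovery_on_sharpened_shapes(self):
        errs = []
        for seed in range(30):
            spec = ShapeSpec(semi_axes=(9, 6.5, 3), bump_amplitude=0.05,
                             tip_sharpening=0.25, rng_seed=seed)
            b, info = generate_boundary(spec, return_info=True)
            _, d = find_ovoid_tip(b)
            gt = info["tip_direction"][:2]
            cosang = np.clip(d[:2] @ gt / np.linalg.norm(d[:2]) / np.linalg.norm(gt), -1, 1)
            errs.append(np.degrees(np.arccos(cosang)))
        assert max(errs) < 15.0

    def test_degenerate_projection_raises(self):
        # needle along z projects to (almost) a point: collinear in xy
        pts = np.array([[0, 0, -1], [0, 0, 1], [1e-12, 1e-12, 0], [-1e-12, 1e-12, 0.5]])
        with pytest.raises(DataError):
            b = convex_boundary_from_points(pts)
            find_ovoid_tip(b)


class TestOrientNucleus:
    def test_tip_along_plus_x_gives_identity_rotation(self, ellipsoid_boundary):
        oriented, tf = orient_nucleus(ellipsoid_boundary, np.array([1.0, 0, 0]))
        assert tf["rotation"] == pytest.approx(np.eye(3))
        assert oriented.centroid == pytest.approx(np.zeros(3), abs=1e-9)

    def test_tip_along_plus_y_rotates_minus_90_about_z(self, ellipsoid_boundary):
        oriented, tf = orient_nucleus(ellipsoid_boundary, np.array([0.0, 1.0, 0]))
        expected = _rot_z(-np.pi / 2)
        assert tf["rotation"] == pytest.approx(expected, abs=1e-12)
        # vertex sets agree after applying the known rotation
        manual = (ellipsoid_boundary.vertices - ellipsoid_boundary.centroid) @ expected.T
        assert np.allclose(np.sort(manual, axis=0), np.sort(oriented.vertices, axis=0), atol=1e-9)

    def test_orientation_invariant_to_prior_z_rotation(self, ellipsoid_boundary):
        rot = _rot_z(1.234)
        moved = ellipsoid_boundary.transformed(rot, np.array([5.0, -3.0, 1.0]))
        o1, _ = orient_nucleus(ellipsoid_boundary, np.array([1.0, 0, 0]))
        o2, _ = orient_nucleus(moved, rot @ np.array([1.0, 0, 0]))
        assert np.allclose(np.sort(o1.vertices, axis=0), np.sort(o2.vertices, axis=0), atol=1e-9)

    def test_rotation_is_proper_and_z_preserving(self, ellipsoid_boundary):
        _, tf = orient_nucleus(ellipsoid_boundary, np.array([0.3, -0.7, 0.0]))
        r = tf["rotation"]
        assert np.linalg.det(r) == pytest.approx(1.0)
        assert r[2] == pytest.approx([0, 0, 1.0])

    def test_zero_direction_raises(self, ellipsoid_boundary):
        with pytest.raises(DataError):
            orient_nucleus(ellipsoid_boundary, np.array([0.0, 0.0, 1.0]))


class TestPlaceLandmarks:
    def test_unit_sphere_single_ring_closed_form(self, unit_sphere_boundary):
        ls = place_landmarks(unit_sphere_boundary, n_rings=1, n_per_ring=4)
        lm = ls.landmarks
        assert len(ls) == 6
        # poles along +-x at (approximately) unit radius
        assert lm[0] == pytest.approx([1, 0, 0], abs=0.01)
        assert lm[-1] == pytest.approx([-1, 0, 0], abs=0.01)
        ring = lm[1:5]
        assert np.abs(ring[:, 0]).max() < 0.01  # equatorial plane x=0
        radii = np.linalg.norm(ring, axis=1)
        assert radii == pytest.approx(np.ones(4), abs=0.01)
        # consecutive azimuthal spacing of 90 degrees (modulo wraparound)
        angles = np.degrees(np.arctan2(-ring[:, 1], ring[:, 2]))
        gaps = np.abs(np.diff(angles)) % 360
        gaps = np.minimum(gaps, 360 - gaps)
        assert np.allclose(gaps, 90, atol=1.0)

    def test_landmarks_satisfy_ellipsoid_equation(self):
        pts = fibonacci_sphere(2000) * [10.0, 7.0, 3.0]
        b = convex_boundary_from_points(pts)
        ls = place_landmarks(b, n_rings=5, n_per_ring=8)
        q = (ls.landmarks / [10, 7, 3]) ** 2
        # landmarks lie on the (finely faceted) ellipsoid surface
        assert q.sum(axis=1) == pytest.approx(np.ones(len(ls)), abs=5e-3)

    def test_pipeline_invariance_under_z_rotation(self):
        spec = ShapeSpec(semi_axes=(9, 6, 3), bump_amplitude=0.04, tip_sharpening=0.25, rng_seed=3)
        b, _ = generate_boundary(spec, return_info=True)

        def oriented_landmarks(boundary):
            _, tip = find_ovoid_tip(boundary)
            ob, _ = orient_nucleus(boundary, tip)
            return place_landmarks(ob, n_rings=4, n_per_ring=8).landmarks

        base = oriented_landmarks(b)
        rotated = b.transformed(_rot_z(0.77), np.array([2.0, -1.0, 0.0]))
        again = oriented_landmarks(rotated)
        assert np.allclose(base, again, atol=1e-6)

    def test_landmark_count_and_ordering_contract(self, ellipsoid_boundary):
        ls = place_landmarks(ellipsoid_boundary, n_rings=3, n_per_ring=5)
        assert len(ls) == 2 + 3 * 5
        # tip pole has the largest x, anti-pole the smallest
        assert ls.landmarks[0, 0] == ls.landmarks[:, 0].max()
        assert ls.landmarks[-1, 0] == ls.landmarks[:, 0].min()


class TestGPA:
    def _landmarks(self, seed=0, n_rings=4, n_per_ring=8):
        spec = ShapeSpec(semi_axes=(9, 6, 3), bump_amplitude=0.04, tip_sharpening=0.25, rng_seed=seed)
        b = generate_boundary(spec)
        _, tip = find_ovoid_tip(b)
        ob, _ = orient_nucleus(b, tip)
        return place_landmarks(ob, n_rings=n_rings, n_per_ring=n_per_ring, replicate_id=f"r{seed}")

    def _similarity_copies(self, base, n, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            ang = rng.uniform(0, 2 * np.pi)
            s = rng.uniform(0.5, 2.0)
            t = rng.uniform(-5, 5, 3)
            lm = s * base.landmarks @ _rot_z(ang).T + t
            out.append(LandmarkSet(lm, replicate_id=f"c{i}", n_rings=base.n_rings,
                                   n_per_ring=base.n_per_ring))
        return out

    def test_exact_recovery_from_similarity_copies(self):
        base = self._landmarks(0)
        copies = self._similarity_copies(base, 6)
        mean, aligned = gpa_mean_shape(copies, tol=1e-12)
        assert procrustes_distance(mean.mean_landmarks, base.landmarks) < 1e-8
        assert mean.converged

    def test_mean_shape_invariants(self):
        sets = [self._landmarks(s) for s in range(5)]
        mean, _ = gpa_mean_shape(sets)
        assert np.linalg.norm(mean.mean_landmarks.mean(axis=0)) < 1e-9
        assert np.linalg.norm(mean.mean_landmarks) == pytest.approx(1.0, abs=1e-9)

    def test_objective_monotone_non_increasing(self):
        sets = [self._landmarks(s) for s in range(6)]
        mean, _ = gpa_mean_shape(sets)
        hist = mean.objective_history
        assert np.all(np.diff(hist) <= 1e-12)

    def test_two_shape_mean_is_equidistant(self):
        a, b = self._landmarks(1), self._landmarks(2)
        mean, _ = gpa_mean_shape([a, b], tol=1e-14, max_iter=2000)
        da = procrustes_distance(a.landmarks, mean.mean_landmarks)
        db = procrustes_distance(b.landmarks, mean.mean_landmarks)
        assert abs(da - db) < 1e-8

    def test_order_invariance_of_mean(self):
        sets = [self._landmarks(s) for s in range(5)]
        m1, _ = gpa_mean_shape(sets, tol=1e-12)
        m2, _ = gpa_mean_shape(sets[::-1], tol=1e-12)
        assert procrustes_distance(m1.mean_landmarks, m2.mean_landmarks) < 1e-6

    def test_rotations_are_proper(self):
        # all aligned sets relate to their originals by proper similarity
        sets = [self._landmarks(s) for s in range(4)]
        mean, aligned = gpa_mean_shape(sets)
        for orig, al in zip(sets, aligned):
            x = orig.landmarks - orig.landmarks.mean(axis=0)
            y = al.landmarks - al.landmarks.mean(axis=0)
            u, _, vt = np.linalg.svd(x.T @ y)
            assert np.linalg.det(u @ vt) > 0

    def test_mean_of_jittered_ellipsoids_recovers_population_shape(self):
        # semi-axes jittered i.i.d.; the mean hull's axis RATIOS should match
        # the population mean ratios (GPA normalizes size) within 5%
        rng = np.random.default_rng(42)
        sets = []
        for i in range(50):
            axes = np.array([9.0, 6.0, 3.0]) * (1 + rng.normal(0, 0.06, 3))
            axes = np.sort(axes)[::-1]
            pts = fibonacci_sphere(600) * axes
            b = convex_boundary_from_points(pts)
            sets.append(place_landmarks(b, n_rings=4, n_per_ring=8, replicate_id=f"e{i}"))
        mean, _ = gpa_mean_shape(sets)
        lm = mean.mean_landmarks
        half_extents = (lm.max(axis=0) - lm.min(axis=0)) / 2
        ratios = half_extents / half_extents[0]
        assert ratios[1] == pytest.approx(6.0 / 9.0, rel=0.05)
        assert ratios[2] == pytest.approx(3.0 / 9.0, rel=0.05)

    def test_length_mismatch_raises(self):
        a = self._landmarks(0, n_rings=4)
        b = self._landmarks(1, n_rings=5)
        with pytest.raises(DataError):
            gpa_mean_shape([a, b])

    def test_fewer_than_two_sets_raise(self):
        with pytest.raises(DataError):
            gpa_mean_shape([self._landmarks(0)])
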