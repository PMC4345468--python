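"""CSR testing: excess maps, cluster enhancement, null simulation, FWE."""
import numpy as np
import pytest

from nucleomap.errors import ConfigurationError, DataError
from nucleomap.inference import (
    cluster_enhance,
    csr_test,
    excess_map,
    significance_maps,
    simulate_null,
)
from nucleomap.intensity import IntensityMap, VoxelGrid, estimate_intensity, voxelize
from nucleomap.pipeline import prepare_replicates, run_study
from nucleomap.registration import build_aggregate_map
from nucleomap.shape import gpa_mean_shape
from nucleomap.synthetic import PatternSpec, generate_cohort


def _grid(n=6, voxel=1.0):
    return VoxelGrid(
        origin=np.zeros(3),
        voxel_size=voxel,
        dims=(n, n, n),
        interior_mask=np.ones((n, n, n), dtype=bool),
    )


def _imap(values, grid, lam0):
    return IntensityMap(grid=grid, values=values, csr_level=lam0)


@pytest.fixture(scope="module")
def cohort_study(small_cohort):
    frames = prepare_replicates(
        [m.boundary for m in small_cohort], [m.pattern for m in small_cohort]
    )
    mean, _ = gpa_mean_shape([f.landmarks for f in frames])
    am = build_aggregate_map([(f.landmarks, f.pattern) for f in frames], mean)
    grid = voxelize(mean, 8_000)
    boundaries = {f.landmarks.replicate_id: f.boundary for f in frames}
    return am, grid, boundaries


class TestExcessMap:
    def test_uniform_map_at_csr_level_is_zero_both_ways(self):
        g = _grid()
        im = _imap(np.full(g.dims, 2.0), g, 2.0)
        assert not excess_map(im, "aggregated").any()
        assert not excess_map(im, "dispersed").any()

    def test_single_hot_voxel_arithmetic(self):
        g = _grid()
        vals = np.full(g.dims, 1.5)
        vals[2, 3, 4] = 3.0
        im = _imap(vals, g, 1.5)
        agg = excess_map(im, "aggregated")
        assert agg[2, 3, 4] == pytest.approx(1.5)
        assert (agg > 0).sum() == 1

    def test_directions_never_both_positive(self):
        rng = np.random.default_rng(0)
        g = _grid(8)
        for _ in range(10):
            im = _imap(rng.exponential(1.0, g.dims), g, 1.0)
            agg = excess_map(im, "aggregated")
            disp = excess_map(im, "dispersed")
            assert not np.any((agg > 0) & (disp > 0))

    def test_zero_outside_interior(self):
        g = _grid()
        g.interior_mask[:] = False
        g.interior_mask[2:4, 2:4, 2:4] = True
        im = _imap(np.full(g.dims, 9.0), g, 1.0)
        agg = excess_map(im, "aggregated")
        assert not agg[~g.interior_mask].any()

    def test_bad_direction_rejected(self):
        g = _grid()
        with pytest.raises(ConfigurationError):
            excess_map(_imap(np.zeros(g.dims), g, 0.0), "sideways")


class TestClusterEnhance:
    def test_single_voxel_cluster_size(self):
        g = _grid(5, voxel=0.5)
        exc = np.zeros(g.dims)
        exc[1, 1, 1] = 3.0
        em = cluster_enhance(exc, g, mode="cluster_size")
        assert em.statistic[1, 1, 1] == pytest.approx(0.5**3)
        assert (em.statistic > 0).sum() == 1

    def test_face_vs_corner_connectivity(self):
        g = _grid(5)
        exc = np.zeros(g.dims)
        exc[1, 1, 1] = exc[1, 1, 2] = 1.0  # share a face
        em = cluster_enhance(exc, g, connectivity=6, mode="cluster_size")
        assert em.statistic[1, 1, 1] == em.statistic[1, 1, 2] == 2.0
        exc2 = np.zeros(g.dims)
        exc2[1, 1, 1] = exc2[2, 2, 2] = 1.0  # share only a corner
        em6 = cluster_enhance(exc2, g, connectivity=6, mode="cluster_size")
        em26 = cluster_enhance(exc2, g, connectivity=26, mode="cluster_size")
        assert em6.statistic[1, 1, 1] == 1.0
        assert em26.statistic[1, 1, 1] == 2.0

    def test_cluster_mass_integrates_excess(self):
        g = _grid(5, voxel=2.0)
        exc = np.zeros(g.dims)
        exc[1, 1, 1], exc[1, 1, 2] = 0.5, 1.5
        em = cluster_enhance(exc, g, mode="cluster_mass")
        assert em.statistic[1, 1, 1] == pytest.approx((0.5 + 1.5) * 8.0)
        assert em.statistic[1, 1, 2] == pytest.approx(16.0)

    def test_statistic_constant_within_component(self):
        rng = np.random.default_rng(1)
        g = _grid(8)
        exc = np.where(rng.random(g.dims) > 0.6, rng.exponential(1, g.dims), 0.0)
        for mode in ("cluster_size", "cluster_mass"):
            em = cluster_enhance(exc, g, mode=mode)
            from scipy import ndimage

            labels, n = ndimage.label(exc > 0, ndimage.generate_binary_structure(3, 1))
            for lbl in range(1, n + 1):
                vals = em.statistic[labels == lbl]
                assert np.allclose(vals, vals[0])
            assert not em.statistic[exc == 0].any()

    def test_tfce_flat_profile_closed_form(self):
        # flat-top excess: with E=1, H=0 the TFCE integral is volume x height
        g = _grid(6, voxel=1.0)
        exc = np.zeros(g.dims)
        exc[2:4, 2:4, 2:4] = 2.0  # 8 voxels at height 2
        em = cluster_enhance(exc, g, mode="tfce", tfce_E=1.0, tfce_H=0.0, tfce_dh=0.1)
        assert em.statistic[2, 2, 2] == pytest.approx(8.0 * 2.0, rel=0.02)

    def test_negative_excess_rejected(self):
        g = _grid()
        with pytest.raises(DataError):
            cluster_enhance(np.full(g.dims, -1.0), g)

    def test_invalid_connectivity_rejected(self):
        g = _grid()
        with pytest.raises(ConfigurationError):
            cluster_enhance(np.zeros(g.dims), g, connectivity=8)


class TestSimulateNull:
    def test_zero_iterations_rejected(self, cohort_study):
        am, grid, boundaries = cohort_study
        with pytest.raises(ConfigurationError):
            simulate_null(am, boundaries, am.mean_shape, grid, M=0)

    def test_fixed_seed_reproducible(self, cohort_study):
        am, grid, boundaries = cohort_study
        a = simulate_null(am, boundaries, am.mean_shape, grid, M=13, seed=5)
        b = simulate_null(am, boundaries, am.mean_shape, grid, M=13, seed=5)
        for d in ("aggregated", "dispersed"):
            assert np.array_equal(a[d], b[d])

    def test_different_seeds_differ(self, cohort_study):
        am, grid, boundaries = cohort_study
        a = simulate_null(am, boundaries, am.mean_shape, grid, M=13, seed=5)
        b = simulate_null(am, boundaries, am.mean_shape, grid, M=13, seed=6)
        assert not np.array_equal(a["aggregated"], b["aggregated"])

    def test_missing_boundaries_raise(self, cohort_study):
        am, grid, boundaries = cohort_study
        partial = dict(list(boundaries.items())[:-1])
        with pytest.raises(DataError):
            simulate_null(am, partial, am.mean_shape, grid, M=3)

    def test_null_statistics_are_positive_for_nonempty_patterns(self, cohort_study):
        am, grid, boundaries = cohort_study
        null = simulate_null(am, boundaries, am.mean_shape, grid, M=19, seed=1)
        assert np.all(null["aggregated"] > 0)
        assert np.all(null["dispersed"] > 0)


class TestSignificanceMaps:
    def _enhanced_pair(self, grid, agg_exc, disp_exc):
        return [
            cluster_enhance(agg_exc, grid, direction="aggregated"),
            cluster_enhance(disp_exc, grid, direction="dispersed"),
        ]

    def test_zero_statistic_never_rejects(self):
        g = _grid()
        observed = self._enhanced_pair(g, np.zeros(g.dims), np.zeros(g.dims))
        null = {"aggregated": np.random.default_rng(0).random(199),
                "dispersed": np.random.default_rng(1).random(199)}
        sig = significance_maps(observed, null, alpha=0.05)
        assert not sig.reject_aggregated.any()
        assert not sig.reject_dispersed.any()

    def test_observed_far_above_null_rejects_argmax(self):
        g = _grid()
        exc = np.zeros(g.dims)
        exc[3, 3, 3] = 100.0
        observed = self._enhanced_pair(g, exc, np.zeros(g.dims))
        null = {"aggregated": np.full(199, 1e-6), "dispersed": np.full(199, 1e-6)}
        sig = significance_maps(observed, null, alpha=0.05)
        assert sig.reject_aggregated[3, 3, 3]

    def test_rejection_monotone_in_statistic(self):
        rng = np.random.default_rng(2)
        g = _grid(8)
        exc = np.where(rng.random(g.dims) > 0.5, rng.exponential(1, g.dims), 0)
        observed = self._enhanced_pair(g, exc, np.zeros(g.dims))
        null = {"aggregated": rng.exponential(2, 199), "dispersed": rng.exponential(2, 199)}
        sig = significance_maps(observed, null, alpha=0.2)
        stat = sig.statistic_aggregated
        if sig.reject_aggregated.any():
            thr = stat[sig.reject_aggregated].min()
            assert np.all(sig.reject_aggregated[stat >= thr] | ~g.interior_mask[stat >= thr])

    def test_p_values_never_zero(self):
        g = _grid()
        exc = np.zeros(g.dims)
        exc[0, 0, 0] = 5.0
        observed = self._enhanced_pair(g, exc, np.zeros(g.dims))
        null = {"aggregated": np.zeros(199), "dispersed": np.zeros(199)}
        sig = significance_maps(observed, null, alpha=0.05)
        assert sig.p_aggregated.min() >= 1.0 / 200.0

    def test_insufficient_null_samples_rejected(self):
        g = _grid()
        observed = self._enhanced_pair(g, np.zeros(g.dims), np.zeros(g.dims))
        null = {"aggregated": np.zeros(10), "dispersed": np.zeros(10)}
        with pytest.raises(ConfigurationError):
            significance_maps(observed, null, alpha=0.05)

    def test_invalid_alpha_rejected(self):
        g = _grid()
        observed = self._enhanced_pair(g, np.zeros(g.dims), np.zeros(g.dims))
        null = {"aggregated": np.zeros(199), "dispersed": np.zeros(199)}
        with pytest.raises(ConfigurationError):
            significance_maps(observed, null, alpha=0.7)


class TestEndToEnd:
    def test_csr_test_runs_and_is_reproducible(self, cohort_study):
        am, grid, boundaries = cohort_study
        s1 = csr_test(am, boundaries, grid, M=39, alpha=0.05, seed=3)
        s2 = csr_test(am, boundaries, grid, M=39, alpha=0.05, seed=3)
        assert np.array_equal(s1.reject_aggregated, s2.reject_aggregated)
        assert np.array_equal(
            s1.null_max_statistics["dispersed"], s2.null_max_statistics["dispersed"]
        )

    def test_rejections_only_at_interior_voxels(self, cohort_study):
        am, grid, boundaries = cohort_study
        sig = csr_test(am, boundaries, grid, M=39, alpha=0.2, seed=4)
        assert not sig.reject_aggregated[~grid.interior_mask].any()
        assert not sig.reject_dispersed[~grid.interior_mask].any()

    def test_strong_central_cohort_rejects_centrally(self):
        cohort = generate_cohort(
            15, PatternSpec(model="central", n_points=12), seed=77, render=False
        )
        res = run_study(
            [m.boundary for m in cohort], [m.pattern for m in cohort],
            grid_axis=20, M=99, alpha=0.05, seed=8,
        )
        sig = res.significance
        assert sig.reject_aggregated.any()
        vox = res.grid.centres(sig.reject_aggregated)
        hull_rad = np.linalg.norm(res.mean.mean_landmarks, axis=1).mean()
        dist = np.linalg.norm(vox.mean(axis=0) - res.mean.mean_hull.centroid)
        assert dist < 0.3 * hull_rad
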