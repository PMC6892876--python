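"""Confocal profile extraction: oracles, closed forms and parameter recovery."""

import math

import numpy as np
import pytest

from habrush import profiles as prof
from habrush import synthetic as syn
from habrush.errors import DegenerateHistogramError, ProfileError
from habrush.geometry import VoxelGeometry

from helpers import naive_cone_bins, naive_otsu

SEED = 0


def make_profile(r_nm, intensity, counts=None):
    counts = np.ones_like(np.asarray(r_nm)) if counts is None else counts
    return prof.RadialProfile(r_nm=r_nm, intensity=intensity, counts=counts)


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        vals = np.array([0.0] * 60 + [100.0] * 40)
        t = prof.otsu_threshold(vals)
        assert 0.0 < t < 100.0

    def test_matches_exhaustive_search_oracle(self, rng):
        vals = rng.integers(0, 256, size=5000).astype(float)
        t_impl = prof.otsu_threshold(vals)
        t_naive = naive_otsu(vals)
        # both must induce the same partition of the data
        assert np.array_equal(vals > t_impl, vals > t_naive)

    def test_disk_mask_area_close_to_truth(self, rng):
        yy, xx = np.mgrid[:128, :128]
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 30**2
        img = np.where(disk, 100.0, 5.0) + rng.normal(0, 2.0, disk.shape)
        t = prof.otsu_threshold(img)
        assert (img > t).sum() == pytest.approx(disk.sum(), rel=0.05)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            prof.otsu_threshold(np.full(100, 7.0))


class TestConeProfile:
    def test_matches_per_voxel_brute_force(self):
        geom = VoxelGeometry(dx=80, dy=100, dz=400)
        rng = np.random.default_rng(SEED)
        img = rng.normal(10, 3, size=(9, 13, 15))
        center = (4 * 400.0, 6 * 100.0, 7 * 80.0)
        for axis in [(0, 0, 1), (0, 1, 0), (0, 0.6, 0.8), (0.5, 0.5, 0.707)]:
            p = prof.cone_profile(
                img, geom, center, axis, aperture_deg=40, bin_width_nm=120, r_max_nm=500
            )
            sums, counts = naive_cone_bins(img, geom, center, axis, 40, 120, 500)
            n = min(p.counts.size, counts.size)
            assert np.array_equal(p.counts[:n], counts[:n])
            got = np.where(p.counts[:n] > 0, p.intensity[:n] * p.counts[:n], 0.0)
            assert np.allclose(got, sums[:n])

    def test_axis_symmetry_on_isotropic_field(self):
        geom = VoxelGeometry(dx=100, dy=100, dz=100)
        z, y, x = np.indices((41, 41, 41)).astype(float) * 100.0
        r = np.sqrt((z - 2000) ** 2 + (y - 2000) ** 2 + (x - 2000) ** 2)
        img = np.exp(-r / 800.0)
        p1 = prof.cone_profile(img, geom, (2000, 2000, 2000), (0, 0, 1))
        p2 = prof.cone_profile(img, geom, (2000, 2000, 2000), (0, -1, 0))
        n = min(p1.r_nm.size, p2.r_nm.size)
        m = (p1.counts[:n] > 0) & (p2.counts[:n] > 0) & (p1.r_nm[:n] > 300)
        assert np.allclose(p1.intensity[:n][m], p2.intensity[:n][m], rtol=0.05, atol=0.01)

    def test_truncation_flag_when_cone_exits_early(self):
        geom = VoxelGeometry(dx=100, dy=100, dz=100)
        img = np.zeros((11, 11, 11))
        p = prof.cone_profile(img, geom, (500, 500, 500), (0, 0, 1), r_max_nm=5000)
        assert p.truncated

    def test_zero_axis_rejected(self):
        geom = VoxelGeometry(dx=100, dy=100, dz=100)
        with pytest.raises(ProfileError):
            prof.cone_profile(np.zeros((5, 5, 5)), geom, (200, 200, 200), (0, 0, 0))


class TestBackgroundStats:
    def test_constant_tail(self):
        p = make_profile(np.arange(1, 101) * 10.0, np.full(100, 3.5))
        bg = prof.background_stats(p, n_tail=50)
        assert bg.mean == 3.5 and bg.sd == 0.0

    def test_matches_direct_computation_on_gaussian_tail(self, rng):
        intensity = np.concatenate([np.full(30, 50.0), rng.normal(2.0, 0.5, 60)])
        p = make_profile(np.arange(1, 91) * 10.0, intensity)
        bg = prof.background_stats(p, n_tail=50)
        tail = intensity[-50:]
        assert bg.mean == pytest.approx(tail.mean())
        assert bg.sd == pytest.approx(tail.std(ddof=1))

    def test_short_profile_is_an_error_not_a_silent_shrink(self):
        p = make_profile(np.arange(1, 50) * 10.0, np.zeros(49))
        with pytest.raises(ProfileError):
            prof.background_stats(p, n_tail=50)


class TestEdgeDetection:
    def test_closed_form_exponential_crossing(self):
        """Noiseless I0 exp(-r/lambda) with bg (0, 1) crosses 2 sigma at lambda ln 50."""
        r = np.arange(0.5, 400) * 20.0  # 20 nm bins out to 8 um
        intensity = 100.0 * np.exp(-r / 1000.0)
        p = make_profile(r, intensity)
        bg = prof.BackgroundStats(mean=0.0, sd=1.0, n_tail=50)
        edge = prof.detect_brush_edge(p, bg)
        assert edge.found
        assert edge.r_nm == pytest.approx(1000.0 * math.log(50.0), abs=20.0)

    def test_all_background_profile_has_no_crossing(self):
        p = make_profile(np.arange(1, 101) * 10.0, np.full(100, 1.0))
        edge = prof.detect_brush_edge(p, prof.BackgroundStats(1.0, 0.5, 50))
        assert not edge.found and edge.flag == "no-crossing"

    def test_step_profile_edge_within_one_bin(self):
        r = np.arange(0.5, 100) * 10.0
        intensity = np.where(r <= 500.0, 80.0, 0.0)
        p = make_profile(r, intensity)
        edge = prof.detect_brush_edge(p, prof.BackgroundStats(0.0, 1.0, 50))
        assert edge.found and abs(edge.r_nm - 500.0) <= 10.0

    def test_edge_monotone_in_brush_height(self):
        r = np.arange(0.5, 300) * 10.0
        bg = prof.BackgroundStats(0.0, 1.0, 50)
        edges = []
        for h in (500.0, 1000.0, 1500.0):
            intensity = np.where(r <= h, 50.0 * np.exp(-r / 2000.0), 0.0)
            edges.append(prof.detect_brush_edge(make_profile(r, intensity), bg).r_nm)
        assert edges[0] < edges[1] < edges[2]


class TestSurfaceDetection:
    def test_shell_peak_recovered_within_one_bin(self):
        r = np.arange(0.5, 120) * 50.0
        intensity = 100.0 * np.exp(-((r - 4000.0) ** 2) / (2 * 150.0**2))
        res = prof.detect_surface(make_profile(r, intensity))
        assert res.method == "peak"
        assert res.r_nm == pytest.approx(4000.0, abs=50.0)

    def test_flat_profile_falls_back_to_nominal_radius(self):
        res = prof.detect_surface(
            make_profile(np.arange(1, 50) * 10.0, np.ones(49)), nominal_radius_nm=4000.0
        )
        assert res.method == "nominal" and res.flag == "no-interior-peak"

    def test_boundary_peak_rejected_as_non_interior(self):
        r = np.arange(1, 50) * 10.0
        res = prof.detect_surface(make_profile(r, r.copy()), nominal_radius_nm=1234.0)
        assert res.method == "nominal"
        with pytest.raises(ProfileError):
            prof.detect_surface(make_profile(r, r.copy()))


class TestSegmentation:
    def test_single_sphere_centroid_within_a_voxel(self):
        stack, truth = syn.spherical_scene(
            height_nm=1000, decay_nm=400, radius_nm=1500, snr=50, seed=SEED, n_tail=10
        )
        dets = prof.segment_sphere_centers(stack)
        assert len(dets) == 1
        err = np.abs(np.array(dets[0].center_nm) - np.array(truth.center_nm))
        assert np.all(err <= stack.geom.spacing_zyx_nm)

    def test_empty_stack_yields_no_detections(self, rng):
        from habrush.geometry import ImageStack

        geom = VoxelGeometry(dx=100, dy=100, dz=200)
        stack = ImageStack(
            rng.normal(10, 2, size=(1, 10, 64, 64)).astype(np.float32), geom, ("surface",)
        )
        assert prof.segment_sphere_centers(stack) == []

    def test_two_spheres_distance_preserved(self):
        geom = VoxelGeometry(dx=100, dy=100, dz=100)
        mk = lambda cx: syn.SphericalBrushTruth(
            center_nm=(6000, 6000, cx), radius_nm=1200, height_nm=600, decay_nm=200,
            bg_sd=1.0,
        )
        stack, _ = syn.generate_spherical_brush_stack(
            [mk(4000), mk(9000)], geom, (121, 121, 131), SEED
        )
        dets = prof.segment_sphere_centers(stack, min_voxels=200)
        assert len(dets) == 2
        d = np.linalg.norm(np.array(dets[0].center_nm) - np.array(dets[1].center_nm))
        assert d == pytest.approx(5000.0, abs=100.0)


class TestSphericalHeightPipeline:
    def test_near_noiseless_recovery_within_one_bin(self):
        stack, truth = syn.spherical_scene(
            height_nm=2000, decay_nm=5000, radius_nm=2000, snr=1e5, seed=SEED, n_tail=50
        )
        rep = prof.spherical_brush_height(stack)
        assert rep.n_spheres == 1
        assert rep.mean_nm == pytest.approx(truth.height_nm, abs=2 * stack.geom.dx)

    def test_zero_height_brush_reads_near_zero_or_flagged(self):
        stack, _ = syn.spherical_scene(
            height_nm=0.0, decay_nm=500, radius_nm=2000, snr=20, seed=SEED, n_tail=50
        )
        rep = prof.spherical_brush_height(stack)
        for r in rep.per_sphere:
            assert (not r.valid) or r.height_nm < 3 * stack.geom.dx

    def test_facing_cones_of_adjacent_spheres_are_flagged(self):
        geom = VoxelGeometry(dx=100, dy=100, dz=300)
        mk = lambda cx: syn.SphericalBrushTruth(
            center_nm=(6000, 12000, cx), radius_nm=1500, height_nm=800, decay_nm=300,
            bg_sd=2.0,
        )
        stack, _ = syn.generate_spherical_brush_stack(
            [mk(8000), mk(16000)], geom, (41, 241, 241), SEED
        )
        cfg = prof.SphereAnalysisConfig(h_max_nm=1500.0, n_tail=20)
        rep = prof.spherical_brush_height(stack, cfg)
        assert any("cone-overlap" in r.flags for r in rep.per_sphere)


class TestPlanarHeights:
    def test_exclusion_height_recovers_truth_within_two_voxels(self):
        stack, truth = syn.planar_scene(seed=SEED)
        res = prof.planar_exclusion_height(stack)
        assert res.valid
        assert res.height_nm == pytest.approx(truth.height_nm, abs=2 * stack.geom.dz)

    def test_uniform_particle_channel_reads_zero_height(self):
        stack, _ = syn.planar_scene(height_nm=0.0, seed=SEED)
        res = prof.planar_exclusion_height(stack)
        assert res.height_nm == 0.0

    def test_gfpn_and_exclusion_heights_agree(self):
        stack, truth = syn.planar_scene(seed=SEED)
        excl = prof.planar_exclusion_height(stack)
        gfpn = prof.planar_edge_height(stack)
        assert excl.valid and gfpn.valid
        assert abs(excl.height_nm - gfpn.height_nm) < 300.0  # combined tolerance


class TestExponentialFit:
    def _sphere_profile(self, bg_sd, seed=SEED):
        rng = np.random.default_rng(seed)
        r = np.arange(0.5, 200) * 50.0
        surface = 2000.0
        intensity = np.where(
            (r >= surface) & (r <= surface + 4500.0),
            100.0 * np.exp(-(r - surface) / 1500.0),
            0.0,
        ) + rng.normal(0.0, bg_sd, r.size)
        return make_profile(r, intensity), surface

    def test_noiseless_parameters_within_one_percent(self):
        p, surface = self._sphere_profile(0.0)
        fit = prof.fit_exponential_profile(p, surface, edge_nm=surface + 4000.0)
        assert fit.converged
        assert fit.i0 == pytest.approx(100.0, rel=0.01)
        assert fit.decay_nm == pytest.approx(1500.0, rel=0.01)

    def test_pure_background_rejected(self, rng):
        p = make_profile(np.arange(0.5, 100) * 50.0, rng.normal(0, 1.0, 100))
        fit = prof.fit_exponential_profile(
            p, 500.0, bg_stats=prof.BackgroundStats(0.0, 1.0, 50)
        )
        assert not fit.converged and fit.flag == "pure-background"

    def test_decay_recovery_unbiased_over_seeds(self):
        estimates = []
        for seed in range(50):
            p, surface = self._sphere_profile(2.0, seed=seed)
            fit = prof.fit_exponential_profile(p, surface, edge_nm=surface + 4000.0)
            if fit.converged:
                estimates.append(fit.decay_nm)
        assert len(estimates) >= 45
        rel_bias = (np.mean(estimates) - 1500.0) / 1500.0
        assert abs(rel_bias) < 0.05
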