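"""Synthetic scene generator: determinism, spacing, rendering, hierarchy."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import cryptmorph as cm
from cryptmorph.scenes import InfeasibleDensityError


def brute_force_polygon_distance(va, vb):
    """Min distance between two polygons by exhaustive segment pairs."""

    def seg_dist(p1, p2, q1, q2):
        # sample segments densely; lower bound is fine at this resolution
        ts = np.linspace(0, 1, 20)[:, None]
        a = p1 + ts * (p2 - p1)
        b = q1 + ts * (q2 - q1)
        return np.min(np.hypot(*(a[:, None, :] - b[None, :, :]).T))

    best = np.inf
    for i in range(len(va)):
        p1, p2 = va[i], va[(i + 1) % len(va)]
        for j in range(len(vb)):
            q1, q2 = vb[j], vb[(j + 1) % len(vb)]
            best = min(best, seg_dist(p1, p2, q1, q2))
    return best


class TestLayout:
    def test_zero_crypts_gives_empty_layout(self):
        params = cm.preset("tumor", seed=1)
        assert params.crypt_count == 0
        assert len(cm.sample_crypt_layout(params)) == 0

    def test_tumor_preset_rejects_nonzero_count(self):
        with pytest.raises(ValueError, match="tumor"):
            cm.SceneParams(phenotype="tumor", crypt_count=3)

    def test_same_seed_identical_layout(self, small_params):
        l1 = cm.sample_crypt_layout(small_params)
        l2 = cm.sample_crypt_layout(small_params)
        assert len(l1) == len(l2)
        for g1, g2 in zip(l1, l2):
            assert g1 == g2

    def test_pairwise_edge_spacing_brute_force(self):
        """Every placed pair keeps the requested edge-to-edge distance."""
        spacing = 6.0
        params = cm.SceneParams(
            field_size_px=512,
            crypt_count=50,
            lumen_radius_um=(10.0, 2.0),
            min_edge_spacing_um=spacing,
            noise_sigma=0.0,
            seed=23,
        )
        layout = cm.sample_crypt_layout(params)
        assert len(layout) >= 40  # dense but feasible
        polys = [g.boundary_polygon() for g in layout]
        shapely_polys = [Polygon(v) for v in polys]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                d = shapely_polys[i].distance(shapely_polys[j])
                assert d >= spacing - 1e-9
        # cross-check a few pairs against the exhaustive segment oracle
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            d_ref = brute_force_polygon_distance(polys[i], polys[j])
            assert d_ref >= spacing - 0.05

    def test_infeasible_density_raises_before_sampling(self):
        params = cm.SceneParams(
            field_size_px=64, crypt_count=500, lumen_radius_um=(20.0, 0.0),
            noise_sigma=0.0,
        )
        with pytest.raises(InfeasibleDensityError):
            cm.sample_crypt_layout(params)

    def test_shortfall_recorded_when_field_fills_up(self):
        params = cm.SceneParams(
            field_size_px=128,
            crypt_count=29,
            lumen_radius_um=(12.0, 0.5),
            aspect_ratio=(1.0, 0.0),
            min_edge_spacing_um=3.0,
            noise_sigma=0.0,
            seed=4,
        )
        layout = cm.sample_crypt_layout(params, max_tries_per_crypt=30)
        assert len(layout) + layout.shortfall == params.crypt_count
        assert layout.shortfall > 0


class TestRender:
    def test_empty_layout_constant_background(self):
        params = cm.preset("tumor", seed=1, noise_sigma=0.0)
        scene = cm.generate_scene(params)
        assert np.all(scene.image.pixels == params.background_intensity)
        assert scene.truth.label_mask.max() == 0

    def test_single_disk_pixel_count_matches_area(self):
        """Rasterized lumen pixel count approximates pi r^2 / pitch^2."""
        from conftest import single_crypt_scene

        r = 20.0
        scene, _ = single_crypt_scene(r)
        n_lumen = int(np.sum(scene.image.pixels == scene.params.lumen_intensity))
        expected = np.pi * r**2  # pitch = 1
        perimeter_px = 2 * np.pi * r
        assert abs(n_lumen - expected) <= 2 * perimeter_px

    def test_intensities_within_14bit_range(self):
        params = cm.preset("normal", seed=9, field_size_px=128, crypt_count=5,
                           lumen_radius_um=(8, 1), noise_sigma=3000.0)
        scene = cm.generate_scene(params)
        assert scene.image.pixels.min() >= 0
        assert scene.image.pixels.max() <= 16383

    def test_label_mask_matches_polygon_list(self, small_scene):
        mask = small_scene.truth.label_mask
        n_labels = len(np.setdiff1d(np.unique(mask), [0]))
        assert n_labels == len(small_scene.truth.crypts)

    def test_render_deterministic_with_noise(self):
        params = cm.preset("normal", seed=5, field_size_px=128, crypt_count=4,
                           lumen_radius_um=(8, 1))
        s1, s2 = cm.generate_scene(params), cm.generate_scene(params)
        assert np.array_equal(s1.image.pixels, s2.image.pixels)

    def test_overlapping_layout_rejected(self):
        params = cm.SceneParams(field_size_px=64, crypt_count=2,
                                lumen_radius_um=(10, 0), noise_sigma=0.0)
        g = cm.CryptGeometry(center_um=(30, 30), a_um=10, b_um=10, orientation_rad=0)
        with pytest.raises(cm.scenes.OverlapError):
            cm.render_scene([g, g], params)


class TestDepthStack:
    def test_five_depths_five_scenes(self, small_params):
        scenes = cm.generate_depth_stack(small_params, [20, 40, 60, 80, 100])
        assert len(scenes) == 5
        assert [s.image.metadata["depth_um"] for s in scenes] == [20, 40, 60, 80, 100]

    def test_no_drift_no_noise_identical_planes(self, small_params):
        scenes = cm.generate_depth_stack(small_params, [20, 40, 60])
        for s in scenes[1:]:
            assert np.array_equal(s.image.pixels, scenes[0].image.pixels)

    def test_drift_scales_radii_but_keeps_centroids(self, small_params):
        scenes = cm.generate_depth_stack(
            small_params, [20, 40], drift={40: 0.8}
        )
        g0, g1 = scenes[0].truth.crypts[0], scenes[1].truth.crypts[0]
        assert g0.center_um == g1.center_um
        assert g1.a_um == pytest.approx(0.8 * g0.a_um)

    def test_stack_deterministic(self, small_params):
        a = cm.generate_depth_stack(small_params, [20, 40])
        b = cm.generate_depth_stack(small_params, [20, 40])
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image.pixels, sb.image.pixels)

    def test_empty_depth_list_errors(self, small_params):
        with pytest.raises(ValueError):
            cm.generate_depth_stack(small_params, [])

    def test_unsorted_depths_error(self, small_params):
        with pytest.raises(ValueError):
            cm.generate_depth_stack(small_params, [40, 20])


class TestCohortDataset:
    def test_study_design_arithmetic(self):
        design = cm.study_design()
        assert design.total_mice == 31
        assert design.total_stacks == 43
        assert all(len(c.depths_um) == 5 for c in design.cohorts)

    def test_hierarchy_counts_match_design(self):
        design = cm.demo_design(seed=2)
        ds = cm.generate_cohort_dataset(design)
        df = ds.to_frame()
        assert len(ds) == design.total_stacks * 5  # 5 depths per stack
        assert df["mouse"].nunique() == design.total_mice
        assert df.groupby("location").size().eq(5).all()
        assert set(df["depth_um"]) == {20.0, 40.0, 60.0, 80.0, 100.0}

    def test_dataset_reproducible_from_seed(self):
        d1 = cm.generate_cohort_dataset(cm.demo_design(seed=3))
        d2 = cm.generate_cohort_dataset(cm.demo_design(seed=3))
        for r1, r2 in zip(d1, d2):
            assert r1.image_id == r2.image_id
            assert np.array_equal(r1.scene.image.pixels, r2.scene.image.pixels)

    def test_zero_mice_cohort_errors(self):
        design = cm.CohortDesign(
            cohorts=(cm.CohortSpec("empty", n_mice=0, n_stacks=0),), seed=0
        )
        with pytest.raises(ValueError, match="mice"):
            cm.generate_cohort_dataset(design)

    def test_empty_design_empty_dataset(self):
        ds = cm.generate_cohort_dataset(cm.CohortDesign(cohorts=(), seed=0))
        assert len(ds) == 0

    def test_stack_allocation_respects_one_to_three(self):
        spec = cm.CohortSpec("AOM late", n_mice=3, n_stacks=9)
        assert spec.stacks_per_mouse() == [3, 3, 3]
        spec = cm.CohortSpec("AOM-DSS late", n_mice=9, n_stacks=12)
        alloc = spec.stacks_per_mouse()
        assert sum(alloc) == 12 and max(alloc) <= 3 and min(alloc) >= 1
        with pytest.raises(ValueError):
            cm.CohortSpec("too dense", n_mice=2, n_stacks=9).stacks_per_mouse()


def test_phenotype_separation_area_sd():
    """Tumor-adjacent fields are more heterogeneous in crypt area than normal."""
    normal_areas, ta_areas = [], []
    for seed in range(3):
        normal_areas += [
            g.area_um2
            for g in cm.sample_crypt_layout(cm.preset("normal", seed=seed, noise_sigma=0.0))
        ]
        ta_areas += [
            g.area_um2
            for g in cm.sample_crypt_layout(
                cm.preset("tumor_adjacent", seed=seed, noise_sigma=0.0)
            )
        ]
    assert np.std(ta_areas, ddof=1) > np.std(normal_areas, ddof=1)
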