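import math

import numpy as np
import pytest

from memtube.synthgen import (
    COVERED_ENRICHMENT_THRESHOLD,
    DEFAULT_OPTICS,
    NOISELESS_OPTICS,
    FluorImage,
    MembraneObjectSpec,
    OpticsModel,
    SceneGenerationError,
    make_frap_trace,
    make_flat_film_scene,
    make_guv_tubule_scene,
    make_scaffold_scene,
    make_tubulation_scene,
    render_scene,
)

PX = 100.0


def _horizontal_tubule(diameter_nm, density=10.0, enrichment=1.0, y=2400.0):
    return MembraneObjectSpec(
        kind="tubule",
        centerline_nm=np.array([[y, 1000.0], [y, 7000.0]]),
        diameter_nm=diameter_nm,
        lipid_density=density,
        protein_enrichment=enrichment,
    )


def _cross_profile_per_nm(image, col):
    """Integrated cross-profile intensity per nm of length at one column."""
    return image.pixels[:, col].sum() / image.pixel_size_nm


class TestRenderScene:
    def test_tubule_rendering_rule(self):
        # d = 50 nm, rho = 10 units/nm^2 -> F_l = 10 * pi * 50
        images, _ = render_scene(
            [_horizontal_tubule(50.0)], NOISELESS_OPTICS, (48, 80), PX, seed=1
        )
        fl = _cross_profile_per_nm(images["lipid"], 40)
        assert fl == pytest.approx(10 * math.pi * 50, rel=1e-6)

    def test_flat_film_mean_value(self):
        film = MembraneObjectSpec(kind="flat_film", lipid_density=5.0)
        images, _ = render_scene([film], NOISELESS_OPTICS, (32, 32), PX, seed=0)
        assert images["lipid"].pixels[10:22, 10:22].mean() == pytest.approx(5 * PX**2, rel=1e-6)

    def test_same_seed_bit_identical(self):
        a, _ = render_scene([_horizontal_tubule(50.0)], DEFAULT_OPTICS, (48, 80), PX, seed=9)
        b, _ = render_scene([_horizontal_tubule(50.0)], DEFAULT_OPTICS, (48, 80), PX, seed=9)
        assert np.array_equal(a["lipid"].pixels, b["lipid"].pixels)

    def test_different_seeds_differ(self):
        a, _ = render_scene([_horizontal_tubule(50.0)], DEFAULT_OPTICS, (48, 80), PX, seed=1)
        b, _ = render_scene([_horizontal_tubule(50.0)], DEFAULT_OPTICS, (48, 80), PX, seed=2)
        assert not np.array_equal(a["lipid"].pixels, b["lipid"].pixels)

    def test_rendering_linearity(self):
        one, _ = render_scene([_horizontal_tubule(50.0, density=3.0)], NOISELESS_OPTICS, (48, 80), PX, seed=0)
        two, _ = render_scene([_horizontal_tubule(50.0, density=6.0)], NOISELESS_OPTICS, (48, 80), PX, seed=0)
        np.testing.assert_allclose(two["lipid"].pixels, 2 * one["lipid"].pixels, atol=1e-9)

    @pytest.mark.parametrize("diameter", [10.0, 29.0, 80.0, 250.0])
    @pytest.mark.parametrize("psf_sigma", [100.0, 250.0])
    def test_psf_preserves_integrated_cross_profile(self, diameter, psf_sigma):
        optics = OpticsModel(psf_sigma_nm=psf_sigma, photons_per_unit=0, read_noise_sd=0, background_level=0)
        images, _ = render_scene([_horizontal_tubule(diameter, density=5.0)], optics, (48, 80), PX, seed=0)
        fl = _cross_profile_per_nm(images["lipid"], 40)
        assert fl == pytest.approx(5.0 * math.pi * diameter, rel=1e-4)

    def test_label_map_partition(self):
        _, truth = make_tubulation_scene(0.5, 6, DEFAULT_OPTICS, seed=3, image_shape=(256, 256))
        lab = truth.true_label_map
        counts = [(lab == c).sum() for c in (0, 1, 2)]
        assert sum(counts) == lab.size
        assert set(np.unique(lab)) <= {0, 1, 2}

    def test_empty_scene_is_valid(self):
        images, truth = render_scene([], NOISELESS_OPTICS, (16, 16), PX, seed=0)
        assert np.all(images["lipid"].pixels == 0)
        assert truth.true_tubulation_ratio is None

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            MembraneObjectSpec(kind="flat_film", lipid_density=-1.0)

    def test_out_of_bounds_geometry_rejected(self):
        bad = MembraneObjectSpec(
            kind="vesicle", center_nm=(100.0, 100.0), radius_nm=5000.0, lipid_density=1.0
        )
        with pytest.raises(ValueError, match="bounds"):
            render_scene([bad], NOISELESS_OPTICS, (32, 32), PX, seed=0)

    def test_protein_channel_scales_with_enrichment(self):
        objs = [_horizontal_tubule(60.0, enrichment=4.0)]
        images, _ = render_scene(
            objs, NOISELESS_OPTICS, (48, 80), PX, channels=("lipid", "protein"), seed=0,
            protein_reference_density=2.0,
        )
        fl_l = _cross_profile_per_nm(images["lipid"], 40)
        fl_p = _cross_profile_per_nm(images["protein"], 40)
        # lipid density 10, protein density 4 * 2 = 8
        assert fl_p / fl_l == pytest.approx(0.8, rel=1e-6)


class TestTubulationScene:
    def test_target_zero_all_vesicles(self):
        _, truth = make_tubulation_scene(0.0, 5, DEFAULT_OPTICS, seed=1, image_shape=(256, 256))
        assert truth.true_tubulation_ratio == 0.0
        assert all(o.kind == "vesicle" for o in truth.objects)

    def test_target_one_all_tubules(self):
        _, truth = make_tubulation_scene(1.0, 5, DEFAULT_OPTICS, seed=1, image_shape=(256, 256))
        assert truth.true_tubulation_ratio == 1.0
        assert all(o.kind == "tubule" for o in truth.objects)

    def test_target_half_within_tolerance_by_pixel_count(self):
        _, truth = make_tubulation_scene(0.5, 8, DEFAULT_OPTICS, seed=7)
        lab = truth.true_label_map
        n_tub = int((lab == 1).sum())
        n_ves = int((lab == 2).sum())
        ratio = n_tub / (n_tub + n_ves)
        assert abs(ratio - 0.5) <= 0.02
        assert truth.true_tubulation_ratio == pytest.approx(ratio)

    def test_infeasible_packing_raises(self):
        with pytest.raises(SceneGenerationError):
            make_tubulation_scene(
                0.5, 80, DEFAULT_OPTICS, seed=0, image_shape=(64, 64), max_attempts=10
            )

    def test_objects_do_not_overlap(self):
        _, truth = make_tubulation_scene(0.5, 8, DEFAULT_OPTICS, seed=5)
        # per-object masks are disjoint iff total labeled area == sum of parts
        from memtube.synthgen import _disk_mask, _polyline_dist_mask

        total = 0
        for o in truth.objects:
            if o.kind == "vesicle":
                m = _disk_mask(truth.true_label_map.shape, truth.pixel_size_nm, o.center_nm, o.radius_nm)
            else:
                m = _polyline_dist_mask(
                    truth.true_label_map.shape, truth.pixel_size_nm, o.centerline_nm,
                    max(o.diameter_nm / 2, truth.pixel_size_nm / 2),
                )
            total += int(m.sum())
        assert total == int((truth.true_label_map > 0).sum())


class TestGuvTubuleScene:
    def test_enrichment_one_plants_unity_ratio(self):
        _, _, truth = make_guv_tubule_scene(8.0, 60.0, 1.0, NOISELESS_OPTICS, seed=0)
        assert truth.true_sorting_ratio == 1.0

    def test_planted_values_passed_through(self):
        _, _, truth = make_guv_tubule_scene(8.0, 60.0, 3.0, NOISELESS_OPTICS, seed=0)
        assert truth.true_sorting_ratio == 3.0
        assert truth.true_diameters_nm == [60.0]

    def test_negative_enrichment_rejected(self):
        with pytest.raises(ValueError):
            make_guv_tubule_scene(8.0, 60.0, -0.5, NOISELESS_OPTICS, seed=0)

    def test_lipid_fl_scales_with_diameter_at_equal_protein_density(self):
        # two tubules with equal protein areal densities: lipid F_l ratio = 90/55
        t55 = _horizontal_tubule(55.0, density=5.0, enrichment=1.0, y=1200.0)
        t90 = _horizontal_tubule(90.0, density=5.0, enrichment=1.0, y=3600.0)
        images, _ = render_scene(
            [t55, t90], NOISELESS_OPTICS, (48, 80), PX, channels=("lipid", "protein"), seed=0
        )
        lip = images["lipid"].pixels
        fl55 = lip[:24, 40].sum() / PX
        fl90 = lip[24:, 40].sum() / PX
        assert fl90 / fl55 == pytest.approx(90 / 55, rel=1e-4)
        # planted sorting ratios (enrichments) are equal
        prot = images["protein"].pixels
        assert (prot[:24, 40].sum() / lip[:24, 40].sum()) == pytest.approx(
            prot[24:, 40].sum() / lip[24:, 40].sum(), rel=1e-4
        )


class TestScaffoldScene:
    def test_lipid_step_matches_diameter_ratio(self):
        lip, _, truth = make_scaffold_scene(
            [(5000.0, 80.0, 1.0), (3000.0, 55.0, 10.0)], NOISELESS_OPTICS, seed=0
        )
        bounds = truth.meta["segment_boundaries_x_nm"]
        col_a = int((bounds[0] + 2500.0) / PX)
        col_b = int((bounds[1] + 1500.0) / PX)
        fl_a = lip.pixels[:, col_a].sum() / PX
        fl_b = lip.pixels[:, col_b].sum() / PX
        assert fl_b / fl_a == pytest.approx(55 / 80, rel=1e-3)

    def test_single_uniform_segment(self):
        _, _, truth = make_scaffold_scene([(6000.0, 70.0, 1.0)], NOISELESS_OPTICS, seed=0)
        assert truth.true_diameters_nm == [70.0]
        assert truth.covered_flags == [False]

    def test_three_segments_listed_in_order(self):
        segs = [(3000.0, 80.0, 1.0), (2000.0, 55.0, 10.0), (3000.0, 78.0, 1.0)]
        _, _, truth = make_scaffold_scene(segs, NOISELESS_OPTICS, seed=0)
        assert truth.true_diameters_nm == [80.0, 55.0, 78.0]
        assert truth.covered_flags == [False, True, False]
        assert all(
            (enr > COVERED_ENRICHMENT_THRESHOLD) == flag
            for (_, _, enr), flag in zip(segs, truth.covered_flags)
        )

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            make_scaffold_scene([(0.0, 80.0, 1.0)], NOISELESS_OPTICS, seed=0)


class TestFrapTrace:
    TIMES = np.concatenate([np.arange(-3.0, 0.0), np.arange(0.0, 200.0)])

    def test_full_mobility_returns_to_prebleach(self):
        tr = make_frap_trace(1.0, 5.0, 1000.0, 0.8, 0.0, 0.0, self.TIMES, seed=0)
        assert tr.intensity[-1] == pytest.approx(1000.0, rel=1e-3)

    def test_zero_mobility_flat_at_bleached_level(self):
        tr = make_frap_trace(0.0, 5.0, 1000.0, 0.8, 0.0, 0.0, self.TIMES, seed=0)
        post = tr.intensity[tr.bleach_index :]
        assert np.allclose(post, 200.0)

    def test_half_mobility_closed_form(self):
        tr = make_frap_trace(0.5, 5.0, 1000.0, 0.8, 0.0, 0.0, self.TIMES, seed=0)
        i = tr.bleach_index + 5  # t = 5 s = tau
        recovered = (tr.intensity[i] - 200.0) / 800.0
        assert recovered == pytest.approx(0.5 * (1 - math.exp(-1)), rel=1e-6)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            make_frap_trace(0.5, 5.0, 1000.0, 0.8, 0.0, 0.0, np.array([-2.0, -1.0, -1.0, 1.0]), seed=0)

    def test_noise_seeded(self):
        a = make_frap_trace(0.5, 5.0, 1000.0, 0.8, 10.0, 5.0, self.TIMES, seed=3)
        b = make_frap_trace(0.5, 5.0, 1000.0, 0.8, 10.0, 5.0, self.TIMES, seed=3)
        assert np.array_equal(a.intensity, b.intensity)


class TestValidation:
    def test_optics_validation(self):
        with pytest.raises(ValueError):
            OpticsModel(psf_sigma_nm=0.0)
        with pytest.raises(ValueError):
            OpticsModel(read_noise_sd=-1.0)

    def test_fluorimage_validation(self):
        with pytest.raises(ValueError):
            FluorImage(pixels=np.array([[-1.0]]), pixel_size_nm=100.0)
        with pytest.raises(ValueError):
            FluorImage(pixels=np.zeros((4, 4)), pixel_size_nm=0.0)
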