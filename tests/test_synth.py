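import numpy as np
import pytest

from octarep.synth import (
    ChoriocapillarisSceneParams,
    CohortSpec,
    RetinaSceneParams,
    SceneSpec,
    generate_cc_scene,
    generate_cohort,
    generate_latent_cohort,
    generate_retina_scene,
    generate_visit_pair,
)


class TestSceneSpec:
    def test_default_pitch_from_field(self):
        spec = SceneSpec()
        assert spec.pitch_x_um == pytest.approx(15000 / 800)
        assert spec.pitch_y_um == pytest.approx(9000 / 534)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(width_px=32, height_px=32)

    def test_fovea_outside_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(fovea_center_px=(1000.0, 10.0))


class TestRetinaScene:
    def test_empty_scene_is_uniform_background(self, small_spec):
        params = RetinaSceneParams(
            large_vessel_count=0, capillary_density_target=0.0,
            speckle_sigma=0.0, vignetting_strength=0.0, background_level=0.2,
        )
        img, truth = generate_retina_scene(small_spec, params)
        assert np.all(img.pixels == 0.2)
        assert truth.true_pd_percent == 0.0

    def test_deterministic(self, default_spec):
        a, _ = generate_retina_scene(default_spec)
        b, _ = generate_retina_scene(default_spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_capillary_density_calibration(self):
        """Requested capillary coverage is realized within +/- 0.03."""
        params = RetinaSceneParams(
            large_vessel_count=0, capillary_density_target=0.35, speckle_sigma=0.0,
        )
        _, truth = generate_retina_scene(SceneSpec(seed=3), params)
        realized = truth.union_vessel_mask.mean()
        assert realized == pytest.approx(0.35, abs=0.03)

    def test_truth_masks_match_grid(self, small_spec):
        img, truth = generate_retina_scene(small_spec)
        assert truth.large_vessel_mask.shape == img.shape
        assert truth.capillary_mask.shape == img.shape
        union = truth.union_vessel_mask
        assert truth.true_pd_percent == pytest.approx(100 * union.mean())

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RetinaSceneParams(capillary_density_target=1.5)
        with pytest.raises(ValueError):
            RetinaSceneParams(large_vessel_width_um=(100.0, 60.0))
        with pytest.raises(ValueError):
            RetinaSceneParams(capillary_width_um=80.0)  # above LV minimum


class TestCCScene:
    def test_zero_target_empty_voids(self, small_spec):
        params = ChoriocapillarisSceneParams(void_fraction_target=0.0)
        _, truth = generate_cc_scene(small_spec, params)
        assert not truth.void_mask.any()
        assert truth.true_void_fraction == 0.0

    def test_void_fraction_calibration(self):
        params = ChoriocapillarisSceneParams(void_fraction_target=0.15)
        _, truth = generate_cc_scene(SceneSpec(seed=6), params)
        assert truth.true_void_fraction == pytest.approx(0.15, abs=0.02)

    def test_deterministic(self, default_spec):
        a, _ = generate_cc_scene(default_spec)
        b, _ = generate_cc_scene(default_spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestVisitPair:
    def test_zero_sd_shared_noise_identical(self, small_spec):
        (v1, v2), _ = generate_visit_pair(
            generate_retina_scene, small_spec, RetinaSceneParams(),
            within_subject_sd=0.0, share_noise=True,
        )
        np.testing.assert_array_equal(v1.pixels, v2.pixels)

    def test_perturbation_changes_image(self, small_spec):
        (v1, v2), _ = generate_visit_pair(
            generate_retina_scene, small_spec, RetinaSceneParams(),
            within_subject_sd=0.05,
        )
        assert np.abs(v1.pixels - v2.pixels).mean() > 0

    def test_shared_anatomy(self, small_spec):
        """Both visits carry one ground truth: the noise-free scenes agree."""
        params = RetinaSceneParams(speckle_sigma=0.0)
        (v1, v2), truth = generate_visit_pair(
            generate_retina_scene, small_spec, params, within_subject_sd=0.0,
            share_noise=False,
        )
        np.testing.assert_array_equal(v1.pixels, v2.pixels)
        assert truth.large_vessel_mask.shape == v1.shape

    def test_negative_sd_rejected(self, small_spec):
        with pytest.raises(ValueError):
            generate_visit_pair(generate_retina_scene, small_spec,
                                RetinaSceneParams(), within_subject_sd=-0.1)


class TestCohort:
    @pytest.mark.parametrize("b,w,icc", [(1.0, 0.0, 1.0), (3.0, 1.0, 0.9),
                                         (0.0, 1.0, 0.0)])
    def test_implied_icc(self, b, w, icc):
        spec = CohortSpec(between_subject_sd=b, within_subject_sd=w)
        assert spec.implied_true_icc == pytest.approx(icc)

    def test_variance_components_recovered(self):
        """A 200-subject cohort recovers (b, w) within 15% relative error."""
        spec = CohortSpec(n_subjects=200, between_subject_sd=3.0,
                          within_subject_sd=1.0, seed=11)
        lat = generate_latent_cohort(spec)
        wide = lat.pivot(index="subject_id", columns="visit", values="value")
        d = wide[1] - wide[2]
        w_hat = d.std(ddof=1) / np.sqrt(2)
        subj_var = wide.mean(axis=1).var(ddof=1) - w_hat**2 / 2
        b_hat = np.sqrt(subj_var)
        assert w_hat == pytest.approx(1.0, rel=0.15)
        assert b_hat == pytest.approx(3.0, rel=0.15)

    def test_latent_deterministic(self):
        spec = CohortSpec(seed=5)
        a = generate_latent_cohort(spec)
        b = generate_latent_cohort(spec)
        assert a.equals(b)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)

    def test_both_sds_zero_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(between_subject_sd=0.0, within_subject_sd=0.0)

    def test_image_cohort_manifest(self, tmp_path):
        spec = CohortSpec(
            n_subjects=2, seed=3,
            base_scene=SceneSpec(width_px=256, height_px=170, seed=3),
        )
        ds = generate_cohort(spec, scene_kind="retina", out_dir=tmp_path)
        assert len(ds.manifest) == 2 * 2  # subjects x visits, one slab
        assert (tmp_path / "manifest.csv").exists()
        for p in ds.manifest["image_path"]:
            assert (tmp_path / p).exists()
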