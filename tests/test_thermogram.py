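"""Synthetic thermogram generation, operator jitter, and ROI measurement."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import ndimage

from batirt import (
    MaskDegenerateError,
    SceneSpec,
    SegmentationJitter,
    empirical_error_budget,
    generate_thermogram,
    measure_roi,
    neonate_scene,
    perturb_mask,
)
from batirt.thermogram import (
    read_thermogram_tiff,
    write_mask_png,
    write_thermogram_tiff,
)


def quiet(spec: SceneSpec) -> SceneSpec:
    return dataclasses.replace(spec, camera_sigma=0.0, frame_offset_sigma=0.0)


class TestGenerateThermogram:
    def test_flat_scene_is_constant_background(self):
        spec = SceneSpec(
            activation_rise=0.0, camera_sigma=0.0, background_temp=305.0
        )
        th = generate_thermogram(spec)
        assert np.all(th.temperature_field == 305.0)

    def test_hard_edge_contrast_equals_rise(self):
        spec = SceneSpec(
            activation_rise=0.5,
            edge_softness=0.0,
            camera_sigma=0.0,
            background_temp=306.0,
        )
        th = generate_thermogram(spec)
        inside = th.temperature_field[th.true_mask].mean()
        outside = th.temperature_field[~th.true_mask].mean()
        assert inside - outside == pytest.approx(0.5, abs=1e-9)

    def test_plateau_holds_full_rise_inside_mask(self):
        """With an edge ramp, every pixel of the nominal ROI still carries
        the full activation rise (the ramp lives outside)."""
        spec = SceneSpec(
            activation_rise=0.3, edge_softness=1.0, camera_sigma=0.0
        )
        th = generate_thermogram(spec)
        inside = th.temperature_field[th.true_mask]
        assert np.allclose(inside, spec.background_temp + 0.3)

    def test_mask_area_matches_analytic_ellipse(self):
        spec = SceneSpec(roi_axes=(4.0, 2.0), pixel_scale=0.1)
        th = generate_thermogram(spec)
        assert th.true_area_cm2 == pytest.approx(
            math.pi * 4.0 * 2.0, rel=0.02
        )

    @pytest.mark.parametrize(
        ("pixel_scale", "rel_tol"), [(0.2, 0.02), (0.1, 0.01), (0.05, 0.005)]
    )
    def test_area_converges_with_resolution(self, pixel_scale, rel_tol):
        npx = int(16.0 / pixel_scale)
        spec = SceneSpec(
            roi_axes=(4.0, 2.0),
            pixel_scale=pixel_scale,
            image_shape=(npx, npx),
        )
        th = generate_thermogram(spec)
        assert th.true_area_cm2 == pytest.approx(8 * math.pi, rel=rel_tol)

    def test_deterministic_given_seed(self):
        spec = SceneSpec(camera_sigma=0.05, frame_offset_sigma=0.01, seed=21)
        a = generate_thermogram(spec).temperature_field
        b = generate_thermogram(spec).temperature_field
        assert np.array_equal(a, b)
        c = generate_thermogram(
            dataclasses.replace(spec, seed=22)
        ).temperature_field
        assert not np.array_equal(a, c)

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError):
            generate_thermogram(
                SceneSpec(roi_axes=(15.0, 12.0), image_shape=(100, 100))
            )


class TestMeasureRoi:
    def test_full_frame_on_flat_scene(self):
        spec = SceneSpec(
            activation_rise=0.0, camera_sigma=0.0, background_temp=304.0,
            image_shape=(50, 60), pixel_scale=0.1, roi_axes=(1.0, 1.0),
        )
        th = generate_thermogram(spec)
        area, temp = measure_roi(th, np.ones(spec.image_shape, bool))
        assert area == pytest.approx(50 * 60 * 0.01)
        assert temp == pytest.approx(304.0)

    def test_true_mask_zero_noise(self):
        spec = quiet(neonate_scene())
        th = generate_thermogram(spec)
        area, temp = measure_roi(th, th.true_mask)
        assert area == pytest.approx(spec.analytic_roi_area_cm2, rel=0.02)
        assert temp == pytest.approx(
            spec.background_temp + spec.activation_rise, abs=1e-9
        )

    def test_empty_mask_rejected(self):
        th = generate_thermogram(SceneSpec())
        with pytest.raises(MaskDegenerateError):
            measure_roi(th, np.zeros_like(th.true_mask))

    def test_mean_temperature_noise_follows_clt(self):
        """Across noisy frames, sd(mean over mask) ~ camera_sigma/sqrt(n_px)
        when the noise is pixel-independent."""
        spec = SceneSpec(
            image_shape=(80, 80), pixel_scale=0.1, roi_axes=(2.0, 1.5),
            camera_sigma=0.05, activation_rise=0.0,
        )
        truth = generate_thermogram(spec).true_mask
        n_px = truth.sum()
        means = []
        for s in range(200):
            th = generate_thermogram(dataclasses.replace(spec, seed=s))
            means.append(th.temperature_field[truth].mean())
        expected = 0.05 / math.sqrt(n_px)
        assert np.std(means, ddof=1) == pytest.approx(expected, rel=0.2)


class TestPerturbMask:
    def test_zero_magnitude_is_identity(self):
        truth = generate_thermogram(neonate_scene()).true_mask
        jit = SegmentationJitter(magnitude=0.0, seed=5)
        assert np.array_equal(perturb_mask(truth, jit, 0.1), truth)

    def test_deterministic_given_seed(self):
        truth = generate_thermogram(neonate_scene()).true_mask
        jit = SegmentationJitter(magnitude=10.0, seed=8)
        a = perturb_mask(truth, jit, 0.1)
        b = perturb_mask(truth, jit, 0.1)
        assert np.array_equal(a, b)
        c = perturb_mask(truth, dataclasses.replace(jit, seed=9), 0.1)
        assert not np.array_equal(a, c)

    def test_empty_truth_rejected(self):
        with pytest.raises(MaskDegenerateError):
            perturb_mask(
                np.zeros((10, 10), bool), SegmentationJitter(magnitude=1.0),
                0.1,
            )

    def test_boundary_noise_area_sd_calibrated(self):
        """Over 500 operator realizations the sd of the area error lands
        within 20% of the requested 10 cm^2 magnitude."""
        spec = quiet(neonate_scene())
        th = generate_thermogram(spec)
        errs = np.empty(500)
        for s in range(500):
            m = perturb_mask(
                th.true_mask,
                SegmentationJitter(magnitude=10.0, seed=s),
                spec.pixel_scale,
            )
            errs[s] = m.sum() * spec.pixel_scale**2 - th.true_area_cm2
        assert 8.0 <= np.std(errs, ddof=1) <= 12.0

    def test_boundary_noise_masks_simply_connected(self):
        spec = quiet(neonate_scene())
        th = generate_thermogram(spec)
        for s in range(50):
            m = perturb_mask(
                th.true_mask,
                SegmentationJitter(magnitude=10.0, seed=s),
                spec.pixel_scale,
            )
            _, n_comp = ndimage.label(m)
            assert n_comp == 1
            assert np.array_equal(ndimage.binary_fill_holes(m), m)

    def test_affine_offset_area_sd_calibrated(self):
        spec = quiet(neonate_scene())
        th = generate_thermogram(spec)
        jit = SegmentationJitter(magnitude=10.0, mode="affine_offset")
        errs = np.empty(400)
        for s in range(400):
            m = perturb_mask(
                th.true_mask,
                dataclasses.replace(jit, seed=s),
                spec.pixel_scale,
            )
            errs[s] = m.sum() * spec.pixel_scale**2 - th.true_area_cm2
        assert 8.0 <= np.std(errs, ddof=1) <= 12.0

    def test_invalid_jitter_rejected(self):
        with pytest.raises(ValueError):
            SegmentationJitter(magnitude=-1.0)
        with pytest.raises(ValueError):
            SegmentationJitter(mode="warp")


class TestEmpiricalErrorBudget:
    def test_no_jitter_all_error_from_temperature(self):
        eb = empirical_error_budget(
            neonate_scene(), SegmentationJitter(magnitude=0.0),
            n_replicates=100, seed=1,
        )
        assert eb.component_area == pytest.approx(0.0, abs=1e-30)
        assert eb.ratio == pytest.approx(0.0, abs=1e-12)

    def test_no_camera_noise_all_error_from_area(self):
        spec = quiet(neonate_scene())
        eb = empirical_error_budget(
            spec, SegmentationJitter(magnitude=10.0),
            n_replicates=100, seed=1,
        )
        assert eb.component_temperature == pytest.approx(0.0, abs=1e-30)
        assert eb.ratio == math.inf

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            empirical_error_budget(
                neonate_scene(), SegmentationJitter(), n_replicates=10
            )

    def test_crossover_scene_components_comparable(self, crossover_budget):
        """At the measured-A ~ 50 cm^2, 0.2 K rise crossover point with
        dA ~ 10 cm^2 and dT ~ 0.01 K, the two ablation components agree
        within 25%."""
        eb = crossover_budget
        assert 45.0 <= eb.mean_area_cm2 <= 55.0
        assert 0.75 <= eb.ratio <= 1.25

    def test_total_variance_matches_delta_method(
        self, neonate_budget, adult_budget, crossover_budget
    ):
        """End-to-end simulated variance of the power agrees with the
        analytic budget evaluated at the empirical error magnitudes."""
        for eb in (neonate_budget, adult_budget, crossover_budget):
            assert abs(eb.relative_gap) <= 0.15

    def test_jitter_only_ablation_isolates_area_sd(self, neonate_budget):
        """The empirical area-error sd stays at the calibrated operator
        magnitude and the temperature-error sd at the sensor offset scale."""
        assert neonate_budget.delta_area_cm2 == pytest.approx(10.0, rel=0.2)
        assert neonate_budget.delta_temp_K == pytest.approx(0.01, rel=0.15)


class TestIO:
    def test_tiff_round_trip(self, tmp_path):
        th = generate_thermogram(
            SceneSpec(
                camera_sigma=0.02, seed=3, image_shape=(80, 80),
                roi_axes=(2.0, 1.5), edge_softness=0.5,
            )
        )
        sidecar = write_thermogram_tiff(th, tmp_path / "t.tif")
        assert sidecar.exists()
        field, meta = read_thermogram_tiff(tmp_path / "t.tif")
        assert meta["pixel_scale_cm"] == th.pixel_scale
        # quantization at 0.001 K per digital number
        assert np.max(np.abs(field - th.temperature_field)) <= 0.0006

    def test_mask_png_round_trip(self, tmp_path):
        import imageio.v3 as iio

        th = generate_thermogram(
            SceneSpec(image_shape=(80, 80), roi_axes=(2.0, 1.5),
                      edge_softness=0.5)
        )
        write_mask_png(th.true_mask, tmp_path / "m.png")
        back = iio.imread(tmp_path / "m.png") > 0
        assert np.array_equal(back, th.true_mask)
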