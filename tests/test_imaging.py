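"""Pipeline tests: segmentation, region partition, morphometry, calibration fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from mcascreen import DegenerateObjectError, FitError, InputError
from mcascreen.imaging import (
    CalibrationFit,
    Frame,
    SegmentationParams,
    classify_phenotype,
    estimate_thickness,
    evaluate_classifier,
    fit_attenuation_length,
    fit_cyst_scaling,
    measure,
    normalize_frame,
    partition_regions,
    segment,
)
from mcascreen.synthetic import MCAGeometry, OpticsConfig, render_frame


def _fv(center_int, mean_inner):
    from mcascreen.imaging import FeatureVector

    return FeatureVector(
        A=1000, P=100, D=100, a=60, b=50, e=0.3, theta=0.0,
        mean_inner=mean_inner, center_int=center_int, I0_local=1.0,
        circ=1.0, P_geom=100,
    )


class TestNormalize:
    def test_identity_maps_to_ones(self):
        raw = Frame(np.full((8, 8), 7.0))
        assert np.allclose(normalize_frame(raw, raw).pixels, 1.0)

    def test_half_background_maps_to_half(self):
        bg = Frame(np.full((8, 8), 4.0))
        raw = Frame(np.full((8, 8), 2.0))
        assert np.allclose(normalize_frame(raw, bg).pixels, 0.5)

    def test_zero_background_pixel_uses_floor(self):
        bg = Frame(np.ones((4, 4)))
        bg.pixels[0, 0] = 0.0
        out = normalize_frame(Frame(np.ones((4, 4))), bg)
        assert np.all(np.isfinite(out.pixels))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            normalize_frame(Frame(np.ones((4, 4))), Frame(np.ones((5, 5))))


class TestSegment:
    def test_blank_frame_is_discarded(self):
        assert segment(Frame(np.ones((64, 64)))) is None

    def test_subthreshold_disk_area_matches_closed_form(self):
        # pixels fall below 0.9 where the chord exceeds h0*ln(1/0.9); for a
        # sphere that is a disk of radius sqrt(R^2 - (h0 ln(1/0.9)/2)^2)
        optics = OpticsConfig()
        g = MCAGeometry("spheroid", a=150.0, b=150.0)
        frame = render_frame(g, optics)
        regions = segment(frame)
        l_crit = optics.h0 * math.log(1 / 0.9)
        rho = math.sqrt(150.0**2 - (l_crit / 2) ** 2)
        expected_px = math.pi * (rho / optics.pixel_scale) ** 2
        assert regions.mask.sum() == pytest.approx(expected_px, rel=0.05)

    def test_small_object_discarded(self):
        pixels = np.ones((64, 64))
        pixels[30:33, 30:33] = 0.1  # 9 px < min_area
        assert segment(Frame(pixels)) is None

    def test_two_objects_keeps_larger_and_flags(self):
        g1 = MCAGeometry("spheroid", a=120.0, b=120.0, center=(-150.0, 0.0))
        g2 = MCAGeometry("spheroid", a=60.0, b=60.0, center=(200.0, 0.0))
        regions = segment(render_frame([g1, g2], OpticsConfig()))
        assert regions.multi_object
        # the kept component is the larger one (centroid on the left)
        assert regions.centroid_px[1] < 128


class TestPartitionRegions:
    def test_inner_and_border_tile_the_mask(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 20)
        mask[rr, cc] = True
        r = partition_regions(mask)
        assert np.array_equal(r.inner | r.border, mask)
        assert not np.any(r.inner & r.border)

    def test_disk_erosion_matches_bruteforce_distance_oracle(self):
        # brute force: a pixel survives erosion by a disk of radius 6 iff every
        # mask-complement pixel is farther than 6 (Euclidean distance map)
        from scipy.ndimage import distance_transform_edt

        mask = np.zeros((128, 128), bool)
        rr, cc = draw_disk((64, 64), 50)
        mask[rr, cc] = True
        r = partition_regions(mask)
        dist = distance_transform_edt(mask)
        # the disk footprint of radius 6 includes offsets with |d| <= 6
        oracle = dist > 6
        mismatch = np.sum(r.inner ^ oracle)
        assert mismatch / oracle.sum() < 0.02  # rasterisation boundary only

    def test_inner_radius_shrinks_by_erosion_radius(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = draw_disk((64, 64), 50)
        mask[rr, cc] = True
        r = partition_regions(mask)
        inner_radius = math.sqrt(r.inner.sum() / math.pi)
        assert inner_radius == pytest.approx(44.0, abs=1.0)

    def test_thin_strip_raises_degenerate(self):
        mask = np.zeros((64, 64), bool)
        mask[10:60, 30:35] = True  # 5 px wide, erosion by 6 empties it
        with pytest.raises(DegenerateObjectError):
            partition_regions(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            partition_regions(np.zeros((8, 8), bool))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_identity_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((96, 96), bool)
        for _ in range(3):
            rr, cc = draw_disk(tuple(rng.integers(25, 70, 2)), int(rng.integers(10, 22)),
                               shape=mask.shape)
            mask[rr, cc] = True
        try:
            r = partition_regions(mask)
        except DegenerateObjectError:
            return
        assert np.array_equal(r.inner | r.border, mask)
        assert not np.any(r.inner & r.border)


class TestMeasure:
    def _measure_mask(self, mask, scale=3.0):
        regions = partition_regions(mask)
        frame = Frame(np.where(mask, 0.2, 1.0), scale)
        return measure(frame, regions)

    def test_rasterised_disk_morphometry(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = draw_disk((64, 64), 50)
        mask[rr, cc] = True
        fv = self._measure_mask(mask)
        assert fv.e <= 0.05
        assert fv.D == pytest.approx(300.0, abs=3.0)
        assert fv.circ == pytest.approx(1.0, abs=0.03)

    def test_two_to_one_ellipse_eccentricity(self):
        mask = np.zeros((256, 256), bool)
        rr, cc = draw_ellipse(128, 128, 40, 80)
        mask[rr, cc] = True
        fv = self._measure_mask(mask)
        assert fv.e == pytest.approx(math.sqrt(3) / 2, abs=0.02)

    def test_equivalent_diameter_formula(self):
        # D = 2 * scale * sqrt(A / pi) evaluated directly
        mask = np.zeros((220, 220), bool)
        rr, cc = draw_disk((110, 110), 57)  # area ~10200 px
        mask[rr, cc] = True
        fv = self._measure_mask(mask)
        assert fv.D == pytest.approx(2 * 3.0 * math.sqrt(fv.A / math.pi))

    def test_scale_equivariance(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = draw_ellipse(64, 64, 30, 45)
        mask[rr, cc] = True
        fv1 = self._measure_mask(mask, scale=3.0)
        fv2 = self._measure_mask(mask, scale=6.0)
        assert fv2.D == pytest.approx(2 * fv1.D)
        assert fv2.a == pytest.approx(2 * fv1.a)
        assert fv2.e == pytest.approx(fv1.e)
        assert fv2.circ == pytest.approx(fv1.circ)

    def test_isoperimetric_ratio_bounded(self):
        for radius in (20, 35, 50):
            mask = np.zeros((128, 128), bool)
            rr, cc = draw_disk((64, 64), radius)
            mask[rr, cc] = True
            fv = self._measure_mask(mask)
            assert fv.circ <= 1.05


class TestClassifyPhenotype:
    def test_bright_center_is_cyst(self):
        assert classify_phenotype(_fv(center_int=0.8, mean_inner=0.6)) == "cyst"

    def test_tie_breaks_to_spheroid(self):
        assert classify_phenotype(_fv(center_int=0.6, mean_inner=0.6)) == "spheroid"

    def test_noiseless_renders_classified_perfectly(self):
        # the bright-center signature is guaranteed for thin shells
        # (t < b/2); thickness ratio 4.5 keeps that precondition at any
        # sampled eccentricity
        from mcascreen.imaging import analyze_frame
        from mcascreen.synthetic import PopulationConfig, sample_population

        cysts = sample_population(
            PopulationConfig(n=30, cyst_fraction=1.0, cyst_thickness_ratio=4.5, seed=21)
        )
        spheroids = sample_population(PopulationConfig(n=30, cyst_fraction=0.0, seed=22))
        for g in cysts + spheroids:
            assert all(g.t < g.b / 2 for g in cysts)
            fv = analyze_frame(render_frame(g, OpticsConfig()))
            assert classify_phenotype(fv) == g.kind


class TestEstimateThickness:
    def test_background_intensity_gives_zero(self):
        assert estimate_thickness(1.0, 1.0, 140.0) == 0.0

    def test_one_attenuation_length(self):
        assert estimate_thickness(1.0 / math.e, 1.0, 140.0) == pytest.approx(140.0)

    def test_render_then_invert_round_trip(self, spheroid_series_features):
        # a 300 µm sphere has a 300 µm center chord; find it in the series
        fv = min(spheroid_series_features, key=lambda f: abs(f.D - 300))
        h = estimate_thickness(fv.center_int, fv.I0_local, 140.0)
        assert h == pytest.approx(fv.D, abs=3.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InputError):
            estimate_thickness(0.0, 1.0, 140.0)

    def test_above_background_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert estimate_thickness(1.2, 1.0, 140.0) == 0.0


class TestAttenuationFit:
    def test_two_exact_points_recover_h0_exactly(self):
        h0 = 140.0
        feats = [_fv(math.exp(-D / h0), 0.5) for D in (200.0, 400.0)]
        for f, D in zip(feats, (200.0, 400.0)):
            f.D = D
        fit = fit_attenuation_length(feats)
        assert fit.h0_hat == pytest.approx(h0)

    def test_recovery_on_noiseless_renders(self, spheroid_series_features):
        fit = fit_attenuation_length(spheroid_series_features)
        assert fit.h0_hat == pytest.approx(140.0, rel=0.03)

    def test_recovery_with_noise(self):
        from mcascreen.imaging import analyze_frame

        rng = np.random.default_rng(17)
        optics = OpticsConfig(noise_sd=0.01)
        feats = []
        for D in np.linspace(150, 550, 25):
            g = MCAGeometry("spheroid", a=D / 2, b=D / 2)
            feats.append(analyze_frame(render_frame(g, optics, rng=rng)))
        fit = fit_attenuation_length(feats)
        assert fit.h0_hat == pytest.approx(140.0, rel=0.10)

    def test_all_equal_diameters_rejected(self):
        feats = [_fv(0.3, 0.5) for _ in range(5)]
        for f in feats:
            f.D = 300.0
        with pytest.raises(FitError):
            fit_attenuation_length(feats)


class TestCystScalingFit:
    def test_exact_half_diameter_thickness_gives_k_two(self):
        h0 = 140.0
        feats = []
        for D in (150.0, 300.0, 450.0):
            f = _fv(math.exp(-(D / 2) / h0), 0.5)
            f.D = D
            feats.append(f)
        fit = fit_cyst_scaling(feats, h0)
        assert fit.k == pytest.approx(2.0)
        assert not fit.nonlinear

    def test_recovery_on_noiseless_renders(self, cyst_series_features):
        fit = fit_cyst_scaling(cyst_series_features, 140.0)
        assert fit.k == pytest.approx(1.62, rel=0.05)
        assert not fit.nonlinear

    def test_constant_thickness_flags_nonlinearity(self):
        h0 = 140.0
        feats = []
        for D in np.linspace(150, 550, 12):
            f = _fv(math.exp(-80.0 / h0), 0.5)  # h = 80 µm regardless of D
            f.D = D
            feats.append(f)
        assert fit_cyst_scaling(feats, h0).nonlinear


class TestEvaluateClassifier:
    def test_all_correct(self):
        rep = evaluate_classifier(["cyst", "spheroid"], ["cyst", "spheroid"])
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_printed_precision_recall_combination(self):
        pred = ["cyst"] * 100 + ["spheroid"] * 11
        truth = ["cyst"] * 99 + ["spheroid"] + ["cyst"] * 11
        rep = evaluate_classifier(pred, truth)
        assert rep.tp == 99 and rep.fp == 1 and rep.fn == 11
        assert rep.precision == pytest.approx(0.99)
        assert rep.recall == pytest.approx(0.90)

    def test_no_positives_predicted_reports_missing_precision(self):
        rep = evaluate_classifier(["spheroid"] * 4, ["cyst"] * 4)
        assert rep.precision is None and rep.tp == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            evaluate_classifier(["cyst"], ["cyst", "spheroid"])


class TestNoisyBenchmark:
    def test_classifier_meets_regression_bounds(self, classifier_benchmark_report):
        # seeded noisy synthetic benchmark (noise_sd=0.02, 500 per class)
        rep = classifier_benchmark_report
        assert rep.precision >= 0.95
        assert rep.recall >= 0.85
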