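"""Well detection, illumination correction, enhancement, sphere detection."""

import math

import numpy as np
import pytest

from gliomaquant import spheres, synth
from gliomaquant.frames import IntensityFrame
from gliomaquant.spheres import (SphereCandidate, SphereRecord,
                                 WellDetectionError)
from gliomaquant.synth import SphereSpec, WellImageSpec


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


@pytest.fixture(scope="module")
def empty_well():
    sc = synth.make_well_image(WellImageSpec(seed=1))
    well = spheres.detect_well_interior(sc.image)
    return sc, well


class TestWellInterior:
    def test_sharp_rim_iou(self, empty_well):
        sc, well = empty_well
        assert _iou(well.interior, sc.interior_mask) >= 0.98

    def test_vignetted_rim_iou(self):
        sc = synth.make_well_image(WellImageSpec(seed=2,
                                                 vignetting_strength=0.3))
        well = spheres.detect_well_interior(sc.image)
        assert _iou(well.interior, sc.interior_mask) >= 0.95

    def test_rimless_frame_raises(self):
        rng = np.random.default_rng(0)
        img = IntensityFrame(0.55 + 0.01 * rng.standard_normal((280, 280)), 2.0)
        with pytest.raises(WellDetectionError):
            spheres.detect_well_interior(img, max_iterations=200)

    def test_contour_encloses_interior(self, empty_well):
        _, well = empty_well
        assert len(well.contour) > 100
        rows, cols = well.contour[:, 0], well.contour[:, 1]
        interior_rows = np.where(well.interior.any(axis=1))[0]
        assert rows.min() <= interior_rows.min() + 1
        assert rows.max() >= interior_rows.max() - 1


class TestIlluminationCorrection:
    def test_flat_image_stays_flat(self):
        sc = synth.make_well_image(WellImageSpec(seed=3, noise_sd=0.0))
        well = spheres.detect_well_interior(sc.image)
        out = spheres.correct_illumination(sc.image, well)
        vals = out.pixels[well.interior]
        assert (vals.max() - vals.min()) / vals.mean() < 0.01

    def test_gradient_cv_reduction(self):
        sc = synth.make_well_image(WellImageSpec(seed=4,
                                                 illumination_gradient=2.0))
        well = spheres.detect_well_interior(sc.image)
        out = spheres.correct_illumination(sc.image, well)

        def cv(img):
            v = img[well.interior]
            return v.std() / v.mean()

        assert cv(out.pixels) < 0.25 * cv(sc.image.pixels)

    def test_sphere_contrast_preserved_vs_gradient_free(self):
        layout = [SphereSpec(center=(-250.0, -250.0), diameter=120.0),
                  SphereSpec(center=(200.0, 250.0), diameter=120.0)]
        flat_sc = synth.make_well_image(WellImageSpec(seed=5, spheres=layout))
        grad_sc = synth.make_well_image(WellImageSpec(
            seed=5, spheres=layout, illumination_gradient=2.0))
        contrasts = []
        for sc in (flat_sc, grad_sc):
            well = spheres.detect_well_interior(sc.image)
            out = spheres.correct_illumination(sc.image, well)
            nr, nc = out.shape
            rows, cols = np.mgrid[:nr, :nc]
            c = []
            for s, t in zip(layout, sc.truth):
                a, _ = s.semi_axes
                rad_px = a / sc.image.pixel_size
                inside = ((rows - t.centroid[0]) ** 2 +
                          (cols - t.centroid[1]) ** 2) <= (0.8 * rad_px) ** 2
                c.append(out.pixels[inside].std())
            contrasts.append(np.mean(c))
        assert contrasts[1] == pytest.approx(contrasts[0], rel=0.20)

    def test_oversized_structuring_element_raises(self):
        sc = synth.make_well_image(WellImageSpec(seed=3))
        well = spheres.detect_well_interior(sc.image)
        with pytest.raises(ValueError, match="structuring element"):
            spheres.correct_illumination(sc.image, well,
                                         max_sphere_diameter=5000.0)


class TestEnhancement:
    def test_constant_image_unchanged(self):
        img = IntensityFrame(np.full((128, 128), 0.4), 2.0)
        out = spheres.enhance_contrast(img)
        assert np.allclose(out.pixels, 0.4)

    def test_low_contrast_sphere_is_boosted(self):
        layout = [SphereSpec(center=(0.0, 0.0), diameter=150.0, contrast=0.05)]
        sc = synth.make_well_image(WellImageSpec(seed=6, spheres=layout,
                                                 noise_sd=0.002))
        well = spheres.detect_well_interior(sc.image)
        corr = spheres.correct_illumination(sc.image, well)
        enh = spheres.enhance_contrast(corr)

        def local_contrast(img):
            from gliomaquant.spheres import _local_std
            nr, nc = img.shape
            rows, cols = np.mgrid[:nr, :nc]
            t = sc.truth[0]
            rad_px = 0.4 * t.equivalent_diameter / sc.image.pixel_size
            inside = ((rows - t.centroid[0]) ** 2 +
                      (cols - t.centroid[1]) ** 2) <= rad_px ** 2
            return _local_std(img / max(img.max(), 1e-9), 3)[inside].mean()

        assert local_contrast(enh.pixels) >= 2.0 * local_contrast(corr.pixels)

    def test_rank_preservation_on_smooth_ramp(self):
        # the monotone compression plus CLAHE may introduce inversions no
        # larger than one histogram-quantisation step; ranks stay intact
        from scipy import stats as sps
        ramp = np.tile(np.linspace(0.1, 0.9, 256), (256, 1))
        out = spheres.enhance_contrast(IntensityFrame(ramp, 2.0))
        diffs = np.diff(out.pixels, axis=1)
        assert (diffs >= -0.02).all()
        rho = sps.spearmanr(ramp[128], out.pixels[128]).statistic
        assert rho > 0.98


class TestDetection:
    def test_blank_well_has_no_candidates(self, empty_well):
        sc, well = empty_well
        corr = spheres.correct_illumination(sc.image, well)
        enh = spheres.enhance_contrast(corr)
        assert spheres.detect_spheres(enh, well) == []

    def test_ten_separated_spheres_found_exactly(self):
        layout = synth.random_sphere_layout(seed=21, n=10)
        sc = synth.make_well_image(WellImageSpec(
            seed=21, spheres=layout, illumination_gradient=2.0))
        well, records, summary = spheres.analyze_well(sc.image)
        assert summary.sphere_count == 10
        # centroids within one sphere radius of truth
        for t in sc.truth:
            rad_px = t.equivalent_diameter / 2 / sc.image.pixel_size
            d = min(math.hypot(r.centroid[0] - t.centroid[0],
                               r.centroid[1] - t.centroid[1])
                    for r in records)
            assert d <= rad_px

    def test_touching_pair_is_split(self):
        d = 100.0
        for seed in (31, 32):
            rng = np.random.default_rng(seed)
            ang = rng.uniform(0, 2 * math.pi)
            off = 0.8 * d / 2
            cx, cy = rng.uniform(-120, 120, 2)
            layout = [
                SphereSpec(center=(cx - off * math.sin(ang),
                                   cy - off * math.cos(ang)), diameter=d),
                SphereSpec(center=(cx + off * math.sin(ang),
                                   cy + off * math.cos(ang)), diameter=d)]
            sc = synth.make_well_image(WellImageSpec(seed=seed, spheres=layout))
            _, _, summary = spheres.analyze_well(sc.image)
            assert summary.sphere_count == 2

    def test_rotation_permutes_but_preserves_areas(self):
        layout = synth.random_sphere_layout(seed=41, n=5)
        sc = synth.make_well_image(WellImageSpec(seed=41, spheres=layout))
        _, _, s0 = spheres.analyze_well(sc.image)
        rot = IntensityFrame(np.ascontiguousarray(np.rot90(sc.image.pixels)),
                             sc.image.pixel_size)
        _, _, s1 = spheres.analyze_well(rot)
        a0, a1 = sorted(s0.areas), sorted(s1.areas)
        assert len(a0) == len(a1) == 5
        assert np.allclose(a0, a1, rtol=0.02)

    def test_resolution_invariance_of_areas(self):
        layout = [SphereSpec(center=(0.0, 0.0), diameter=100.0),
                  SphereSpec(center=(200.0, 0.0), diameter=140.0,
                             eccentricity=0.5),
                  SphereSpec(center=(-150.0, 150.0), diameter=80.0)]
        lo = synth.make_well_image(WellImageSpec(
            seed=7, spheres=layout, pixel_size=2.0, frame_shape=(560, 560)))
        hi = synth.make_well_image(WellImageSpec(
            seed=7, spheres=layout, pixel_size=1.0, frame_shape=(1120, 1120)))
        _, _, slo = spheres.analyze_well(lo.image, entropy_radius=12,
                                         watershed_sigma=4.0)
        _, _, shi = spheres.analyze_well(hi.image, entropy_radius=24,
                                         watershed_sigma=8.0)
        assert slo.sphere_count == shi.sphere_count == 3
        assert np.allclose(sorted(slo.areas), sorted(shi.areas), rtol=0.05)


def _circle_candidate(diameter_um, pixel_size=2.0, ecc=0.0):
    area_px = math.pi * (diameter_um / 2 / pixel_size) ** 2
    return SphereCandidate(label=1, centroid=(0.0, 0.0),
                           area_px=area_px,
                           equivalent_diameter_px=diameter_um / pixel_size,
                           eccentricity=ecc)


class TestFilter:
    @pytest.mark.parametrize("diameter,ecc,kept", [
        (40.0, 0.0, False),   # too small
        (60.0, 0.0, True),
        (100.0, 0.85, False),  # too elongated
        (100.0, 0.5, True),
        (50.0, 0.0, False),   # boundary: strictly greater than 50 µm
        (100.0, 0.8, False),  # boundary: strictly less than 0.8
    ])
    def test_strict_size_and_shape_bounds(self, diameter, ecc, kept):
        recs = spheres.filter_spheres([_circle_candidate(diameter, ecc=ecc)],
                                      pixel_size=2.0)
        assert (len(recs) == 1) == kept

    def test_equivalent_diameter_consistency(self):
        rec = spheres.filter_spheres([_circle_candidate(90.0)], 2.0)[0]
        assert rec.equivalent_diameter == pytest.approx(
            2 * math.sqrt(rec.area / math.pi))

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        cands = [_circle_candidate(d, ecc=e)
                 for d, e in zip(rng.uniform(30, 200, 30),
                                 rng.uniform(0, 0.95, 30))]
        base = len(spheres.filter_spheres(cands, 2.0))
        stricter_d = len(spheres.filter_spheres(cands, 2.0, min_diameter=80))
        stricter_e = len(spheres.filter_spheres(cands, 2.0,
                                                max_eccentricity=0.5))
        assert stricter_d <= base and stricter_e <= base

    def test_missing_pixel_size_raises(self):
        with pytest.raises(ValueError, match="pixel_size"):
            spheres.filter_spheres([_circle_candidate(90.0)], 0.0)


class TestSummary:
    def test_empty_summary(self):
        s = spheres.summarize_well([], "w0")
        assert s.sphere_count == 0 and s.areas == []

    def test_large_sphere_threshold(self):
        recs = [SphereRecord(1, (0, 0), 2e4, 2 * math.sqrt(2e4 / math.pi), 0.1),
                SphereRecord(2, (0, 0), 1.2e5, 2 * math.sqrt(1.2e5 / math.pi),
                             0.1)]
        s = spheres.summarize_well(recs, "w0")
        assert s.sphere_count == 2 and s.large_sphere_count == 1

    def test_group_mean_count_is_plain_average(self):
        counts = [3, 5, 4]
        assert np.mean(counts) == pytest.approx(4.0)
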