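import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wspdrop import (
    DropletMask,
    GAConfig,
    StructuringElement,
    SyntheticSpec,
    analyze_image,
    classify_pa_group,
    coverage,
    density,
    filter_small_droplets,
    generate_wsp,
    label_droplets,
    morphological_close,
)

from .conftest import image_from


def mask_of(array):
    return DropletMask(pixels=np.asarray(array, dtype=bool))


class TestStructuringElement:
    def test_default_disk(self):
        fp = StructuringElement().footprint()
        np.testing.assert_array_equal(fp, [[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    def test_square(self):
        fp = StructuringElement(shape="square", radius_px=1).footprint()
        assert fp.shape == (3, 3) and fp.all()

    def test_invalid(self):
        with pytest.raises(ValueError):
            StructuringElement(shape="cross")
        with pytest.raises(ValueError):
            StructuringElement(radius_px=0)


class TestMorphologicalClose:
    def test_fills_center_hole(self):
        m = np.ones((5, 5), dtype=bool)
        m[2, 2] = False
        closed = morphological_close(mask_of(m), StructuringElement(shape="square"))
        assert closed.pixels.all()

    def test_disk_fills_single_pixel_hole(self):
        m = np.ones((7, 7), dtype=bool)
        m[3, 3] = False
        closed = morphological_close(mask_of(m))
        assert closed.pixels.all()

    def test_empty_mask(self):
        m = mask_of(np.zeros((4, 6)))
        assert morphological_close(m).foreground_px == 0

    def test_idempotence_and_extensivity_random(self, rng):
        for _ in range(20):
            m = mask_of(rng.random((20, 30)) < 0.4)
            once = morphological_close(m)
            twice = morphological_close(once)
            np.testing.assert_array_equal(once.pixels, twice.pixels)
            assert (once.pixels | ~m.pixels).all()  # input fg preserved

    def test_border_foreground_survives(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0, :] = True
        closed = morphological_close(mask_of(m), StructuringElement(shape="square"))
        assert (closed.pixels[0, :]).all()


@settings(max_examples=40, deadline=None)
@given(
    pixels=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=16)),
    shape=st.sampled_from(["disk", "square"]),
    radius=st.integers(1, 2),
)
def test_closing_properties(pixels, shape, radius):
    m = mask_of(pixels)
    selem = StructuringElement(shape=shape, radius_px=radius)
    closed = morphological_close(m, selem)
    # extensive
    assert not (m.pixels & ~closed.pixels).any()
    # idempotent
    np.testing.assert_array_equal(
        morphological_close(closed, selem).pixels, closed.pixels
    )


class TestLabelDroplets:
    def test_diagonal_connectivity(self):
        m = mask_of([[1, 0], [0, 1]])
        assert len(label_droplets(m, connectivity=8)) == 1
        assert len(label_droplets(m, connectivity=4)) == 2

    def test_empty(self):
        assert label_droplets(mask_of(np.zeros((3, 3)))) == []

    def test_three_squares(self):
        m = np.zeros((10, 10), dtype=bool)
        for r, c in [(0, 0), (0, 7), (7, 0)]:
            m[r : r + 2, c : c + 2] = True
        records = label_droplets(mask_of(m))
        assert len(records) == 3
        assert all(r.area_px == 4 for r in records)
        assert len({r.label for r in records}) == 3

    def test_area_sum_matches_mask(self, rng):
        m = mask_of(rng.random((30, 30)) < 0.3)
        records = label_droplets(m)
        assert sum(r.area_px for r in records) == m.foreground_px

    def test_bbox_contains_centroid(self, rng):
        m = mask_of(rng.random((20, 20)) < 0.3)
        for r in label_droplets(m):
            r0, c0, r1, c1 = r.bbox
            assert r0 <= r.centroid[0] < r1
            assert c0 <= r.centroid[1] < c1

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_droplets(mask_of(np.zeros((2, 2))), connectivity=6)


class TestCoverageDensity:
    def test_quarter_coverage(self):
        m = np.zeros((10, 10), dtype=bool)
        m.ravel()[:25] = True
        assert coverage(mask_of(m)) == 25.0

    def test_extremes(self):
        assert coverage(mask_of(np.ones((5, 5)))) == 100.0
        assert coverage(mask_of(np.zeros((5, 5)))) == 0.0

    def test_density_zero_records(self):
        assert density([], 5.0) == 0.0

    def test_density_wsp_card(self):
        area = 287 * 98 * (25.4 / 96) ** 2 / 100  # ~19.69 cm^2
        records = [object()] * 100
        assert density(records, area) == pytest.approx(100 / area, rel=1e-12)
        assert density(records, area) == pytest.approx(5.08, abs=0.01)

    def test_density_simple(self):
        assert density([object()] * 50, 10.0) == 5.0

    def test_density_invalid_area(self):
        with pytest.raises(ValueError):
            density([], 0.0)


class TestClassifyPaGroup:
    @pytest.mark.parametrize(
        "pa,expected",
        [
            (0, "sparse"),
            (12_000, "sparse"),
            (12_001, "medium"),
            (40_000, "medium"),
            (40_001, "dense"),
            (89_999, "dense"),
        ],
    )
    def test_printed_boundaries(self, pa, expected):
        assert classify_pa_group(pa) == expected

    def test_above_printed_range_warns_dense(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert classify_pa_group(90_000) == "dense"
            assert classify_pa_group(150_000) == "dense"
        assert sum("dense" in r.message for r in caplog.records) == 2

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_pa_group(-1)


class TestFilterSmallDroplets:
    def test_removes_specks(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0, 0] = True  # single-pixel speck
        m[5:8, 5:8] = True
        filtered = filter_small_droplets(mask_of(m), 2)
        assert filtered.foreground_px == 9

    def test_zero_threshold_is_identity(self, rng):
        m = mask_of(rng.random((15, 15)) < 0.3)
        np.testing.assert_array_equal(filter_small_droplets(m, 0).pixels, m.pixels)


@pytest.fixture(scope="module")
def clean_scene():
    spec = SyntheticSpec(
        seed=31, n_droplets=20, width_px=400, height_px=200,
        noise_sigma=0.0, min_center_distance_px=40,
    )
    return generate_wsp(spec)


class TestAnalyzeImage:
    @pytest.mark.parametrize("method", ["fixed", "otsu", "genetic_otsu"])
    def test_exact_truth_recovery(self, clean_scene, method):
        img, truth = clean_scene
        ga = GAConfig(seed=9) if method == "genetic_otsu" else None
        report = analyze_image(img, method, ga_config=ga)
        assert truth.n_droplets_placed == 20
        assert report.droplet_count == truth.n_droplets_placed
        assert report.coverage_pct == truth.coverage_pct

    def test_blank_background(self):
        img, _ = generate_wsp(SyntheticSpec(seed=1, n_droplets=0, noise_sigma=2.0))
        report = analyze_image(img, "fixed")
        assert report.droplet_count == 0
        assert report.coverage_pct == 0.0
        assert report.density_per_cm2 == 0.0
        assert report.pa_group == "sparse"

    def test_determinism(self, clean_scene):
        img, _ = clean_scene
        a = analyze_image(img, "genetic_otsu", ga_config=GAConfig(seed=5))
        b = analyze_image(img, "genetic_otsu", ga_config=GAConfig(seed=5))
        assert a == b

    def test_method_config_mismatch(self, clean_scene):
        img, _ = clean_scene
        with pytest.raises(ValueError):
            analyze_image(img, "genetic_otsu")  # missing ga_config
        with pytest.raises(ValueError):
            analyze_image(img, "otsu", ga_config=GAConfig(seed=1))
        with pytest.raises(ValueError):
            analyze_image(img, "watershed")

    def test_count_zero_implies_zero_metrics(self):
        img = image_from(np.full((20, 20), 220))
        report = analyze_image(img, "fixed")
        assert report.droplet_count == 0
        assert report.coverage_pct == 0.0 and report.density_per_cm2 == 0.0


class TestTranslationInvariance:
    def test_shifted_content_same_metrics(self):
        base = np.zeros((40, 40), dtype=bool)
        base[5:12, 6:15] = True
        base[20:24, 25:30] = True
        shifted = np.roll(np.roll(base, 7, axis=0), 9, axis=1)
        for m in (base, shifted):
            records = label_droplets(mask_of(m))
            assert len(records) == 2
            assert sorted(r.area_px for r in records) == [20, 63]
        assert coverage(mask_of(base)) == coverage(mask_of(shifted))


class TestGlareRepair:
    def test_holes_repaired_exactly(self):
        spec = SyntheticSpec(
            seed=17, n_droplets=15, width_px=400, height_px=200,
            noise_sigma=0.0, glare_hole_prob=1.0, min_center_distance_px=40,
        )
        img, truth = generate_wsp(spec)
        raw = DropletMask(pixels=img.pixels < 150)
        assert coverage(raw) < truth.coverage_pct  # holes bite before repair
        closed = morphological_close(raw)
        assert coverage(closed) == truth.coverage_pct
        np.testing.assert_array_equal(closed.pixels, truth.mask.pixels)
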