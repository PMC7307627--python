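import numpy as np
import pytest
from scipy import ndimage

from histotensor import (CellCountConfig, HistoImage, NisslImageSpec,
                         count_and_density, extract_markers, gen_nissl_image,
                         marker_intensity_image, preliminary_segmentation,
                         segment_cells, speed_image, triage_components,
                         watershed_correct)
from histotensor.cell_counting import CellDensity


def _draw_ellipse(shape, center, major, minor, angle=0.0):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    dr, dc = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    uu = dc * ca + dr * sa
    vv = -dc * sa + dr * ca
    return ((uu / (major / 2)) ** 2 + (vv / (minor / 2)) ** 2) <= 1.0


class TestSpeedImage:
    def test_constant_green_channel_gives_zero_field(self):
        img = np.zeros((32, 32, 3))
        img[..., 1] = 0.5
        img[..., 0] = np.random.default_rng(0).random((32, 32))  # red ignored
        assert np.allclose(speed_image(img), 0.0)

    def test_step_edge_peaks_on_edge_columns(self):
        img = np.zeros((32, 32, 3))
        img[:, 16:, 1] = 1.0
        sp = speed_image(img)
        peak_cols = set(np.nonzero(sp == sp.max())[1])
        assert peak_cols <= {15, 16}

    def test_grayscale_requires_channel_override(self):
        with pytest.raises(ValueError, match="channel"):
            speed_image(np.zeros((16, 16)))
        assert speed_image(np.zeros((16, 16)), channel=0).shape == (16, 16)


class TestPreliminarySegmentation:
    def test_blank_image_yields_no_components(self):
        img = np.full((128, 128, 3), 0.9)
        with pytest.warns(UserWarning, match="single phase"):
            labels = preliminary_segmentation(img, CellCountConfig())
        assert labels.max() == 0

    def test_separated_cells_each_form_one_component(self):
        img, truth = gen_nissl_image(NisslImageSpec(
            size=420, n_cells=4, fraction_touching=0.0, seed=5))
        labels = preliminary_segmentation(img, CellCountConfig())
        comps = [c for c in triage_components(labels) if c.status == "accepted"]
        assert len(comps) == truth["n_cells"]

    def test_count_stable_across_seeds(self):
        img, truth = gen_nissl_image(NisslImageSpec(
            size=420, n_cells=4, fraction_touching=0.0, seed=6))
        counts = {segment_cells(img, CellCountConfig(rng_seed=s)).cell_count
                  for s in range(5)}
        assert counts == {truth["n_cells"]}


class TestTriage:
    @pytest.mark.parametrize("major, expected", [
        (24, "noise"),        # below S = 30
        (36, "accepted"),     # just above S
        (60, "accepted"),
        (132, "accepted"),    # just below B = 140
        (150, "under_segmented"),  # above B
    ])
    def test_major_axis_thresholds(self, major, expected):
        shape = (220, 220)
        labels = _draw_ellipse(shape, (110, 110), major, 0.6 * major).astype(int)
        comps = triage_components(labels, CellCountConfig())
        assert len(comps) == 1
        assert comps[0].status == expected

    def test_fused_dumbbell_is_under_segmented(self):
        shape = (256, 256)
        blob = (_draw_ellipse(shape, (128, 90), 80, 50)
                | _draw_ellipse(shape, (128, 170), 80, 50))
        comps = triage_components(blob.astype(int), CellCountConfig())
        assert comps[0].status == "under_segmented"
        assert comps[0].major_axis > 140

    def test_relaxing_s_never_decreases_accepted(self):
        img, _ = gen_nissl_image(NisslImageSpec(size=420, n_cells=4,
                                                fraction_touching=0.0, seed=9))
        labels = preliminary_segmentation(img, CellCountConfig())
        strict = triage_components(labels, CellCountConfig(S=40))
        relaxed = triage_components(labels, CellCountConfig(S=20))
        n_strict = sum(c.status != "noise" for c in strict)
        n_relaxed = sum(c.status != "noise" for c in relaxed)
        assert n_relaxed >= n_strict

    def test_growing_b_never_increases_under_segmented(self):
        shape = (256, 256)
        blob = (_draw_ellipse(shape, (128, 90), 80, 50)
                | _draw_ellipse(shape, (128, 170), 80, 50)).astype(int)
        low = triage_components(blob, CellCountConfig(B=120))
        high = triage_components(blob, CellCountConfig(B=200))
        n_low = sum(c.status == "under_segmented" for c in low)
        n_high = sum(c.status == "under_segmented" for c in high)
        assert n_high <= n_low


def _two_bump_intensity(shape=(200, 200), centers=((100, 60), (100, 140)),
                        heights=(0.9, 0.8), sigma=18.0):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    field = np.zeros(shape)
    for (cy, cx), h in zip(centers, heights):
        field = np.maximum(
            field, h * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma**2)))
    return field


class TestMarkerIntensityImage:
    def test_gray_image_value_channel(self):
        img = np.full((32, 32, 3), 0.6)
        out = marker_intensity_image(img)
        # constant image: inverted and rescaled to all zeros
        assert np.allclose(out, 0.0)

    def test_dark_cell_becomes_single_maximum(self):
        img, _ = gen_nissl_image(NisslImageSpec(size=300, n_cells=1,
                                                fraction_touching=0.0, seed=2,
                                                noise_sd=0.0))
        out = marker_intensity_image(img)
        peaks = (ndimage.maximum_filter(out, size=15) == out) & (out > 0.5)
        lbl, n = ndimage.label(peaks)
        assert n == 1

    def test_matches_separable_gaussian_oracle(self, rng):
        img = rng.random((48, 48, 3))
        cfg = CellCountConfig(marker_sigma=3.0)
        out = marker_intensity_image(img, cfg)
        v = img.max(axis=-1)  # HSV value channel of RGB
        radius = int(4.0 * cfg.marker_sigma + 0.5)
        u = np.arange(-radius, radius + 1)
        k = np.exp(-u**2 / (2 * cfg.marker_sigma**2))
        k /= k.sum()
        padded = np.pad(v, radius, mode="symmetric")
        tmp = np.apply_along_axis(lambda r: np.convolve(r, k, "valid"), 1, padded)
        ref = np.apply_along_axis(lambda c: np.convolve(c, k, "valid"), 0, tmp)
        inv = ref.max() - ref
        ref_out = (inv - inv.min()) / (inv.max() - inv.min())
        assert np.allclose(out, ref_out, atol=1e-10)


class TestExtractMarkers:
    def test_single_interior_maximum(self):
        field = _two_bump_intensity(centers=((100, 100),), heights=(0.9,))
        mask = field > 0.05
        markers = extract_markers(field, mask, CellCountConfig())
        assert len(markers) == 1
        assert markers[0][2] == pytest.approx(0.9, abs=0.01)

    def test_intensity_floor_drops_dim_marker(self):
        field = _two_bump_intensity(heights=(0.9, 0.4))
        markers = extract_markers(field, field > 0.02, CellCountConfig(I=0.5))
        assert len(markers) == 1
        field2 = _two_bump_intensity(heights=(0.9, 0.55))
        markers2 = extract_markers(field2, field2 > 0.02, CellCountConfig(I=0.5))
        assert len(markers2) == 2

    def test_spatial_separation_keeps_brighter(self):
        close = _two_bump_intensity(centers=((100, 80), (100, 120)),
                                    heights=(0.9, 0.8), sigma=12.0)
        markers = extract_markers(close, close > 0.02, CellCountConfig(D_s=70))
        assert len(markers) == 1
        assert markers[0][2] == pytest.approx(0.9, abs=0.02)
        far = _two_bump_intensity(centers=((100, 50), (100, 150)),
                                  heights=(0.9, 0.8), sigma=12.0)
        markers = extract_markers(far, far > 0.02, CellCountConfig(D_s=70))
        assert len(markers) == 2

    def test_intensity_distance_rule_on_8bit_scale(self):
        # peaks differing by 0.5/255 merge; differing by 3/255 survive
        near = _two_bump_intensity(centers=((100, 50), (100, 150)),
                                   heights=(0.9, 0.9 - 0.5 / 255), sigma=12.0)
        markers = extract_markers(near, near > 0.02, CellCountConfig(D_i=1.0))
        assert len(markers) == 1
        apart = _two_bump_intensity(centers=((100, 50), (100, 150)),
                                    heights=(0.9, 0.9 - 3.0 / 255), sigma=12.0)
        markers = extract_markers(apart, apart > 0.02, CellCountConfig(D_i=1.0))
        assert len(markers) == 2


class TestWatershedCorrect:
    def test_single_marker_keeps_component_whole(self):
        field = _two_bump_intensity(centers=((100, 100),), heights=(0.9,))
        mask = field > 0.05
        sub = watershed_correct(mask, [(100.0, 100.0, 0.9)], field)
        assert set(np.unique(sub[mask])) == {1}
        assert (sub > 0).sum() == mask.sum()

    def test_symmetric_pair_splits_evenly(self):
        field = _two_bump_intensity(heights=(0.9, 0.89), sigma=25.0)
        mask = field > 0.05
        markers = [(100.0, 60.0, 0.9), (100.0, 140.0, 0.89)]
        sub = watershed_correct(mask, markers, field)
        areas = [(sub == i).sum() for i in (1, 2)]
        assert abs(areas[0] / areas[1] - 1) < 0.2
        assert (sub > 0).sum() == mask.sum()

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_k_markers_give_k_sublabels(self, k):
        centers = [(100.0, 20.0 + 40.0 * i) for i in range(k)]
        field = _two_bump_intensity(centers=centers, heights=[0.9] * k, sigma=10.0)
        mask = field > 0.01
        markers = [(r, c, 0.9) for r, c in centers]
        sub = watershed_correct(mask, markers, field)
        assert len(set(np.unique(sub[mask]))) == k

    def test_marker_outside_component_rejected(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError, match="outside"):
            watershed_correct(mask, [(40.0, 40.0, 0.9)], np.zeros((50, 50)))


class TestCountAndDensity:
    def test_density_closed_form(self):
        dens = CellDensity.from_counts(100, 20000.0)
        assert dens.rho == pytest.approx(0.5e-2)
        assert CellDensity.from_counts(0, 100.0).rho == 0.0

    def test_rho_scales_inversely_with_area(self):
        big = CellDensity.from_counts(10, 4000.0)
        small = CellDensity.from_counts(10, 2000.0)
        assert small.rho == pytest.approx(2 * big.rho)

    def test_empty_mask_rejected(self):
        img, _ = gen_nissl_image(NisslImageSpec(size=300, n_cells=1, seed=0,
                                                fraction_touching=0.0))
        with pytest.raises(ValueError, match="empty"):
            count_and_density(img, roi_mask=np.zeros((300, 300), dtype=bool))

    def test_roi_restriction_counts_centroids_inside(self):
        img, truth = gen_nissl_image(NisslImageSpec(
            size=420, n_cells=4, fraction_touching=0.0, seed=8))
        result = segment_cells(img, CellCountConfig())
        full = count_and_density(img, result=result)
        assert full.n_cells == truth["n_cells"]
        half = np.zeros((420, 420), dtype=bool)
        half[:, :210] = True
        in_left = sum(1 for r, c in truth["centroids"] if c < 210)
        left = count_and_density(img, roi_mask=half, result=result)
        assert left.n_cells == in_left
        assert left.area_um2 == pytest.approx(half.sum() * img.pixel_area)

    def test_translation_invariance_of_count(self):
        img, truth = gen_nissl_image(NisslImageSpec(
            size=420, n_cells=3, fraction_touching=0.0, seed=12))
        shifted = HistoImage(pixels=np.roll(img.pixels, (7, -5), axis=(0, 1)),
                             pixel_area=img.pixel_area, stain="nissl")
        n0 = segment_cells(img, CellCountConfig()).cell_count
        n1 = segment_cells(shifted, CellCountConfig()).cell_count
        assert n0 == n1 == truth["n_cells"]


class TestEndToEndSplitting:
    def test_touching_pair_is_detected_and_split(self):
        img, truth = gen_nissl_image(NisslImageSpec(
            size=480, n_cells=4, fraction_touching=0.5, seed=21))
        result = segment_cells(img, CellCountConfig())
        under = [c for c in result.components if c.status == "under_segmented"]
        assert len(under) == len(truth["pairs"])
        assert all(c.n_cells == 2 for c in under)
        assert result.cell_count == truth["n_cells"]

    def test_watershed_never_merges_or_leaks(self):
        img, _ = gen_nissl_image(NisslImageSpec(
            size=480, n_cells=4, fraction_touching=0.5, seed=22))
        result = segment_cells(img, CellCountConfig())
        prelim, final = result.preliminary_labels, result.final_labels
        for lab in np.unique(final[final > 0]):
            parents = np.unique(prelim[final == lab])
            assert len(parents) == 1 and parents[0] > 0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="S < B"):
            CellCountConfig(S=150, B=140)
        with pytest.raises(ValueError, match="I must"):
            CellCountConfig(I=1.5)
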