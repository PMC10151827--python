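"""Watershed segmentation, ridge QC, area filtering, and morphometry."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from epimorph import cells, imaging
from epimorph.synth import region_ellipse_stats

from conftest import PX, permissive_params


def proj_of(img, plane="apical", px=PX):
    return imaging.Projection(np.asarray(img, float), plane, px)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    @pytest.mark.parametrize("plane", ["apical", "basal"])
    def test_constant_image_unchanged(self, plane):
        img = np.full((32, 32), 500.0)
        out = cells.preprocess(proj_of(img, plane), cells.SegmentationParams(plane_name=plane))
        np.testing.assert_allclose(out.image, img)

    def test_apical_removes_isolated_bright_pixel(self):
        img = np.full((32, 32), 500.0)
        img[16, 16] = 5000.0
        out = cells.preprocess(proj_of(img), cells.SegmentationParams(plane_name="apical"))
        assert out.image[16, 16] == pytest.approx(500.0)

    def test_basal_matches_direct_local_statistics_filter(self):
        """The adaptive filter equals the textbook local mean/variance form."""
        rng = np.random.default_rng(0)
        img = rng.uniform(400, 600, size=(20, 20))
        params = cells.SegmentationParams(plane_name="basal", wiener_window_px=3)
        out = cells.preprocess(proj_of(img, "basal"), params).image

        p = np.pad(img, 1, mode="reflect")
        mu = ndi.uniform_filter(p, 3, mode="constant")
        var = ndi.uniform_filter(p * p, 3, mode="constant") - mu * mu
        noise = var.mean()
        expected = mu + np.where(var < noise, 0.0,
                                 (var - noise) / np.where(var == 0, 1, var)) * (p - mu)
        np.testing.assert_allclose(out, expected[1:-1, 1:-1], atol=1e-8)

    def test_unknown_plane_error(self):
        with pytest.raises(ValueError, match="plane"):
            cells.preprocess(proj_of(np.zeros((8, 8))),
                             cells.SegmentationParams(plane_name="fiber"))


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------

class TestSegmentCells:
    def test_recovers_synthetic_cell_count(self, cell_field_small):
        spec, image, truth = cell_field_small
        lmap = cells.segment_cells(proj_of(image), permissive_params())
        assert lmap.n_cells == truth.n_cells == 50

    def test_uniform_image_single_label(self):
        lmap = cells.segment_cells(proj_of(np.full((20, 20), 7.0)),
                                   permissive_params())
        assert lmap.n_cells == 1
        assert (lmap.labels == 1).all()

    def test_deterministic(self, cell_field_small):
        _, image, _ = cell_field_small
        l1 = cells.segment_cells(proj_of(image), permissive_params())
        l2 = cells.segment_cells(proj_of(image), permissive_params())
        np.testing.assert_array_equal(l1.labels, l2.labels)


# ---------------------------------------------------------------------------
# ridge QC
# ---------------------------------------------------------------------------

def three_strip_image(dim_middle):
    """Three vertical cells separated by two straight ridges."""
    img = np.full((100, 150), 1000.0)
    img[:, 49:52] = 12000.0
    img[:, 99:102] = 4000.0 if dim_middle else 12000.0
    return img


class TestQcBoundaries:
    def test_dim_ridge_dissolved(self):
        img = three_strip_image(dim_middle=True)
        params = permissive_params(min_ridge_intensity_pct=30.0)
        lmap = cells.segment_cells(proj_of(img), params)
        assert lmap.n_cells == 3
        out = cells.qc_boundaries(lmap, proj_of(img), params)
        assert out.n_cells == 2

    def test_all_pass_returns_input_unchanged(self):
        img = three_strip_image(dim_middle=False)
        params = permissive_params(min_ridge_intensity_pct=30.0)
        lmap = cells.segment_cells(proj_of(img), params)
        out = cells.qc_boundaries(lmap, proj_of(img), params)
        np.testing.assert_array_equal(out.labels, lmap.labels)

    def test_straight_ridge_tortuosity_is_one(self):
        path = [(r, 10) for r in range(20)]
        plen, tort = cells._path_stats(path, PX)
        assert tort == pytest.approx(1.0)
        assert plen == pytest.approx(19 * PX)

    def test_qc_never_increases_count(self, cell_field_small):
        _, image, _ = cell_field_small
        params = permissive_params(min_ridge_intensity_pct=30.0,
                                   min_ridge_len_um=3.0)
        lmap = cells.segment_cells(proj_of(image), params)
        out = cells.qc_boundaries(lmap, proj_of(image), params)
        assert out.n_cells <= lmap.n_cells


# ---------------------------------------------------------------------------
# area filter
# ---------------------------------------------------------------------------

class TestFilterByArea:
    def test_unbounded_is_identity(self, cell_field_small):
        _, image, _ = cell_field_small
        lmap = cells.segment_cells(proj_of(image), permissive_params())
        out = cells.filter_by_area(lmap, 0.0, math.inf)
        np.testing.assert_array_equal(out.labels, lmap.labels)

    def test_small_label_removed(self):
        labels = np.zeros((60, 60), np.int32)
        labels[5:45, 5:45] = 1          # 400 µm² at 0.5 µm/px
        labels[50:54, 50:55] = 2        # 5 µm²
        lmap = cells.CellLabelMap(labels, PX)
        out = cells.filter_by_area(lmap, 50.0, math.inf)
        assert out.n_cells == lmap.n_cells - 1 == 1

    def test_everything_excluded(self):
        labels = np.ones((10, 10), np.int32)
        out = cells.filter_by_area(cells.CellLabelMap(labels, PX), 1e6, 1e7)
        assert out.n_cells == 0


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def metrics_of(labels, px=PX):
    return cells.cell_morphology(cells.CellLabelMap(labels.astype(np.int32), px))


class TestCellMorphology:
    def test_rectangle_ar_exact(self):
        """Closed-form second moments of a 40x20 rectangle give AR = 2."""
        labels = np.zeros((60, 80), np.int32)
        labels[10:30, 10:50] = 1
        m = metrics_of(labels)
        assert m.cells["aspect_ratio"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_disk_ar_near_one(self):
        yy, xx = np.mgrid[:101, :101]
        labels = ((yy - 50) ** 2 + (xx - 50) ** 2 <= 40 ** 2).astype(np.int32)
        m = metrics_of(labels)
        assert m.cells["aspect_ratio"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_single_pixel_ar_is_one(self):
        labels = np.zeros((5, 5), np.int32)
        labels[2, 2] = 1
        m = metrics_of(labels)
        assert m.cells["aspect_ratio"].iloc[0] == pytest.approx(1.0)

    def test_density_arithmetic(self):
        # 50 cells in a 563x356 µm FOV -> 50 / 0.200428 mm²
        labels = np.zeros((356, 563), np.int32)
        for i in range(50):
            r, c = divmod(i, 10)
            labels[r * 40 + 5:r * 40 + 15, c * 50 + 5:c * 50 + 15] = i + 1
        m = metrics_of(labels, px=1.0)
        assert m.density_per_mm2 == pytest.approx(50 / 0.200428, rel=1e-4)

    def test_ar_invariant_under_rotation_and_rescale(self):
        labels = np.zeros((60, 80), np.int32)
        labels[10:30, 10:50] = 1
        ar0 = metrics_of(labels, px=0.5).cells["aspect_ratio"].iloc[0]
        ar90 = metrics_of(np.rot90(labels), px=0.5).cells["aspect_ratio"].iloc[0]
        ar_rescaled = metrics_of(labels, px=2.0).cells["aspect_ratio"].iloc[0]
        assert ar90 == pytest.approx(ar0, abs=1e-12)
        assert ar_rescaled == pytest.approx(ar0, abs=1e-12)

    def test_areas_do_not_exceed_fov(self, cell_field_small):
        _, image, _ = cell_field_small
        lmap, m = cells.segment_pipeline(proj_of(image), permissive_params(),
                                         apply_qc=False)
        assert m.cells["area_um2"].sum() <= lmap.fov_width_um * lmap.fov_height_um + 1e-9


class TestEllipseOracle:
    @pytest.mark.parametrize("a,b", [(40, 20), (30, 10), (16, 16)])
    def test_rectangle_closed_form(self, a, b):
        """AR of an a x b rectangle equals a/b under the unit-square model."""
        yy, xx = np.mgrid[:b, :a]
        coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        ar, theta, n = region_ellipse_stats(coords)
        assert n == a * b
        assert ar == pytest.approx(max(a, b) / min(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# end-to-end parameter recovery
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("target_ar", [1.5, 2.0])
def test_pipeline_recovers_truth_shape(target_ar):
    from epimorph import synth
    spec = synth.CellFieldSpec(fov_width_um=250.0, fov_height_um=250.0,
                               pixel_size_um=0.5, n_cells=100,
                               target_ar=target_ar, noise_sd=0.0, rng_seed=3)
    image, truth = synth.generate_cell_field(spec)
    _, metrics = cells.segment_pipeline(proj_of(image), permissive_params(),
                                        apply_qc=False)
    assert abs(metrics.n_cells - truth.n_cells) <= 0.02 * truth.n_cells
    truth_ar = truth.cells["aspect_ratio"].mean()
    assert metrics.mean_ar == pytest.approx(truth_ar, rel=0.10)
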