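"""Fiber tracing, joining, orientation fields, and the alignment AUC."""

import math

import numpy as np
import pytest

from epimorph import cells, fibers, imaging

from conftest import draw_segments


def fiber_proj(img, px=0.25):
    return imaging.Projection(np.asarray(img, float), "fiber", px)


# ---------------------------------------------------------------------------
# boundary masking
# ---------------------------------------------------------------------------

class TestMaskCellBoundaries:
    def test_empty_label_map_changes_nothing(self):
        img = np.full((40, 40), 2000.0)
        proj = fiber_proj(img, px=0.5)
        lmap = cells.CellLabelMap(np.zeros((40, 40), np.int32), 0.5)
        out = fibers.mask_cell_boundaries(proj, lmap, 1.5)
        np.testing.assert_array_equal(out.image, img)
        assert out.searched_area_um2 == pytest.approx(40 * 40 * 0.25)

    def test_straight_ridge_masks_three_px_band(self):
        labels = np.ones((40, 40), np.int32)
        labels[:, 20] = 0
        labels[:, 21:] = 2
        proj = fiber_proj(np.full((40, 40), 2000.0), px=0.5)
        out = fibers.mask_cell_boundaries(proj, cells.CellLabelMap(labels, 0.5), 1.5)
        assert (out.image[:, 19:22] == 0).all()
        assert (out.image[:, :19] == 2000).all() and (out.image[:, 22:] == 2000).all()
        assert out.excluded_mask.sum() == 3 * 40

    def test_idempotent(self):
        labels = np.ones((40, 40), np.int32)
        labels[:, 20] = 0
        labels[:, 21:] = 2
        proj = fiber_proj(np.full((40, 40), 2000.0), px=0.5)
        lmap = cells.CellLabelMap(labels, 0.5)
        once = fibers.mask_cell_boundaries(proj, lmap, 1.5)
        twice = fibers.mask_cell_boundaries(once, lmap, 1.5)
        np.testing.assert_array_equal(once.image, twice.image)
        np.testing.assert_array_equal(once.excluded_mask, twice.excluded_mask)

    def test_shape_mismatch_error(self):
        proj = fiber_proj(np.zeros((10, 10)))
        lmap = cells.CellLabelMap(np.zeros((8, 8), np.int32), 0.25)
        with pytest.raises(ValueError, match="shape"):
            fibers.mask_cell_boundaries(proj, lmap)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

class TestTraceFragments:
    def test_single_straight_line_length(self):
        # 50 µm segment at 0.25 µm/px
        img = draw_segments((120, 240), [(20, 60, 220, 60)])
        frags = fibers.trace_fragments(fiber_proj(img))
        assert len(frags) == 1
        assert frags[0].length_um == pytest.approx(200 * 0.25, abs=1.0)

    def test_crossing_lines_yield_two_fragments(self, crossing_image):
        frags = fibers.trace_fragments(crossing_image)
        assert len(frags) == 2
        truth = math.hypot(160, 160) * 0.25
        for f in frags:
            assert f.length_um == pytest.approx(truth, rel=0.05)

    def test_blank_image_empty(self):
        assert fibers.trace_fragments(fiber_proj(np.full((50, 50), 900.0))) == []

    def test_short_fragments_discarded(self):
        img = draw_segments((60, 60), [(28, 30, 31, 30)])  # 0.75 µm
        frags = fibers.trace_fragments(
            fiber_proj(img), fibers.TracerParams(min_length_um=1.0))
        assert frags == []


# ---------------------------------------------------------------------------
# joining
# ---------------------------------------------------------------------------

def make_fragment(p0, p1, intensity=12000.0, n=20):
    pts = np.linspace(p0, p1, n)
    v = np.asarray(p1) - np.asarray(p0)
    tan = math.atan2(v[1], v[0]) % math.pi
    return fibers.FiberFragment(points=pts, length_um=float(np.hypot(*v)),
                                mean_intensity=intensity,
                                tangent_start=tan, tangent_end=tan)


class TestJoinFragments:
    def collinear_setup(self, bright_connector):
        """Two collinear 10 µm fragments with a 2 µm gap at y = 10 µm."""
        # image in px at 0.25 µm/px: fragments [4,44] and [52,92] px, gap 8 px
        segs = [(4, 40, 44, 40), (52, 40, 92, 40)]
        if bright_connector:
            segs.append((44, 40, 52, 40))
        img = draw_segments((80, 100), segs)
        proj = fiber_proj(img)
        fa = make_fragment((1.0, 10.0), (11.0, 10.0))
        fb = make_fragment((13.0, 10.0), (23.0, 10.0))
        return proj, [fa, fb]

    def test_bright_connector_joins(self):
        proj, frags = self.collinear_setup(bright_connector=True)
        fs = fibers.join_fragments(frags, proj)
        assert fs.n_fibers == 1
        assert fs.fibers[0].length_um == pytest.approx(22.0, abs=0.1)

    def test_dark_connector_rejected(self):
        proj, frags = self.collinear_setup(bright_connector=False)
        fs = fibers.join_fragments(frags, proj)
        assert fs.n_fibers == 2

    def test_perpendicular_tangents_rejected(self):
        img = np.full((80, 100), 12000.0)  # bright everywhere: intensity passes
        proj = fiber_proj(img)
        fa = make_fragment((1.0, 10.0), (11.0, 10.0))
        fb = make_fragment((12.0, 11.0), (12.0, 21.0))
        fs = fibers.join_fragments([fa, fb], proj)
        assert fs.n_fibers == 2

    def test_total_length_never_decreases(self):
        proj, frags = self.collinear_setup(bright_connector=True)
        fs = fibers.join_fragments(frags, proj)
        assert fs.total_length_um >= sum(f.length_um for f in frags) - 1e-9

    def test_order_independent(self):
        proj, frags = self.collinear_setup(bright_connector=True)
        fs1 = fibers.join_fragments(frags, proj)
        fs2 = fibers.join_fragments(frags[::-1], proj)
        assert sorted(round(f.length_um, 6) for f in fs1.fibers) == \
               sorted(round(f.length_um, 6) for f in fs2.fibers)

    def test_chain_of_three(self):
        img = np.full((80, 200), 12000.0)
        proj = fiber_proj(img)
        frags = [make_fragment((x, 10.0), (x + 10.0, 10.0))
                 for x in (1.0, 13.0, 25.0)]
        fs = fibers.join_fragments(frags, proj)
        assert fs.n_fibers == 1
        assert fs.fibers[0].length_um == pytest.approx(34.0, abs=0.1)


class TestLengthMetrics:
    def test_arithmetic(self):
        fs = fibers.FiberSet([make_fragment((0, 0), (3, 0)),
                              make_fragment((0, 1), (5, 1))], 100.0)
        mean, density = fibers.length_metrics(fs)
        assert mean == pytest.approx(4.0)
        assert density == pytest.approx(0.08)

    def test_empty_set(self):
        mean, density = fibers.length_metrics(fibers.FiberSet([], 50.0))
        assert mean is None
        assert density == 0.0

    def test_zero_area_error(self):
        with pytest.raises(ValueError):
            fibers.length_metrics(fibers.FiberSet([], 0.0))


# ---------------------------------------------------------------------------
# orientation field
# ---------------------------------------------------------------------------

def stripe_image(deg, shape=(300, 300), px=0.5, period_um=4.0):
    th = math.radians(deg)
    yy, xx = np.mgrid[: shape[0], : shape[1]] * px
    phase = -math.sin(th) * xx + math.cos(th) * yy
    return 1000 + 10000 * (0.5 + 0.5 * np.sin(2 * math.pi * phase / period_um))


class TestOrientationField:
    @pytest.mark.parametrize("deg", [0, 30, 77, 123])
    def test_stripes_report_their_angle(self, deg):
        of = fibers.orientation_field(fiber_proj(stripe_image(deg), px=0.5))
        _, theta = of.valid_points()
        err = np.degrees(np.abs((theta - math.radians(deg) + math.pi / 2)
                                % math.pi - math.pi / 2))
        assert of.n_valid > 100
        assert err.max() <= 2.0

    def test_axial_equivalence_mod_180(self):
        of1 = fibers.orientation_field(fiber_proj(stripe_image(30), px=0.5))
        of2 = fibers.orientation_field(fiber_proj(stripe_image(210), px=0.5))
        np.testing.assert_allclose(of1.theta[of1.valid], of2.theta[of2.valid],
                                   atol=1e-6)

    def test_constant_image_all_masked(self):
        of = fibers.orientation_field(fiber_proj(np.full((60, 60), 5.0), px=0.5))
        assert of.n_valid == 0

    def test_excluded_mask_invalidates_subregions(self):
        img = stripe_image(30)
        proj = fiber_proj(img, px=0.5)
        proj.excluded_mask = np.zeros_like(img, bool)
        proj.excluded_mask[:30, :30] = True
        of = fibers.orientation_field(proj)
        assert not of.valid[:5, :5].any()

    def test_subregion_larger_than_image_error(self):
        with pytest.raises(ValueError, match="larger"):
            fibers.orientation_field(fiber_proj(np.zeros((10, 10)), px=0.5),
                                     subregion_um=100.0)


# ---------------------------------------------------------------------------
# alignment AUC
# ---------------------------------------------------------------------------

def grid_field(theta, nx=20, ny=20, spacing=3.0):
    theta = np.asarray(theta, float)
    if theta.ndim == 2:
        ny, nx = theta.shape
    th = np.broadcast_to(theta, (ny, nx)).copy()
    return fibers.OrientationField(
        theta=th, valid=np.ones((ny, nx), bool),
        centers_x_um=(np.arange(nx) + 0.5) * spacing,
        centers_y_um=(np.arange(ny) + 0.5) * spacing,
        subregion_um=spacing)


class TestAlignmentAuc:
    def test_identical_orientations_auc_exactly_zero(self):
        curve = fibers.alignment_auc(grid_field(0.7), rng_seed=0)
        np.testing.assert_allclose(curve.experimental[~np.isnan(curve.experimental)], 1.0)
        np.testing.assert_allclose(curve.null_mean[~np.isnan(curve.null_mean)], 1.0)
        assert curve.auc == 0.0

    def test_iid_uniform_auc_within_null_noise(self):
        rng = np.random.default_rng(123)
        th = rng.uniform(0, math.pi, size=(20, 20))
        curve = fibers.alignment_auc(grid_field(th), n_null_reps=20, rng_seed=5)
        assert abs(curve.auc) < 3 * curve.null_auc_se + 1e-12

    def test_alignment_values_bounded(self):
        rng = np.random.default_rng(7)
        th = rng.uniform(0, math.pi, size=(15, 15))
        curve = fibers.alignment_auc(grid_field(th), rng_seed=2)
        ok = ~np.isnan(curve.experimental)
        assert (curve.experimental[ok] >= -1 - 1e-12).all()
        assert (curve.experimental[ok] <= 1 + 1e-12).all()

    def test_auc_invariant_under_global_rotation(self):
        rng = np.random.default_rng(11)
        th = rng.uniform(0, math.pi, size=(15, 15))
        c1 = fibers.alignment_auc(grid_field(th), rng_seed=3)
        c2 = fibers.alignment_auc(grid_field((th + 0.9) % math.pi), rng_seed=3)
        assert c2.auc == pytest.approx(c1.auc, abs=1e-9)

    def test_patchwise_exceeds_shuffled(self):
        """Locally aligned patches have larger AUC than the same orientation
        multiset randomly repositioned."""
        rng = np.random.default_rng(4)
        patch = rng.uniform(0, math.pi, size=(4, 4))
        th = np.repeat(np.repeat(patch, 5, axis=0), 5, axis=1)  # 20x20, 15µm patches
        c_patch = fibers.alignment_auc(grid_field(th), rng_seed=6)
        shuffled = rng.permutation(th.ravel()).reshape(th.shape)
        c_shuf = fibers.alignment_auc(grid_field(shuffled), rng_seed=6)
        assert c_patch.auc > c_shuf.auc

    def test_too_few_valid_error(self):
        f = grid_field(0.0, nx=2, ny=1)
        f.valid[:, 1] = False
        with pytest.raises(ValueError, match="valid"):
            fibers.alignment_auc(f)
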