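"""Shared fixtures: small synthetic fields and constructed image fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from epimorph import imaging, synth
from epimorph.synth import _dist_to_segment

PX = 0.5  # µm/px used by most constructed fixtures


def draw_segments(shape, segments, *, background=1000.0, amplitude=11000.0,
                  sigma_px=0.85):
    """Render bright Gaussian-profile line segments on a constant background.

    ``segments`` are (x0, y0, x1, y1) in pixel coordinates.
    """
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, background, float)
    for x0, y0, x1, y1 in segments:
        d = _dist_to_segment(xx.astype(float), yy.astype(float), x0, y0, x1, y1)
        img += amplitude * np.exp(-0.5 * (d / sigma_px) ** 2)
    return np.clip(img, 0, 65535)


@pytest.fixture(scope="session")
def cell_field_small():
    """Noise-free 50-cell field used by the segmentation tests."""
    spec = synth.CellFieldSpec(
        fov_width_um=180.0, fov_height_um=180.0, pixel_size_um=PX,
        n_cells=50, target_ar=1.0, noise_sd=0.0, rng_seed=42)
    image, truth = synth.generate_cell_field(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def fiber_field_small():
    """200 sparse fibers, truth mean length 3 µm."""
    spec = synth.FiberFieldSpec(
        fov_width_um=150.0, fov_height_um=150.0, pixel_size_um=0.25,
        n_fibers=200, length_mean_um=3.0, length_sd_um=0.5,
        orientation_mode="uniform", rng_seed=1)
    image, truth = synth.generate_fiber_field(spec)
    return spec, image, truth


@pytest.fixture
def crossing_image():
    """Two straight fibers crossing in an X; each spans 56.57 µm."""
    img = draw_segments((200, 200), [(20, 20, 180, 180), (20, 180, 180, 20)])
    return imaging.Projection(img, "fiber", 0.25)


def permissive_params(**overrides):
    """Segmentation parameters with QC/area filters effectively disabled.

    Synthetic tessellations contain legitimately short, uniformly bright
    ridges; the QC defaults target over-segmentation artifacts of real
    images and are exercised by their own constructed fixtures.
    """
    from epimorph.cells import SegmentationParams

    defaults = dict(plane_name="apical", marker_h=500.0,
                    min_ridge_len_um=0.0, min_ridge_intensity_pct=0.0,
                    min_area_um2=0.0, max_area_um2=np.inf)
    defaults.update(overrides)
    return SegmentationParams(**defaults)
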