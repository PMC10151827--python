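"""Synthetic fluorescence-microscopy fields with exported ground truth.

Three generators emulate the data the analysis pipeline consumes:

* :func:`generate_cell_field` — a confluent epithelial plane rendered as
  bright cortical-actin boundaries around dark cell interiors, built from a
  Lloyd-relaxed Voronoi tessellation.  Mean cell elongation is controlled by
  ``target_ar``: seed coordinates are generated in a frame compressed along x
  by that factor, so the tessellation computed under the anisotropic metric
  elongates every cell along x.
* :func:`generate_fiber_field` — a basal stress-fiber plane rendered as
  anti-aliased line segments with Gaussian cross-section, with uniform,
  globally-aligned, or patchwise-aligned orientations.
* :func:`generate_timelapse` — a phase-contrast-like texture advected by an
  analytic flow field (static, translation, rigid rotation, or swirl).

Ground truth is always computed from generator internals (seed geometry,
segment endpoints, the analytic flow map), never from rendered pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "CellFieldSpec",
    "FiberFieldSpec",
    "FlowSpec",
    "CellFieldTruth",
    "FiberFieldTruth",
    "FlowTruth",
    "generate_cell_field",
    "generate_fiber_field",
    "generate_timelapse",
    "region_ellipse_stats",
]

GRAY_MAX = 65535.0


# ---------------------------------------------------------------------------
# cell fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellFieldSpec:
    """Parameters of a synthetic cell-boundary image.

    Defaults follow the static-imaging field of view (563 by 356 µm) with a
    cell density giving mean apical/basal areas in the ~150 µm² range typical
    of a confluent pseudostratified airway epithelium.
    """

    fov_width_um: float = 563.0
    fov_height_um: float = 356.0
    pixel_size_um: float = 0.5
    n_cells: int = 1300
    target_ar: float = 1.0
    boundary_intensity: float = 12000.0
    background_intensity: float = 1500.0
    noise_sd: float = 0.0
    boundary_sigma_um: float = 0.4
    background_gradient: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.target_ar < 1:
            raise ValueError("target_ar must be >= 1")
        if self.boundary_intensity <= self.background_intensity:
            raise ValueError("boundary_intensity must exceed background_intensity")
        if self.pixel_size_um <= 0 or self.fov_width_um <= 0 or self.fov_height_um <= 0:
            raise ValueError("geometry must be positive")
        npx = (self.fov_width_um / self.pixel_size_um) * (
            self.fov_height_um / self.pixel_size_um
        )
        if npx / self.n_cells < 4.0:
            raise ValueError("n_cells too large for FOV (mean cell area < 4 px^2)")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.fov_height_um / self.pixel_size_um)),
            int(round(self.fov_width_um / self.pixel_size_um)),
        )


@dataclass
class CellFieldTruth:
    """Ground truth for a synthetic cell field."""

    label_map: np.ndarray            # (H, W) int, labels 1..n
    cells: pd.DataFrame              # label, centroid_x/y_um, area_um2, aspect_ratio, orientation
    pixel_size_um: float
    rng_seed: int

    @property
    def n_cells(self) -> int:
        return int(self.cells.shape[0])


def region_ellipse_stats(coords_rc: np.ndarray) -> tuple[float, float, float]:
    """Ellipse-fit statistics of a pixel region under the unit-square model.

    Each pixel contributes a unit square, so the covariance of the region is
    the covariance of the pixel centers plus 1/12 per axis.  Returns
    ``(aspect_ratio, orientation, area_px)`` with the orientation axial in
    ``[0, pi)`` measured from +x (columns) toward +y (rows).  A single pixel
    has covariance I/12 and therefore aspect ratio exactly 1.
    """
    n = coords_rc.shape[0]
    if n == 0:
        raise ValueError("empty region")
    c = coords_rc - coords_rc.mean(axis=0)
    cov = (c.T @ c) / n + np.eye(2) / 12.0
    # cov indices: 0=row(y), 1=col(x)
    myy, mxx, mxy = cov[0, 0], cov[1, 1], cov[0, 1]
    tr, det = mxx + myy, mxx * myy - mxy * mxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + math.sqrt(disc)
    l2 = tr / 2.0 - math.sqrt(disc)
    ar = math.sqrt(l1 / l2) if l2 > 0 else math.inf
    theta = 0.5 * math.atan2(2.0 * mxy, mxx - myy) % math.pi
    return ar, theta, float(n)


def _label_coords(labels: np.ndarray):
    """Yield ``(label, (n, 2) float row/col coordinates)`` per positive label."""
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    rr, cc = np.unravel_index(order, labels.shape)
    uniq, starts = np.unique(sorted_labels, return_index=True)
    bounds = np.append(starts, flat.size)
    for i, lab in enumerate(uniq):
        if lab == 0:
            continue
        sl = slice(bounds[i], bounds[i + 1])
        yield int(lab), np.column_stack([rr[sl], cc[sl]]).astype(float)


def _best_candidate_seeds(
    rng: np.random.Generator, n: int, width: float, height: float, k: int = 8
) -> np.ndarray:
    """Mitchell's best-candidate sampling: approximately Poisson-disk seeds."""
    pts = np.empty((n, 2))
    pts[0] = rng.uniform([0, 0], [width, height])
    for i in range(1, n):
        cand = rng.uniform([0, 0], [width, height], size=(k, 2))
        tree = cKDTree(pts[:i])
        d, _ = tree.query(cand, k=1)
        pts[i] = cand[int(np.argmax(d))]
    return pts


def _nearest_seed_labels(shape: tuple[int, int], seeds_xy: np.ndarray,
                         px: float, x_compress: float) -> np.ndarray:
    """Label each pixel by its nearest seed, distances measured with x/ar."""
    h, w = shape
    ys = (np.arange(h) + 0.5) * px
    xs = (np.arange(w) + 0.5) * px / x_compress
    xx, yy = np.meshgrid(xs, ys)
    tree = cKDTree(seeds_xy)
    _, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel()]), k=1, workers=-1)
    return idx.reshape(shape).astype(np.int32) + 1


def generate_cell_field(spec: CellFieldSpec) -> tuple[np.ndarray, CellFieldTruth]:
    """Render a synthetic cell-boundary image and its ground truth.

    Returns ``(image, truth)`` where the image is float64 grayscale in
    ``[0, 65535]`` and the truth label map partitions the full field of view.
    Identical specs produce bit-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    px = spec.pixel_size_um
    ar = spec.target_ar
    # seeds live in the compressed (isotropic) frame: x' in [0, W/ar]
    seeds = _best_candidate_seeds(rng, spec.n_cells, spec.fov_width_um / ar,
                                  spec.fov_height_um)
    labels = _nearest_seed_labels((h, w), seeds, px, ar)
    # Lloyd relaxation (2 iterations) in the compressed frame
    for _ in range(2):
        idx = np.arange(1, spec.n_cells + 1)
        cy = ndi.mean(np.broadcast_to(((np.arange(h) + 0.5) * px)[:, None], (h, w)),
                      labels, idx)
        cx = ndi.mean(np.broadcast_to(((np.arange(w) + 0.5) * px / ar)[None, :], (h, w)),
                      labels, idx)
        present = ~(np.isnan(cx) | np.isnan(cy))
        seeds = seeds.copy()
        seeds[present] = np.column_stack([cx[present], cy[present]])
        labels = _nearest_seed_labels((h, w), seeds, px, ar)
    # compact labels in case a seed lost all pixels
    present = np.unique(labels)
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    labels = remap[labels]

    image = _render_boundaries(labels, spec)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, GRAY_MAX)

    rows = []
    for lab, coords in _label_coords(labels):
        a_r, theta, npx = region_ellipse_stats(coords)
        rows.append({
            "label": lab,
            "centroid_x_um": (coords[:, 1].mean() + 0.5) * px,
            "centroid_y_um": (coords[:, 0].mean() + 0.5) * px,
            "area_um2": npx * px * px,
            "aspect_ratio": a_r,
            "orientation": theta,
        })
    truth = CellFieldTruth(labels, pd.DataFrame(rows), px, spec.rng_seed)
    return image, truth


def _render_boundaries(labels: np.ndarray, spec: CellFieldSpec) -> np.ndarray:
    """Bright Gaussian-profile ridges along inter-cell interfaces."""
    h, w = labels.shape
    iface = np.zeros((h, w), bool)
    iface[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    iface[:-1, :] |= labels[:-1, :] != labels[1:, :]
    bg = np.full((h, w), spec.background_intensity, float)
    if spec.background_gradient != 0.0:
        bg = bg + spec.background_gradient * np.linspace(0.0, 1.0, w)[None, :]
    if not iface.any():
        return bg
    d = ndi.distance_transform_edt(~iface) * spec.pixel_size_um
    sigma = max(spec.boundary_sigma_um, 1e-6)
    amp = spec.boundary_intensity - spec.background_intensity
    return bg + amp * np.exp(-0.5 * (d / sigma) ** 2)


# ---------------------------------------------------------------------------
# fiber fields
# ---------------------------------------------------------------------------

OrientationMode = Literal["uniform", "global", "patchwise"]


@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters of a synthetic stress-fiber plane.

    The default fiber count reproduces a total-length density near
    0.12 µm⁻¹ over the 563 × 356 µm field of view at a 3 µm mean length,
    within the range measured in remodeling basal layers.
    """

    fov_width_um: float = 563.0
    fov_height_um: float = 356.0
    pixel_size_um: float = 0.25
    n_fibers: int = 8000
    length_mean_um: float = 3.0
    length_sd_um: float = 0.5
    orientation_mode: OrientationMode = "uniform"
    patch_size_um: float = 30.0
    fiber_width_um: float = 0.5     # FWHM of the Gaussian cross-section
    fiber_intensity: float = 12000.0
    background_intensity: float = 1000.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length_mean_um <= 0:
            raise ValueError("length_mean_um must be > 0")
        if self.orientation_mode == "patchwise" and self.patch_size_um <= 0:
            raise ValueError("patch_size_um must be > 0 in patchwise mode")
        if self.orientation_mode not in ("uniform", "global", "patchwise"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        diag = math.hypot(self.fov_width_um, self.fov_height_um)
        if self.length_mean_um >= diag:
            raise ValueError("fibers longer than the FOV diagonal")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.fov_height_um / self.pixel_size_um)),
            int(round(self.fov_width_um / self.pixel_size_um)),
        )


@dataclass
class FiberFieldTruth:
    """Ground truth for a synthetic fiber plane."""

    fibers: pd.DataFrame            # x0..y1 (µm), length_um, theta (axial, rad)
    patches: pd.DataFrame | None    # patchwise mode: patch centers + orientation
    pixel_size_um: float
    rng_seed: int

    @property
    def total_length_um(self) -> float:
        return float(self.fibers["length_um"].sum())

    @property
    def mean_length_um(self) -> float:
        return float(self.fibers["length_um"].mean())


def generate_fiber_field(spec: FiberFieldSpec) -> tuple[np.ndarray, FiberFieldTruth]:
    """Render bright line segments with Gaussian cross-section plus truth.

    Segment midpoints are re-drawn until the whole segment fits inside the
    field of view, so every truth length is fully rendered.  In patchwise mode
    every fiber takes the orientation of the patch containing its midpoint.
    """
    rng = np.random.default_rng(spec.rng_seed)
    w_um, h_um = spec.fov_width_um, spec.fov_height_um
    diag = math.hypot(w_um, h_um)
    lengths = np.clip(
        rng.normal(spec.length_mean_um, spec.length_sd_um, spec.n_fibers),
        0.2, 0.98 * diag,
    )

    patches = None
    if spec.orientation_mode == "patchwise":
        npx_ = int(math.ceil(w_um / spec.patch_size_um))
        npy_ = int(math.ceil(h_um / spec.patch_size_um))
        patch_theta = rng.uniform(0.0, math.pi, size=(npy_, npx_))
        pcx = (np.arange(npx_) + 0.5) * spec.patch_size_um
        pcy = (np.arange(npy_) + 0.5) * spec.patch_size_um
        patches = pd.DataFrame({
            "patch_x_um": np.tile(pcx, npy_),
            "patch_y_um": np.repeat(pcy, npx_),
            "theta": patch_theta.ravel(),
        })
    elif spec.orientation_mode == "global":
        theta0 = rng.uniform(0.0, math.pi)

    mids = np.empty((spec.n_fibers, 2))
    thetas = np.empty(spec.n_fibers)
    for i in range(spec.n_fibers):
        li = lengths[i]
        for _ in range(1000):
            m = rng.uniform([0.0, 0.0], [w_um, h_um])
            if spec.orientation_mode == "uniform":
                th = rng.uniform(0.0, math.pi)
            elif spec.orientation_mode == "global":
                th = theta0
            else:
                ix = min(int(m[0] / spec.patch_size_um), patch_theta.shape[1] - 1)
                iy = min(int(m[1] / spec.patch_size_um), patch_theta.shape[0] - 1)
                th = patch_theta[iy, ix]
            dx, dy = 0.5 * li * math.cos(th), 0.5 * li * math.sin(th)
            if (0 <= m[0] - dx <= w_um and 0 <= m[0] + dx <= w_um
                    and 0 <= m[1] - dy <= h_um and 0 <= m[1] + dy <= h_um):
                mids[i], thetas[i] = m, th
                break
        else:
            raise RuntimeError("could not place fiber inside FOV")

    dx = 0.5 * lengths * np.cos(thetas)
    dy = 0.5 * lengths * np.sin(thetas)
    fibers = pd.DataFrame({
        "x0_um": mids[:, 0] - dx, "y0_um": mids[:, 1] - dy,
        "x1_um": mids[:, 0] + dx, "y1_um": mids[:, 1] + dy,
        "length_um": lengths, "theta": thetas % math.pi,
    })

    image = _render_fibers(fibers, spec)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, GRAY_MAX)
    return image, FiberFieldTruth(fibers, patches, spec.pixel_size_um, spec.rng_seed)


def _render_fibers(fibers: pd.DataFrame, spec: FiberFieldSpec) -> np.ndarray:
    h, w = spec.shape
    px = spec.pixel_size_um
    sigma = spec.fiber_width_um / 2.355  # FWHM -> sigma
    amp = spec.fiber_intensity - spec.background_intensity
    image = np.full((h, w), spec.background_intensity, float)
    pad = 3.0 * sigma
    for row in fibers.itertuples(index=False):
        x0, y0, x1, y1 = row.x0_um, row.y0_um, row.x1_um, row.y1_um
        c0 = max(int((min(x0, x1) - pad) / px), 0)
        c1 = min(int((max(x0, x1) + pad) / px) + 1, w)
        r0 = max(int((min(y0, y1) - pad) / px), 0)
        r1 = min(int((max(y0, y1) + pad) / px) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * px
        ys = (np.arange(r0, r1) + 0.5) * px
        xx, yy = np.meshgrid(xs, ys)
        d = _dist_to_segment(xx, yy, x0, y0, x1, y1)
        image[r0:r1, c0:c1] += amp * np.exp(-0.5 * (d / sigma) ** 2)
    return image


def _dist_to_segment(xx, yy, x0, y0, x1, y1):
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return np.hypot(xx - x0, yy - y0)
    t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / L2, 0.0, 1.0)
    return np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy))


# ---------------------------------------------------------------------------
# time-lapse sequences
# ---------------------------------------------------------------------------

FlowKind = Literal["static", "translation", "rotation", "swirl"]


@dataclass(frozen=True)
class FlowSpec:
    """Parameters of a synthetic time-lapse advected by an analytic flow.

    Defaults follow the live-imaging protocol: frames every 6 min over 1.5 h
    (16 frames).  ``speed_um_per_h`` drives translation;
    ``angular_rate_rad_per_h`` drives rotation and swirl (for swirl the local
    angular rate decays as a Gaussian of radius with scale ``swirl_core_um``).
    """

    flow_kind: FlowKind = "translation"
    speed_um_per_h: float = 4.0
    direction_deg: float = 0.0
    angular_rate_rad_per_h: float = 0.1
    swirl_core_um: float = 80.0
    n_frames: int = 16
    frame_interval_min: float = 6.0
    fov_width_um: float = 256.0
    fov_height_um: float = 256.0
    pixel_size_um: float = 1.0
    texture_scale_um: float = 6.0
    intensity_lo: float = 2000.0
    intensity_hi: float = 20000.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.flow_kind not in ("static", "translation", "rotation", "swirl"):
            raise ValueError(f"unknown flow_kind {self.flow_kind!r}")
        step_um = self._max_step_um()
        if step_um > 0.25 * min(self.fov_width_um, self.fov_height_um):
            raise ValueError("per-frame displacement exceeds 25% of the FOV")

    def _max_step_um(self) -> float:
        dt_h = self.frame_interval_min / 60.0
        if self.flow_kind == "translation":
            return self.speed_um_per_h * dt_h
        if self.flow_kind in ("rotation", "swirl"):
            rmax = 0.5 * math.hypot(self.fov_width_um, self.fov_height_um)
            return abs(self.angular_rate_rad_per_h) * dt_h * rmax
        return 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.fov_height_um / self.pixel_size_um)),
            int(round(self.fov_width_um / self.pixel_size_um)),
        )

    @property
    def center_um(self) -> tuple[float, float]:
        return (0.5 * self.fov_width_um, 0.5 * self.fov_height_um)


@dataclass
class FlowTruth:
    """Analytic trajectories and speeds for a synthetic time-lapse."""

    spec: FlowSpec
    _advect: Callable[[np.ndarray, float], np.ndarray] = field(repr=False)

    def positions(self, seeds_xy_um: np.ndarray, t_hours: float) -> np.ndarray:
        """Advect seed points (µm) forward by ``t_hours``."""
        return self._advect(np.asarray(seeds_xy_um, float), t_hours)

    def speed(self, seeds_xy_um: np.ndarray) -> np.ndarray:
        """Net-displacement speed (µm/h) over the full sequence duration."""
        t = (self.spec.n_frames - 1) * self.spec.frame_interval_min / 60.0
        p0 = np.asarray(seeds_xy_um, float)
        p1 = self.positions(p0, t)
        return np.hypot(*(p1 - p0).T) / t


def _make_advect(spec: FlowSpec) -> Callable[[np.ndarray, float], np.ndarray]:
    cx, cy = spec.center_um
    if spec.flow_kind == "static":
        return lambda p, t: p.copy()
    if spec.flow_kind == "translation":
        phi = math.radians(spec.direction_deg)
        v = spec.speed_um_per_h * np.array([math.cos(phi), math.sin(phi)])
        return lambda p, t: p + v * t
    if spec.flow_kind == "rotation":
        def advect(p, t):
            ang = spec.angular_rate_rad_per_h * t
            return _rotate_about(p, cx, cy, ang)
        return advect
    # swirl: angular rate depends only on radius, which rotation preserves
    def advect(p, t):
        r = np.hypot(p[..., 0] - cx, p[..., 1] - cy)
        ang = spec.angular_rate_rad_per_h * np.exp(-(r / spec.swirl_core_um) ** 2) * t
        return _rotate_about(p, cx, cy, ang)
    return advect


def _rotate_about(p: np.ndarray, cx: float, cy: float, ang) -> np.ndarray:
    x, y = p[..., 0] - cx, p[..., 1] - cy
    ca, sa = np.cos(ang), np.sin(ang)
    return np.stack([cx + ca * x - sa * y, cy + sa * x + ca * y], axis=-1)


def generate_timelapse(spec: FlowSpec) -> tuple[np.ndarray, FlowTruth]:
    """Render a (T, H, W) frame stack advected by the analytic flow.

    Frame ``k`` samples a fixed band-limited random texture at the positions
    obtained by advecting each pixel center backward by ``k`` frame intervals,
    so the rendered motion matches the analytic trajectories exactly (up to
    interpolation).  Rotation-family flows are inverted exactly because the
    local angular rate depends only on the (rotation-invariant) radius.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    px = spec.pixel_size_um
    tex = ndi.gaussian_filter(rng.uniform(size=(h, w)),
                              spec.texture_scale_um / px, mode="wrap")
    tex = tex - tex.min()
    tex = spec.intensity_lo + (spec.intensity_hi - spec.intensity_lo) * tex / tex.max()

    advect = _make_advect(spec)
    dt_h = spec.frame_interval_min / 60.0
    ys = (np.arange(h) + 0.5) * px
    xs = (np.arange(w) + 0.5) * px
    xx, yy = np.meshgrid(xs, ys)
    grid = np.stack([xx, yy], axis=-1)

    frames = np.empty((spec.n_frames, h, w))
    for k in range(spec.n_frames):
        src = advect(grid, -k * dt_h)
        rows = src[..., 1] / px - 0.5
        cols = src[..., 0] / px - 0.5
        frames[k] = ndi.map_coordinates(tex, [rows, cols], order=3, mode="mirror")
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, GRAY_MAX)
    return frames, FlowTruth(spec, advect)
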