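"""Cell segmentation and shape morphometry on projected planes.

Cell boundaries appear as bright cortical-actin ridges.  Segmentation is
marker-controlled watershed: regional minima of the (preprocessed) intensity
surface after h-minima suppression seed the basins, and the watershed lines
trace the ridges.  Quality control dissolves watershed ridges that are too
tortuous, too short, or dimmer than a percentile of all ridges — the
signatures of over-segmentation — by merging the two cells they separate.
Morphometry fits each region with the ellipse having identical normalized
second central moments (pixels modeled as unit squares), so the aspect ratio
of an axis-aligned a x b rectangle is exactly a/b and a single pixel has
aspect ratio exactly 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import wiener
from skimage.morphology import disk, erosion, dilation, h_minima, reconstruction
from skimage.segmentation import watershed

from .imaging import Projection
from .synth import _label_coords, region_ellipse_stats

__all__ = [
    "SegmentationParams",
    "CellLabelMap",
    "CellMetrics",
    "preprocess",
    "segment_cells",
    "qc_boundaries",
    "filter_by_area",
    "cell_morphology",
    "segment_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation and QC parameters for one plane.

    ``marker_h`` is the h-minima suppression depth in grayscale units; minima
    shallower than this are not used as markers, which controls
    over-segmentation at the source.  QC thresholds: ridges with tortuosity
    above ``max_tortuosity``, length outside ``[min_ridge_len_um,
    max_ridge_len_um]``, or mean intensity strictly below the
    ``min_ridge_intensity_pct`` percentile of all ridge intensities are
    dissolved.
    """

    plane_name: str = "apical"
    smoothing_radius_px: int = 2          # disk radius for reconstruction filtering
    wiener_window_px: int = 5             # local window for the adaptive filter
    marker_h: float = 200.0
    max_tortuosity: float = 1.6
    min_ridge_len_um: float = 3.0
    max_ridge_len_um: float = math.inf
    min_ridge_intensity_pct: float = 30.0
    min_area_um2: float = 20.0
    max_area_um2: float = 2000.0

    def __post_init__(self) -> None:
        if self.min_area_um2 > self.max_area_um2:
            raise ValueError("area bounds must be ordered")
        if self.min_ridge_len_um > self.max_ridge_len_um:
            raise ValueError("ridge length bounds must be ordered")
        if not 0.0 <= self.min_ridge_intensity_pct < 100.0:
            raise ValueError("intensity percentile must be in [0, 100)")
        if self.max_tortuosity <= 0 or self.marker_h < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CellLabelMap:
    """Per-pixel cell labels for one projected plane.

    Label 0 marks watershed ridges and removed regions; positive labels are
    contiguous ``1..n`` after compaction.
    """

    labels: np.ndarray
    pixel_size_um: float
    plane_name: str = ""
    params: SegmentationParams | None = None

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def fov_width_um(self) -> float:
        return self.labels.shape[1] * self.pixel_size_um

    @property
    def fov_height_um(self) -> float:
        return self.labels.shape[0] * self.pixel_size_um

    @property
    def fov_area_mm2(self) -> float:
        return self.fov_width_um * self.fov_height_um / 1e6


@dataclass
class CellMetrics:
    """Per-cell morphology table and per-FOV summary."""

    cells: pd.DataFrame
    n_cells: int
    density_per_mm2: float
    mean_area_um2: float
    mean_ar: float


class SegmentationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(proj: Projection, params: SegmentationParams) -> Projection:
    """Plane-specific denoising before watershed.

    Apical projections are filtered by morphological opening-by-reconstruction
    followed by closing-by-reconstruction with a disk structuring element
    (removes bright and dark specks smaller than the disk while preserving
    ridge geometry).  Basal projections are filtered with a local adaptive
    Wiener-type filter (local mean/variance noise estimate).
    """
    img = np.asarray(proj.image, dtype=float)
    if params.plane_name == "apical":
        se = disk(params.smoothing_radius_px)
        opened = reconstruction(erosion(img, se), img, method="dilation")
        closed = reconstruction(dilation(opened, se), opened, method="erosion")
        out = closed
    elif params.plane_name == "basal":
        # reflect-pad so the local statistics are not zero-padding artifacts
        pad = params.wiener_window_px // 2
        padded = np.pad(img, pad, mode="reflect")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = wiener(padded, mysize=params.wiener_window_px)
        out = out[pad:-pad, pad:-pad] if pad else out
        # zero local variance with zero noise estimate divides 0/0; such
        # pixels are noise-free and pass through unchanged
        out = np.where(np.isfinite(out), out, img)
    else:
        raise ValueError(f"unknown plane_name {params.plane_name!r}")
    return replace(proj, image=out)


# ---------------------------------------------------------------------------
# watershed segmentation
# ---------------------------------------------------------------------------

def segment_cells(proj: Projection, params: SegmentationParams) -> CellLabelMap:
    """Marker-controlled watershed on the boundary-intensity surface.

    Markers are the regional minima after h-minima suppression at depth
    ``params.marker_h``; ridge pixels carry label 0.  A perfectly uniform
    image yields a single label covering the FOV (logged as a warning) rather
    than failing mid-pipeline.
    """
    img = np.asarray(proj.image, dtype=float)
    if img.max() == img.min():
        log.warning("uniform %s image: returning a single full-FOV label",
                    proj.plane_name)
        labels = np.ones(img.shape, dtype=np.int32)
        return CellLabelMap(labels, proj.pixel_size_um, proj.plane_name, params)
    minima = h_minima(img, params.marker_h) if params.marker_h > 0 else None
    if minima is None or not minima.any():
        # fall back to plain regional minima
        minima = h_minima(img, 1e-9)
    markers, n_markers = ndi.label(minima, structure=np.ones((3, 3), int))
    if n_markers == 0:
        raise SegmentationError("zero watershed markers found")
    labels = watershed(img, markers, connectivity=1, watershed_line=True)
    return CellLabelMap(labels.astype(np.int32), proj.pixel_size_um,
                        proj.plane_name, params)


def _compact(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    return remap[labels]


# ---------------------------------------------------------------------------
# ridge QC
# ---------------------------------------------------------------------------

def _ridge_segments(labels: np.ndarray) -> tuple[dict, np.ndarray]:
    """Group watershed-line pixels into per-label-pair ridge segments.

    Returns ``(segments, adjacency_count)`` where ``segments`` maps a sorted
    label pair to the list of (r, c) ridge pixels separating exactly that
    pair.  Ridge pixels adjacent to three or more labels are junctions and
    belong to no pair segment.
    """
    h, w = labels.shape
    ridge = labels == 0
    rr, cc = np.nonzero(ridge)
    segments: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in zip(rr.tolist(), cc.tolist()):
        neigh = labels[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
        labs = np.unique(neigh)
        labs = labs[labs > 0]
        if labs.size == 2:
            segments.setdefault((int(labs[0]), int(labs[1])), []).append((r, c))
    return segments, np.column_stack([rr, cc])


def _order_path(pixels: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Order 8-connected ridge pixels into one or more polyline paths."""
    pset = set(pixels)
    paths = []
    remaining = set(pixels)
    while remaining:
        # pick an endpoint if one exists, else any pixel (loop)
        start = None
        for p in remaining:
            deg = _n_neighbors(p, pset, remaining)
            if deg <= 1:
                start = p
                break
        if start is None:
            start = next(iter(remaining))
        path = [start]
        remaining.discard(start)
        cur = start
        while True:
            nxt = None
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (cur[0] + dr, cur[1] + dc)
                    if q != cur and q in remaining:
                        nxt = q
                        break
                if nxt:
                    break
            if nxt is None:
                break
            path.append(nxt)
            remaining.discard(nxt)
            cur = nxt
        paths.append(path)
    return paths


def _n_neighbors(p, pset, remaining):
    n = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if (dr, dc) != (0, 0) and (p[0] + dr, p[1] + dc) in remaining:
                n += 1
    return n


def _path_stats(path: list[tuple[int, int]], px: float) -> tuple[float, float]:
    """(path length, tortuosity) of an ordered ridge path in µm."""
    if len(path) == 1:
        return px, 1.0
    arr = np.asarray(path, float)
    steps = np.hypot(*np.diff(arr, axis=0).T)
    plen = float(steps.sum()) * px
    chord = float(np.hypot(*(arr[-1] - arr[0]))) * px
    tort = plen / chord if chord > 0 else math.inf
    return plen, tort


def qc_boundaries(lmap: CellLabelMap, proj: Projection,
                  params: SegmentationParams | None = None) -> CellLabelMap:
    """Dissolve watershed ridges that fail the over-segmentation QC.

    For every ridge separating exactly two cells: tortuosity (path length /
    endpoint chord), length in µm, and mean image intensity along the ridge
    are computed.  A ridge fails when tortuosity > ``max_tortuosity``, length
    lies outside the ridge-length bounds, or its mean intensity is strictly
    below the ``min_ridge_intensity_pct`` percentile of all ridge
    intensities.  Failing ridges are dissolved by merging the two labels;
    labels are then re-compacted.  Never increases the label count.
    """
    params = params or lmap.params or SegmentationParams(plane_name=lmap.plane_name)
    labels = lmap.labels
    segments, _ = _ridge_segments(labels)
    if not segments:
        return lmap

    img = np.asarray(proj.image, float)
    px = lmap.pixel_size_um
    seg_stats = []
    for pair, pix in segments.items():
        arr = np.asarray(pix)
        mean_int = float(img[arr[:, 0], arr[:, 1]].mean())
        # a pair's ridge may be split into several 8-connected pieces; QC the
        # longest piece (the actual shared boundary), carry intensity overall
        paths = _order_path(pix)
        plen, tort = max((_path_stats(p, px) for p in paths),
                         key=lambda s: s[0])
        seg_stats.append((pair, plen, tort, mean_int))

    intensities = np.array([s[3] for s in seg_stats])
    cut = np.percentile(intensities, params.min_ridge_intensity_pct)

    parent = np.arange(int(labels.max()) + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    n_merged = 0
    for (a, b), plen, tort, mean_int in seg_stats:
        fails = (tort > params.max_tortuosity
                 or plen < params.min_ridge_len_um
                 or plen > params.max_ridge_len_um
                 or mean_int < cut)
        if fails:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
                n_merged += 1
    if n_merged == 0:
        return lmap

    roots = np.array([find(i) for i in range(parent.size)])
    merged = roots[labels]
    # absorb ridge pixels whose surviving neighbors all share one root
    merged = _fill_dissolved_ridges(labels, merged, roots)
    out = _compact(merged)
    return CellLabelMap(out, px, lmap.plane_name, params)


def _fill_dissolved_ridges(labels, merged, roots):
    out = merged.copy()
    rr, cc = np.nonzero(labels == 0)
    h, w = labels.shape
    for r, c in zip(rr.tolist(), cc.tolist()):
        neigh = merged[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
        labs = np.unique(neigh)
        labs = labs[labs > 0]
        if labs.size == 1:
            out[r, c] = labs[0]
    return out


# ---------------------------------------------------------------------------
# area filter and morphology
# ---------------------------------------------------------------------------

def filter_by_area(lmap: CellLabelMap, min_um2: float,
                   max_um2: float = math.inf) -> CellLabelMap:
    """Remove cells with area outside ``[min_um2, max_um2]`` and compact."""
    if min_um2 > max_um2:
        raise ValueError("area bounds must be ordered")
    labels = lmap.labels
    if labels.max() == 0:
        return lmap
    areas_px = np.bincount(labels.ravel())[1:]
    areas = areas_px * lmap.pixel_size_um ** 2
    keep = (areas >= min_um2) & (areas <= max_um2)
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[1:][keep] = 1
    out = _compact(np.where(remap[labels] > 0, labels, 0))
    return CellLabelMap(out, lmap.pixel_size_um, lmap.plane_name, lmap.params)


def cell_morphology(lmap: CellLabelMap) -> CellMetrics:
    """Per-cell ellipse-fit morphology and per-FOV summary.

    The fitted ellipse has the same normalized second central moments as the
    pixel region (unit-square pixel model); aspect ratio = major/minor axis
    length >= 1.  Density uses the full FOV area.
    """
    labels = lmap.labels
    px = lmap.pixel_size_um
    rows = []
    for lab, coords in _label_coords(labels):
        ar, theta, npx = region_ellipse_stats(coords)
        cov = np.cov(coords.T, bias=True) + np.eye(2) / 12.0 if npx > 1 \
            else np.eye(2) / 12.0
        eigs = np.sort(np.linalg.eigvalsh(cov))[::-1]
        rows.append({
            "label": lab,
            "centroid_x_um": (coords[:, 1].mean() + 0.5) * px,
            "centroid_y_um": (coords[:, 0].mean() + 0.5) * px,
            "area_um2": npx * px * px,
            "aspect_ratio": ar,
            "major_axis_um": 4.0 * math.sqrt(eigs[0]) * px,
            "minor_axis_um": 4.0 * math.sqrt(eigs[1]) * px,
            "orientation": theta,
        })
    cells = pd.DataFrame(rows, columns=[
        "label", "centroid_x_um", "centroid_y_um", "area_um2", "aspect_ratio",
        "major_axis_um", "minor_axis_um", "orientation"])
    n = len(cells)
    density = n / lmap.fov_area_mm2
    return CellMetrics(
        cells=cells,
        n_cells=n,
        density_per_mm2=density,
        mean_area_um2=float(cells["area_um2"].mean()) if n else math.nan,
        mean_ar=float(cells["aspect_ratio"].mean()) if n else math.nan,
    )


def segment_pipeline(proj: Projection, params: SegmentationParams,
                     apply_qc: bool = True) -> tuple[CellLabelMap, CellMetrics]:
    """Preprocess, segment, QC, area-filter, and measure one projection."""
    pre = preprocess(proj, params)
    lmap = segment_cells(pre, params)
    if apply_qc:
        lmap = qc_boundaries(lmap, pre, params)
    lmap = filter_by_area(lmap, params.min_area_um2, params.max_area_um2)
    return lmap, cell_morphology(lmap)
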