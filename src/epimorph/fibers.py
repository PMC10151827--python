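"""Stress-fiber segmentation, length metrics, and spatial alignment.

The fiber plane sits just below the basal cell plane.  Processing stages:

1. :func:`mask_cell_boundaries` — remove cortical actin by zeroing the basal
   watershed ridges dilated to a configurable width (1.5 µm by default);
   masked pixels are subtracted from the searched area.
2. :func:`trace_fragments` — ridge-enhance with oriented line filters,
   threshold, skeletonize, split the skeleton at branch points, and bridge
   near-collinear arms across junctions so that crossing fibers come out as
   two straight fragments instead of four arms.
3. :func:`join_fragments` — reconnect fragments of one fiber split by gaps:
   endpoint pairs within a distance threshold whose tangents and connecting
   segment agree in (axial) direction are joined greedily, best score first,
   and only when the image intensity along the connector is consistent with
   the fragments themselves.
4. :func:`orientation_field` / :func:`alignment_auc` — per-subregion axial
   orientations from the intensity structure tensor, and the alignment-AUC
   statistic: the area between the pairwise alignment-versus-distance curve
   of the observed field and that of the same orientations randomly
   repositioned (permutation null), which isolates local over global
   alignment.

Orientations are axial (defined modulo 180 deg) and all averaging happens in
double-angle space, where the alignment of two orientations is
``cos 2(theta_i - theta_j)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, skeletonize

from .cells import CellLabelMap
from .imaging import Projection

__all__ = [
    "TracerParams",
    "JoinParams",
    "FiberFragment",
    "FiberSet",
    "OrientationField",
    "AlignmentCurve",
    "mask_cell_boundaries",
    "trace_fragments",
    "join_fragments",
    "length_metrics",
    "orientation_field",
    "alignment_auc",
]


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerParams:
    """Fragment-tracing parameters.

    ``n_orientations`` oriented zero-mean line kernels of physical length
    ``kernel_len_um`` enhance ridges; the response is thresholded (Otsu by
    default, or a fixed ``threshold``), skeletonized, and split/bridged at
    junctions.  Arms are bridged across a junction when continuing through it
    turns by at most ``max_junction_turn_deg``.  Fragments shorter than
    ``min_length_um`` are discarded.
    """

    n_orientations: int = 12
    kernel_len_um: float = 2.0
    threshold: float | None = None
    min_length_um: float = 1.0
    max_junction_turn_deg: float = 35.0
    tangent_pts: int = 5

    def __post_init__(self) -> None:
        if self.n_orientations < 2 or self.kernel_len_um <= 0:
            raise ValueError("invalid tracer params")


@dataclass(frozen=True)
class JoinParams:
    """Fragment-joining constraints.

    A candidate connection between two fragment endpoints must satisfy: gap
    <= ``max_gap_um``; axial angle between the two fragment end tangents <=
    ``max_tangent_mismatch_deg``; axial angle between the connecting segment
    and each tangent <= ``max_connector_dev_deg``; and mean image intensity
    along the connector >= ``intensity_ratio`` times the dimmer fragment's
    mean intensity.
    """

    max_gap_um: float = 3.0
    max_tangent_mismatch_deg: float = 20.0
    max_connector_dev_deg: float = 20.0
    intensity_ratio: float = 0.6

    def __post_init__(self) -> None:
        if self.max_gap_um <= 0:
            raise ValueError("max_gap_um must be > 0")
        for a in (self.max_tangent_mismatch_deg, self.max_connector_dev_deg):
            if not 0 < a < 90:
                raise ValueError("angle thresholds must lie in (0, 90) deg")
        if not 0 < self.intensity_ratio <= 1:
            raise ValueError("intensity_ratio must lie in (0, 1]")


@dataclass
class FiberFragment:
    """A traced fiber fragment as an ordered polyline in µm coordinates."""

    points: np.ndarray          # (n, 2) x, y in µm
    length_um: float
    mean_intensity: float
    tangent_start: float        # axial, radians: direction leaving points[0]
    tangent_end: float          # axial, radians: direction leaving points[-1]

    def __post_init__(self) -> None:
        if self.points.shape[0] < 2 or self.length_um <= 0:
            raise ValueError("fragment needs >= 2 points and positive length")


@dataclass
class FiberSet:
    """Joined fibers plus field-of-view summary metrics."""

    fibers: list[FiberFragment]
    searched_area_um2: float

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    @property
    def total_length_um(self) -> float:
        return float(sum(f.length_um for f in self.fibers))

    @property
    def mean_length_um(self) -> float | None:
        if not self.fibers:
            return None
        return self.total_length_um / self.n_fibers

    @property
    def total_length_density_per_um(self) -> float:
        if self.searched_area_um2 <= 0:
            raise ValueError("searched area must be > 0")
        return self.total_length_um / self.searched_area_um2


@dataclass
class OrientationField:
    """Grid of axial subregion orientations with a validity mask."""

    theta: np.ndarray           # (ny, nx) radians in [0, pi)
    valid: np.ndarray           # (ny, nx) bool
    centers_x_um: np.ndarray    # (nx,)
    centers_y_um: np.ndarray    # (ny,)
    subregion_um: float

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers (m, 2) µm, orientations (m,)) of valid subregions."""
        yy, xx = np.nonzero(self.valid)
        pts = np.column_stack([self.centers_x_um[xx], self.centers_y_um[yy]])
        return pts, self.theta[yy, xx]


@dataclass
class AlignmentCurve:
    """Alignment-vs-distance curves and their between-curve area (AUC)."""

    bin_edges_um: np.ndarray
    experimental: np.ndarray        # mean pairwise alignment per bin
    null_mean: np.ndarray           # averaged over repositioning replicates
    null_reps: np.ndarray           # (n_reps, n_bins)
    auc: float                      # area between curves, µm
    auc_per_rep: np.ndarray         # AUC against each individual replicate

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    @property
    def null_auc_se(self) -> float:
        """Standard deviation of the AUC under the repositioning null.

        Under the null the observed assignment of orientations to positions
        is exchangeable with the permuted ones, so the AUC statistic is
        distributed like ``trapz(rep_r) - mean_r' trapz(rep_r')``; its spread
        is estimated by the replicate AUCs, inflated by ``sqrt(1 + 1/R)`` for
        the finite replicate mean.
        """
        n = self.auc_per_rep.size
        if n < 2:
            return math.nan
        return float(self.auc_per_rep.std(ddof=1) * math.sqrt(1.0 + 1.0 / n))


# ---------------------------------------------------------------------------
# boundary masking
# ---------------------------------------------------------------------------

def mask_cell_boundaries(proj: Projection, basal_labels: CellLabelMap,
                         width_um: float = 1.5) -> Projection:
    """Zero the basal watershed ridges dilated to ``width_um``.

    Ridge pixels are label-0 pixels of the basal label map adjacent to at
    least one cell; an all-zero label map therefore masks nothing.  Masked
    pixels are flagged in ``excluded_mask`` and excluded from the searched
    area.  Idempotent.
    """
    if proj.image.shape != basal_labels.labels.shape:
        raise ValueError("projection and label map shapes differ")
    labels = basal_labels.labels
    ridge = np.zeros(labels.shape, bool)
    if labels.max() > 0:
        zero = labels == 0
        has_cell = ndi.maximum_filter(labels, size=3) > 0
        ridge = zero & has_cell
    if ridge.any():
        px = proj.pixel_size_um
        radius = max(int(round((width_um / px - 1) / 2)), 0)
        if radius > 0:
            ridge = dilation(ridge, disk(radius))
    img = np.asarray(proj.image, float).copy()
    img[ridge] = 0.0
    mask = ridge
    if proj.excluded_mask is not None:
        mask = mask | proj.excluded_mask
    return replace(proj, image=img, excluded_mask=mask)


# ---------------------------------------------------------------------------
# fragment tracing
# ---------------------------------------------------------------------------

def _line_kernels(length_px: int, n_orient: int) -> list[np.ndarray]:
    """Zero-mean oriented line kernels on a square support."""
    size = length_px if length_px % 2 == 1 else length_px + 1
    half = size // 2
    kernels = []
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    for i in range(n_orient):
        th = math.pi * i / n_orient
        # distance from pixel to the line through the origin at angle th
        d = np.abs(-math.sin(th) * xx + math.cos(th) * yy)
        along = np.abs(math.cos(th) * xx + math.sin(th) * yy)
        k = ((d < 0.6) & (along <= half)).astype(float)
        k -= k.mean()
        kernels.append(k)
    return kernels


def _ridge_response(img: np.ndarray, params: TracerParams, px: float) -> np.ndarray:
    length_px = max(int(round(params.kernel_len_um / px)), 3)
    resp = None
    for k in _line_kernels(length_px, params.n_orientations):
        r = ndi.correlate(img, k, mode="nearest")
        resp = r if resp is None else np.maximum(resp, r)
    return resp


def _skeleton_neighbors(skel: np.ndarray) -> np.ndarray:
    return ndi.correlate(skel.astype(np.uint8), np.array(
        [[1, 1, 1], [1, 0, 1], [1, 1, 1]], np.uint8), mode="constant")


def trace_fragments(proj: Projection, params: TracerParams | None = None
                    ) -> list[FiberFragment]:
    """Trace fiber fragments from a fiber-plane projection.

    Ridge-enhances with oriented line filters, thresholds, skeletonizes,
    splits the skeleton at branch points, and bridges arms across junctions
    when the continuation is near-straight, so crossing fibers yield separate
    straight fragments.  Returns an empty list for a blank image.
    """
    params = params or TracerParams()
    img = np.asarray(proj.image, float)
    px = proj.pixel_size_um
    if img.max() == img.min():
        return []
    resp = _ridge_response(img, params, px)
    pos = resp[resp > 0]
    if pos.size == 0:
        return []
    if params.threshold is not None:
        thresh = params.threshold
    else:
        thresh = threshold_otsu(pos) if np.unique(pos).size > 1 else pos.min()
    mask = resp > thresh
    # the oriented-kernel response smears beyond fiber tips by up to half the
    # kernel length; clip the mask to pixels that are themselves bright
    inten_cut = threshold_otsu(img) if np.unique(img).size > 1 else img.min()
    mask &= img > inten_cut
    if proj.excluded_mask is not None:
        mask &= ~proj.excluded_mask
    skel = skeletonize(mask)
    if not skel.any():
        return []

    nb = _skeleton_neighbors(skel)
    junctions = skel & (nb >= 3)
    arms_mask = skel & ~junctions
    arm_labels, n_arms = ndi.label(arms_mask, structure=np.ones((3, 3), int))
    if n_arms == 0:
        return []
    polylines = [_order_arm(arm_labels == i) for i in range(1, n_arms + 1)]
    polylines = [p for p in polylines if p is not None]
    polylines = _bridge_junctions(polylines, junctions, params)

    frags = []
    for poly in polylines:
        pts = np.asarray(poly, float)
        xy = np.column_stack([(pts[:, 1] + 0.5) * px, (pts[:, 0] + 0.5) * px])
        xy = _smooth_polyline(xy)
        seglen = np.hypot(*np.diff(xy, axis=0).T)
        length = float(seglen.sum())
        if length < params.min_length_um or pts.shape[0] < 2:
            continue
        inten = float(img[pts[:, 0].astype(int), pts[:, 1].astype(int)].mean())
        frags.append(FiberFragment(
            points=xy,
            length_um=length,
            mean_intensity=inten,
            tangent_start=_end_tangent(xy, 0, params.tangent_pts),
            tangent_end=_end_tangent(xy, -1, params.tangent_pts),
        ))
    return frags


def _order_arm(mask: np.ndarray) -> list[tuple[int, int]] | None:
    """Order the pixels of one skeleton arm from endpoint to endpoint."""
    rr, cc = np.nonzero(mask)
    pix = list(zip(rr.tolist(), cc.tolist()))
    if len(pix) == 1:
        return pix
    remaining = set(pix)
    # endpoint: pixel with exactly one 8-neighbor inside the arm
    start = None
    for p in pix:
        n = sum((p[0] + dr, p[1] + dc) in remaining
                for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0))
        if n == 1:
            start = p
            break
    if start is None:
        start = pix[0]  # small loop; arbitrary but deterministic start
    path = [start]
    remaining.discard(start)
    cur = start
    while remaining:
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                q = (cur[0] + dr, cur[1] + dc)
                if q in remaining and (best is None or abs(dr) + abs(dc) <
                                       abs(best[0] - cur[0]) + abs(best[1] - cur[1])):
                    best = q
        if best is None:
            break
        path.append(best)
        remaining.discard(best)
        cur = best
    return path


def _smooth_polyline(xy: np.ndarray, window: int = 5) -> np.ndarray:
    """Endpoint-anchored moving average; removes chain-code staircase bias.

    The polyline through discrete skeleton pixel centers overestimates the
    length of a digitized straight segment by several percent; box-filtering
    the interior coordinates recovers a near-unbiased length.
    """
    n = xy.shape[0]
    if n <= 2 or window <= 1:
        return xy
    w = min(window if window % 2 == 1 else window + 1, n if n % 2 == 1 else n - 1)
    half = w // 2
    pad = np.vstack([xy[0][None, :].repeat(half, 0), xy,
                     xy[-1][None, :].repeat(half, 0)])
    kern = np.ones(w) / w
    sm = np.column_stack([np.convolve(pad[:, 0], kern, mode="valid"),
                          np.convolve(pad[:, 1], kern, mode="valid")])
    sm[0], sm[-1] = xy[0], xy[-1]
    return sm


def _end_tangent(xy: np.ndarray, end: int, k: int) -> float:
    """Axial outward tangent direction (radians) at one end of a polyline."""
    if end == 0:
        a, b = xy[min(k, len(xy) - 1)], xy[0]
    else:
        a, b = xy[max(len(xy) - 1 - k, 0)], xy[-1]
    v = b - a
    return math.atan2(v[1], v[0]) % math.pi


def _bridge_junctions(polylines: list[list[tuple[int, int]]],
                      junctions: np.ndarray,
                      params: TracerParams) -> list[list[tuple[int, int]]]:
    """Merge arm polylines across junctions when the path continues straight."""
    if not junctions.any() or not polylines:
        return polylines
    jlab, njunc = ndi.label(junctions, structure=np.ones((3, 3), int))
    jcenters = ndi.center_of_mass(junctions, jlab, range(1, njunc + 1))
    # arm endpoints adjacent to each junction cluster
    incident: dict[int, list[tuple[int, int, np.ndarray]]] = {}
    for ai, poly in enumerate(polylines):
        for end, p in ((0, poly[0]), (1, poly[-1])):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r, c = p[0] + dr, p[1] + dc
                    if (0 <= r < junctions.shape[0] and 0 <= c < junctions.shape[1]
                            and junctions[r, c]):
                        j = int(jlab[r, c])
                        tan = _arm_dir_away(poly, end, params.tangent_pts)
                        incident.setdefault(j, []).append((ai, end, tan))
                        break
                else:
                    continue
                break

    parent = list(range(len(polylines)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    links: dict[tuple[int, int], tuple[int, int, tuple[float, float]]] = {}
    max_turn = math.radians(params.max_junction_turn_deg)
    for j, ends in incident.items():
        cands = []
        for i in range(len(ends)):
            for k2 in range(i + 1, len(ends)):
                ai, ea, ta = ends[i]
                bi, eb, tb = ends[k2]
                if ai == bi:
                    continue
                # straight continuation: directions away from the junction
                # should be anti-parallel
                turn = math.pi - _vec_angle(ta, tb)
                if turn <= max_turn:
                    cands.append((turn, ai, ea, bi, eb))
        used: set[tuple[int, int]] = set()
        jc = jcenters[j - 1]
        for turn, ai, ea, bi, eb in sorted(
                cands, key=lambda t: (t[0], t[1], t[3])):
            if (ai, ea) in used or (bi, eb) in used or find(ai) == find(bi):
                continue
            used.add((ai, ea))
            used.add((bi, eb))
            links[(ai, ea)] = (bi, eb, (int(round(jc[0])), int(round(jc[1]))))
            links[(bi, eb)] = (ai, ea, (int(round(jc[0])), int(round(jc[1]))))
            parent[find(bi)] = find(ai)

    return _assemble_chains(polylines, links)


def _arm_dir_away(poly, end, k):
    """Unit direction pointing from the junction-side endpoint into the arm,
    reversed so it points away from the arm body toward the junction."""
    pts = np.asarray(poly, float)
    if end == 0:
        v = pts[0] - pts[min(k, len(pts) - 1)]
    else:
        v = pts[-1] - pts[max(len(pts) - 1 - k, 0)]
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _vec_angle(a, b) -> float:
    d = float(np.clip(np.dot(a, b), -1.0, 1.0))
    return math.acos(d)


def _assemble_chains(polylines, links):
    """Concatenate linked arm polylines (through junction pixels) into chains."""
    n = len(polylines)
    visited = [False] * n
    out = []
    for i in range(n):
        if visited[i]:
            continue
        # walk to one extreme of the chain
        cur, end = i, 0
        seen = {i}
        while (cur, end) in links:
            nxt, nend, _ = links[(cur, end)]
            if nxt in seen:
                break
            seen.add(nxt)
            cur, end = nxt, 1 - nend
        # (cur, end) is a free endpoint; build the chain starting there
        chain = list(polylines[cur]) if end == 0 else list(reversed(polylines[cur]))
        visited[cur] = True
        pos, pend = cur, 1 - end
        while (pos, pend) in links:
            nxt, nend, jpix = links[(pos, pend)]
            if visited[nxt]:
                break
            seg = list(polylines[nxt]) if nend == 0 else list(reversed(polylines[nxt]))
            chain.append(jpix)
            chain.extend(seg)
            visited[nxt] = True
            pos, pend = nxt, 1 - nend
        out.append(chain)
    return out


# ---------------------------------------------------------------------------
# fragment joining (gap closing)
# ---------------------------------------------------------------------------

def _axial_diff(a: float, b: float) -> float:
    """Smallest angle between two axial directions, in radians [0, pi/2]."""
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def join_fragments(fragments: list[FiberFragment], proj: Projection,
                   params: JoinParams | None = None) -> FiberSet:
    """Join fragments across gaps into whole fibers.

    Candidate endpoint pairs within ``max_gap_um`` whose fragment tangents
    agree axially and whose connecting segment deviates from both tangents by
    no more than the allowed angles are scored (normalized gap + normalized
    angle, smaller is better) and accepted greedily, each endpoint at most
    once, skipping candidates that would close a cycle.  A candidate is
    accepted only if the mean intensity along the straight connector is at
    least ``intensity_ratio`` times the dimmer fragment's mean intensity.
    """
    params = params or JoinParams()
    area = proj.searched_area_um2
    if not fragments:
        return FiberSet([], area)
    img = np.asarray(proj.image, float)
    px = proj.pixel_size_um

    ends = []  # (frag_idx, end, position, axial tangent)
    for i, f in enumerate(fragments):
        ends.append((i, 0, f.points[0], f.tangent_start))
        ends.append((i, 1, f.points[-1], f.tangent_end))

    cands = []
    for a in range(len(ends)):
        ia, ea, pa, ta = ends[a]
        for b in range(a + 1, len(ends)):
            ib, eb, pb, tb = ends[b]
            if ia == ib:
                continue
            gap = float(np.hypot(*(pb - pa)))
            if gap > params.max_gap_um or gap == 0.0:
                continue
            mismatch = _axial_diff(ta, tb)
            if math.degrees(mismatch) > params.max_tangent_mismatch_deg:
                continue
            conn = math.atan2(pb[1] - pa[1], pb[0] - pa[0]) % math.pi
            dev = max(_axial_diff(conn, ta), _axial_diff(conn, tb))
            if math.degrees(dev) > params.max_connector_dev_deg:
                continue
            score = (gap / params.max_gap_um
                     + mismatch / math.radians(params.max_tangent_mismatch_deg)
                     + dev / math.radians(params.max_connector_dev_deg))
            cands.append((score, a, b, gap))

    parent = list(range(len(fragments)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used: set[int] = set()
    accepted: dict[tuple[int, int], tuple[int, int]] = {}
    for score, a, b, gap in sorted(cands, key=lambda t: (t[0], t[1], t[2])):
        ia, ea, pa, _ = ends[a]
        ib, eb, pb, _ = ends[b]
        if a in used or b in used or find(ia) == find(ib):
            continue
        conn_int = _sample_connector(img, px, pa, pb)
        floor = params.intensity_ratio * min(fragments[ia].mean_intensity,
                                             fragments[ib].mean_intensity)
        if conn_int < floor:
            continue
        used.add(a)
        used.add(b)
        accepted[(ia, ea)] = (ib, eb)
        accepted[(ib, eb)] = (ia, ea)
        parent[find(ib)] = find(ia)

    fibers = _concatenate_fibers(fragments, accepted)
    return FiberSet(fibers, area)


def _sample_connector(img, px, pa, pb) -> float:
    gap = float(np.hypot(*(pb - pa)))
    n = max(int(math.ceil(gap / (0.5 * px))), 2)
    t = np.linspace(0.0, 1.0, n)
    xs = pa[0] + t * (pb[0] - pa[0])
    ys = pa[1] + t * (pb[1] - pa[1])
    rows = np.clip(ys / px - 0.5, 0, img.shape[0] - 1)
    cols = np.clip(xs / px - 0.5, 0, img.shape[1] - 1)
    vals = ndi.map_coordinates(img, [rows, cols], order=1)
    return float(vals.mean())


def _concatenate_fibers(fragments: list[FiberFragment],
                        accepted: dict) -> list[FiberFragment]:
    n = len(fragments)
    visited = [False] * n
    fibers = []
    for i in range(n):
        if visited[i]:
            continue
        cur, end = i, 0
        seen = {i}
        while (cur, end) in accepted:
            nxt, nend = accepted[(cur, end)]
            if nxt in seen:
                break
            seen.add(nxt)
            cur, end = nxt, 1 - nend
        pts = fragments[cur].points if end == 0 else fragments[cur].points[::-1]
        chain_pts = [pts]
        frag_lens = [fragments[cur].length_um]
        frag_ints = [fragments[cur].mean_intensity]
        visited[cur] = True
        pos, pend = cur, 1 - end
        while (pos, pend) in accepted:
            nxt, nend = accepted[(pos, pend)]
            if visited[nxt]:
                break
            seg = fragments[nxt].points if nend == 0 else fragments[nxt].points[::-1]
            chain_pts.append(seg)
            frag_lens.append(fragments[nxt].length_um)
            frag_ints.append(fragments[nxt].mean_intensity)
            visited[nxt] = True
            pos, pend = nxt, 1 - nend
        pts_all = np.vstack(chain_pts)
        seglen = np.hypot(*np.diff(pts_all, axis=0).T)
        length = float(seglen.sum())
        mean_int = float(np.average(frag_ints, weights=frag_lens))
        k = 5
        fibers.append(FiberFragment(
            points=pts_all, length_um=length, mean_intensity=mean_int,
            tangent_start=_end_tangent(pts_all, 0, k),
            tangent_end=_end_tangent(pts_all, -1, k)))
    return fibers


def length_metrics(fs: FiberSet) -> tuple[float | None, float]:
    """(mean fiber length in µm or None if empty, total-length density µm⁻¹).

    Mean length averages over the fibers of the field of view; total-length
    density sums all fiber lengths and divides by the searched area.
    """
    if fs.searched_area_um2 <= 0:
        raise ValueError("searched area must be > 0")
    return fs.mean_length_um, fs.total_length_density_per_um


# ---------------------------------------------------------------------------
# orientation field and alignment AUC
# ---------------------------------------------------------------------------

def orientation_field(proj: Projection, subregion_um: float = 3.0,
                      intensity_percentile: float = 35.0,
                      grad_sigma_px: float = 1.0) -> OrientationField:
    """Dominant axial fiber orientation per square subregion.

    Within each subregion the structure tensor of the intensity gradients is
    summed; the fiber orientation is the eigenvector of the smaller
    eigenvalue (along the ridges, perpendicular to the dominant gradient).
    Subregions overlapping the excluded mask, with mean intensity strictly
    below the given percentile of subregion means (computed over the
    boundary-free image), with no gradient energy, or touching the image
    border (where gradient estimates are padding-contaminated) are masked
    invalid.
    """
    if subregion_um <= 0:
        raise ValueError("subregion_um must be > 0")
    if not 0 <= intensity_percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    img = np.asarray(proj.image, float)
    px = proj.pixel_size_um
    s = int(round(subregion_um / px))
    if s < 1 or s > min(img.shape):
        raise ValueError("subregion larger than image (or below one pixel)")
    ny, nx = img.shape[0] // s, img.shape[1] // s
    crop = img[:ny * s, :nx * s]

    gy = ndi.gaussian_filter(crop, grad_sigma_px, order=(1, 0))
    gx = ndi.gaussian_filter(crop, grad_sigma_px, order=(0, 1))
    jxx = _block_sum(gx * gx, s)
    jyy = _block_sum(gy * gy, s)
    jxy = _block_sum(gx * gy, s)
    means = _block_sum(crop, s) / (s * s)

    # dominant gradient direction; fiber orientation is perpendicular
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = (phi + 0.5 * math.pi) % math.pi
    energy = jxx + jyy
    valid = energy > 1e-12 * max(energy.max(), 1.0)
    # image-border tiles see boundary-padded gradients; mask the outer ring
    if ny > 2 and nx > 2:
        border = np.ones_like(valid)
        border[1:-1, 1:-1] = False
        valid &= ~border
    if proj.excluded_mask is not None:
        excl = proj.excluded_mask[:ny * s, :nx * s]
        overlap = _block_sum(excl.astype(float), s) > 0
        valid &= ~overlap
        free = ~overlap
    else:
        free = np.ones_like(valid)
    if valid.any() and intensity_percentile > 0:
        cut = np.percentile(means[free], intensity_percentile) if free.any() \
            else -math.inf
        valid &= ~(means < cut)
    centers_x = (np.arange(nx) + 0.5) * s * px
    centers_y = (np.arange(ny) + 0.5) * s * px
    return OrientationField(theta, valid, centers_x, centers_y, subregion_um)


def _block_sum(a: np.ndarray, s: int) -> np.ndarray:
    ny, nx = a.shape[0] // s, a.shape[1] // s
    return a[:ny * s, :nx * s].reshape(ny, s, nx, s).sum(axis=(1, 3))


def alignment_auc(field: OrientationField, bin_width_um: float = 1.0,
                  max_distance_um: float = 50.0, n_null_reps: int = 20,
                  rng_seed: int = 0, normalized: bool = False) -> AlignmentCurve:
    """Alignment-versus-distance curve and its area over a repositioning null.

    For every pair of valid subregions closer than ``max_distance_um``, the
    alignment ``cos 2(theta_i - theta_j)`` is binned by center distance and
    averaged.  The null randomly permutes the orientations over the valid
    positions (conserving the orientation multiset), re-bins, and averages
    over ``n_null_reps`` replicates.  The AUC is the trapezoidal area of
    (experimental - null) over distance; positive values mean fibers align
    more with near neighbors than with the field at large.  With
    ``normalized=True`` the area is divided by ``max_distance_um**2``
    (units µm⁻¹); the unnormalized area in µm is the default report.
    """
    pts, theta = field.valid_points()
    m = pts.shape[0]
    if m < 2:
        raise ValueError("need at least 2 valid subregions")
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    pairs = tree.query_pairs(max_distance_um, output_type="ndarray")
    if pairs.shape[0] == 0:
        raise ValueError("no subregion pairs within max_distance_um")
    d = np.hypot(*(pts[pairs[:, 0]] - pts[pairs[:, 1]]).T)
    edges = np.arange(0.0, max_distance_um + bin_width_um, bin_width_um)
    nbins = edges.size - 1
    which = np.clip(np.digitize(d, edges) - 1, 0, nbins - 1)
    counts = np.bincount(which, minlength=nbins)

    def binned_mean(align):
        s = np.bincount(which, weights=align, minlength=nbins)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, s / np.maximum(counts, 1), np.nan)

    exp_curve = binned_mean(np.cos(2.0 * (theta[pairs[:, 0]] - theta[pairs[:, 1]])))

    rng = np.random.default_rng(rng_seed)
    reps = np.empty((n_null_reps, nbins))
    for r in range(n_null_reps):
        perm = rng.permutation(m)
        tp = theta[perm]
        reps[r] = binned_mean(np.cos(2.0 * (tp[pairs[:, 0]] - tp[pairs[:, 1]])))
    null_mean = reps.mean(axis=0)

    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    scale = max_distance_um ** 2 if normalized else 1.0
    auc = float(np.trapezoid((exp_curve - null_mean)[ok], centers[ok])) / scale
    auc_reps = np.array([
        float(np.trapezoid((exp_curve - reps[r])[ok], centers[ok]))
        for r in range(n_null_reps)]) / scale
    return AlignmentCurve(edges, exp_curve, null_mean, reps, auc, auc_reps)
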