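"""Calibrated z-stack reading and slab maximum-intensity projection.

A stack is imaged from the substrate to the apical surface; slabs are
specified as depth windows in µm measured downward from the apical-most
slice, with half-open intervals ``[z_lo, z_hi)``.  Default slabs: the apical
surface (top 4 µm), the basal cell plane (13 µm below the apical surface,
3 µm thick), and the stress-fiber plane (2.2 µm below the basal slab,
1.5 µm thick).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "SlabSpec",
    "Projection",
    "read_stack",
    "max_project",
    "default_slabs",
]

PlaneName = Literal["apical", "basal", "fiber"]


@dataclass
class ImageStack:
    """3D grayscale volume (z, y, x) with physical calibration."""

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D array")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def depth_um(self) -> np.ndarray:
        """Depth of each slice below the top-of-stack reference (z index 0)."""
        return np.arange(self.n_slices) * self.z_step_um


@dataclass(frozen=True)
class SlabSpec:
    """A depth window ``[z_lo_um, z_hi_um)`` below the apical reference."""

    plane_name: str
    z_lo_um: float
    z_hi_um: float

    def __post_init__(self) -> None:
        if not self.z_lo_um < self.z_hi_um:
            raise ValueError("z_lo_um must be < z_hi_um")


@dataclass
class Projection:
    """Maximum-intensity projection of one slab.

    ``excluded_mask`` is populated by downstream masking steps (boundary
    removal before fiber segmentation); it marks pixels excluded from the
    searched area.
    """

    image: np.ndarray
    plane_name: str
    pixel_size_um: float
    slab: SlabSpec | None = None
    excluded_mask: np.ndarray | None = None

    @property
    def fov_width_um(self) -> float:
        return self.image.shape[1] * self.pixel_size_um

    @property
    def fov_height_um(self) -> float:
        return self.image.shape[0] * self.pixel_size_um

    @property
    def searched_area_um2(self) -> float:
        n = self.image.size
        if self.excluded_mask is not None:
            n -= int(self.excluded_mask.sum())
        return n * self.pixel_size_um ** 2


def read_stack(path, pixel_size_um: float, z_step_um: float,
               apical: Literal["first", "last"] = "first") -> ImageStack:
    """Read a multi-page grayscale TIFF as a calibrated stack.

    Page order maps to ascending z index.  ``apical`` states which page holds
    the apical-most slice; with ``"last"`` (substrate-to-apical acquisition)
    the page order is reversed so that z index 0 is always apical.
    Intensities are returned unmodified.
    """
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: pages have inconsistent shapes {shapes}")
    if pages[0].ndim != 2:
        raise ValueError(f"{path}: pages must be single-channel grayscale")
    voxels = np.stack(pages, axis=0)
    if apical == "last":
        voxels = voxels[::-1]
    return ImageStack(voxels, pixel_size_um, z_step_um,
                      metadata={"path": str(path), "apical": apical})


def max_project(stack: ImageStack, slab: SlabSpec) -> Projection:
    """Maximum-intensity projection over the slices inside the slab window.

    A slice at depth ``d`` is selected when ``z_lo_um <= d < z_hi_um``.
    """
    sel = (stack.depth_um >= slab.z_lo_um) & (stack.depth_um < slab.z_hi_um)
    if not sel.any():
        raise ValueError(
            f"slab [{slab.z_lo_um}, {slab.z_hi_um}) um selects no slice "
            f"(stack depth range 0..{stack.depth_um[-1]} um)")
    image = stack.voxels[sel].max(axis=0)
    return Projection(image, slab.plane_name, stack.pixel_size_um, slab=slab)


def default_slabs(basal_depth_um: float = 13.0) -> dict[str, SlabSpec]:
    """Default apical/basal/fiber depth windows.

    ``basal_depth_um`` is the depth of the basal cell plane below the apical
    surface, overridable per field of view.  The fiber slab sits 2.2 µm below
    the bottom of the basal slab, toward the substrate.
    """
    basal_lo = basal_depth_um
    basal_hi = basal_depth_um + 3.0
    fiber_lo = basal_hi + 2.2
    return {
        "apical": SlabSpec("apical", 0.0, 4.0),
        "basal": SlabSpec("basal", basal_lo, basal_hi),
        "fiber": SlabSpec("fiber", fiber_lo, fiber_lo + 1.5),
    }
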