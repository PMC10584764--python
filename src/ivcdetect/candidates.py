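"""Stage 1: metallic-candidate generation.

Metal is far denser than any tissue on CT (> +2000 HU versus +700..+3000 HU
for bone), so candidate metallic objects can be found without scanning every
slice: take the maximum intensity projection (MIP) of the volume on the axial
plane, threshold it at +2000 HU, and label the surviving pixels into
8-connected components — each component gives the (x, y) footprint of one
metallic object. The same procedure on the coronal MIP gives (x, z)
footprints; pairing axial and coronal components along their shared x axis
triangulates a full 3-D center (x, y, z) and z extent for each candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct_io import BoundingBox3D, CTVolume

logger = logging.getLogger(__name__)

DEFAULT_HU_THRESHOLD = 2000.0
DEFAULT_CROP_SIZE = (64, 64, 96)
DEFAULT_MIN_COMPONENT_PX = 4
AIR_HU = -1024.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)

__all__ = [
    "ProjectionImage",
    "Component2D",
    "CandidateRegion",
    "compute_mip",
    "threshold_metal",
    "label_components",
    "triangulate_candidates",
    "extract_candidates",
    "crop_at",
]


@dataclass
class ProjectionImage:
    """2-D maximum intensity projection.

    ``plane="axial"`` collapses z and retains (x, y); ``plane="coronal"``
    collapses y and retains (x, z).
    """

    pixels: np.ndarray
    plane: str

    AXES = {"axial": ("x", "y"), "coronal": ("x", "z")}

    def __post_init__(self) -> None:
        if self.plane not in self.AXES:
            raise ValueError(f"unknown plane {self.plane!r}; expected axial|coronal")

    @property
    def axis_names(self) -> tuple[str, str]:
        return self.AXES[self.plane]


@dataclass
class Component2D:
    """One 8-connected supra-threshold component of a projection."""

    label: int
    pixels: np.ndarray          # (n, 2) integer coordinates in projection axes
    centroid: tuple[float, float]
    box_min: tuple[int, int]    # half-open 2-D box
    box_max: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.pixels)

    def x_interval(self) -> tuple[int, int]:
        # First projection axis is x on both planes.
        return self.box_min[0], self.box_max[0]


@dataclass
class CandidateRegion:
    """A metallic candidate: triangulated center, tight box, fixed-size crop."""

    component_id: int
    center: tuple[int, int, int]
    box: BoundingBox3D
    crop: np.ndarray = field(repr=False)


def compute_mip(volume: CTVolume, plane: str) -> ProjectionImage:
    """Maximum intensity projection along one axis of the volume."""
    if plane == "axial":
        pixels = volume.voxels.max(axis=2)  # collapse z -> (x, y)
    elif plane == "coronal":
        pixels = volume.voxels.max(axis=1)  # collapse y -> (x, z)
    else:
        raise ValueError(f"unknown plane {plane!r}; expected axial|coronal")
    return ProjectionImage(pixels=pixels, plane=plane)


def threshold_metal(
    projection: ProjectionImage, hu_threshold: float = DEFAULT_HU_THRESHOLD
) -> np.ndarray:
    """Binary metal mask: pixels at or above the threshold are retained."""
    return projection.pixels >= hu_threshold


def label_components(
    mask: np.ndarray, min_component_px: int = DEFAULT_MIN_COMPONENT_PX
) -> list[Component2D]:
    """Partition a binary mask into maximal 8-connected components.

    Components with fewer than ``min_component_px`` pixels are discarded
    (single-voxel noise suppression); pass 1 to keep everything.
    """
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    out: list[Component2D] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labeled == lab)
        if len(coords) < min_component_px:
            continue
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        out.append(
            Component2D(
                label=lab,
                pixels=coords,
                centroid=tuple(coords.mean(axis=0)),
                box_min=tuple(int(v) for v in lo),
                box_max=tuple(int(v) for v in hi),
            )
        )
    return out


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def crop_at(
    volume: CTVolume,
    center: tuple[int, int, int],
    crop_size: tuple[int, int, int],
    pad_value: float = AIR_HU,
) -> np.ndarray:
    """Fixed-size crop centered at ``center``; out-of-volume voxels get air HU."""
    out = np.full(crop_size, pad_value, dtype=np.float32)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for ax in range(3):
        lo = int(center[ax]) - crop_size[ax] // 2
        hi = lo + crop_size[ax]
        s_lo = max(lo, 0)
        s_hi = min(hi, volume.shape[ax])
        if s_lo >= s_hi:
            return out
        src_lo.append(s_lo)
        src_hi.append(s_hi)
        dst_lo.append(s_lo - lo)
        dst_hi.append(s_hi - lo)
    out[dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]] = (
        volume.voxels[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]]
    )
    return out


def triangulate_candidates(
    axial_components: list[Component2D],
    coronal_components: list[Component2D],
    volume: CTVolume,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
) -> list[CandidateRegion]:
    """Pair axial (x, y) components with coronal (x, z) components.

    Each axial component is matched to the coronal component whose x interval
    overlaps it most (ties: nearest x centroid, then larger component); the
    pair yields a 3-D center and a tight box whose x/y extent comes from the
    axial component and z extent from the coronal one. Axial components with
    no x-overlapping coronal partner are dropped with a warning — several
    objects sharing x extent cannot be disambiguated by two projections.
    """
    out: list[CandidateRegion] = []
    for cid, ax_comp in enumerate(axial_components):
        best = None
        for cor_comp in coronal_components:
            ov = _interval_overlap(ax_comp.x_interval(), cor_comp.x_interval())
            if ov <= 0:
                continue
            key = (
                ov,
                -abs(ax_comp.centroid[0] - cor_comp.centroid[0]),
                cor_comp.size,
            )
            if best is None or key > best[0]:
                best = (key, cor_comp)
        if best is None:
            logger.warning(
                "axial component %d (x interval %s) has no coronal partner; dropped",
                ax_comp.label,
                ax_comp.x_interval(),
            )
            continue
        cor_comp = best[1]
        cx = int(round(ax_comp.centroid[0]))
        cy = int(round(ax_comp.centroid[1]))
        cz = int(round(cor_comp.centroid[1]))
        box = BoundingBox3D(
            min=(ax_comp.box_min[0], ax_comp.box_min[1], cor_comp.box_min[1]),
            max=(ax_comp.box_max[0], ax_comp.box_max[1], cor_comp.box_max[1]),
        )
        out.append(
            CandidateRegion(
                component_id=cid,
                center=(cx, cy, cz),
                box=box,
                crop=crop_at(volume, (cx, cy, cz), crop_size),
            )
        )
    return out


def extract_candidates(
    volume: CTVolume,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> list[CandidateRegion]:
    """Full stage 1: MIP -> threshold -> label -> triangulate."""
    axial = label_components(
        threshold_metal(compute_mip(volume, "axial"), hu_threshold), min_component_px
    )
    coronal = label_components(
        threshold_metal(compute_mip(volume, "coronal"), hu_threshold), min_component_px
    )
    return triangulate_candidates(axial, coronal, volume, crop_size)
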