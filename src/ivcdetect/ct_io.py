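"""CT volume and annotation I/O.

All downstream stages work in a single voxel coordinate convention:
``voxels[x, y, z]`` with x = left-right column, y = anterior-posterior row,
z = superior-inferior slice, 0-based indices, and half-open bounding boxes
``[min, max)``. Intensities are Hounsfield units (HU). NIfTI volumes are
reoriented to closest-canonical (RAS) at load so that orientation metadata
never leaks past this module; DICOM series are stacked by slice position and
rescaled to HU with the slope/intercept tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

HU_MIN = -2048.0
HU_MAX = 4096.0

__all__ = [
    "CTVolume",
    "BoundingBox3D",
    "Annotation",
    "CalibrationError",
    "GeometryError",
    "AnnotationError",
    "load_volume",
    "save_volume",
    "load_annotations",
    "save_annotations",
]


class CalibrationError(ValueError):
    """Raised when intensities cannot be mapped to a plausible HU range."""


class GeometryError(ValueError):
    """Raised when slice geometry is inconsistent (gaps, mixed series)."""


class AnnotationError(ValueError):
    """Raised when an annotation violates the volume extent or schema."""


@dataclass(frozen=True)
class BoundingBox3D:
    """Half-open axis-aligned box in voxel indices: ``[min, max)`` per axis."""

    min: tuple[int, int, int]
    max: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.min) != 3 or len(self.max) != 3:
            raise AnnotationError("box corners must be 3-vectors")
        object.__setattr__(self, "min", tuple(int(v) for v in self.min))
        object.__setattr__(self, "max", tuple(int(v) for v in self.max))
        for lo, hi in zip(self.min, self.max):
            if lo >= hi:
                raise AnnotationError(
                    f"degenerate box: min {self.min} not < max {self.max} on every axis"
                )

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((lo + hi) / 2.0 for lo, hi in zip(self.min, self.max))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.min, self.max))

    def volume(self) -> int:
        s = self.shape
        return s[0] * s[1] * s[2]

    def contains_point(self, point: Sequence[float]) -> bool:
        return all(lo <= p < hi for lo, p, hi in zip(self.min, point, self.max))

    def within(self, shape: Sequence[int]) -> bool:
        return all(lo >= 0 for lo in self.min) and all(
            hi <= s for hi, s in zip(self.max, shape)
        )

    def to_dict(self) -> dict:
        return {"min": list(self.min), "max": list(self.max)}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox3D":
        return cls(min=tuple(d["min"]), max=tuple(d["max"]))


@dataclass
class CTVolume:
    """A 3-D grid of HU intensities with physical spacing metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError("volume must be 3-D with every dimension >= 1")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise CalibrationError(
                f"intensity range [{lo:.0f}, {hi:.0f}] outside plausible HU "
                f"range [{HU_MIN:.0f}, {HU_MAX:.0f}]; data may be uncalibrated"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Annotation:
    """Ground-truth boxes for one volume.

    ``labels[i]`` is ``"filter"`` or ``"metal"``; ``filter_type[i]`` is
    ``"retrievable"``/``"non_retrievable"`` for filter boxes and None otherwise.
    """

    volume_shape: tuple[int, int, int]
    boxes: list[BoundingBox3D] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    filter_type: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.boxes) == len(self.labels) == len(self.filter_type)):
            raise AnnotationError("boxes, labels and filter_type must align")
        for i, (box, label, ftype) in enumerate(
            zip(self.boxes, self.labels, self.filter_type)
        ):
            if label not in ("filter", "metal"):
                raise AnnotationError(f"box {i}: unknown label {label!r}")
            if not box.within(self.volume_shape):
                raise AnnotationError(
                    f"box {i} {box.to_dict()} outside volume extent {self.volume_shape}"
                )
            if label == "filter":
                if ftype not in ("retrievable", "non_retrievable"):
                    raise AnnotationError(
                        f"box {i}: filter box needs filter_type, got {ftype!r}"
                    )
            elif ftype is not None:
                raise AnnotationError(
                    f"box {i}: filter_type only allowed on filter boxes"
                )

    def filter_boxes(self) -> list[BoundingBox3D]:
        return [b for b, l in zip(self.boxes, self.labels) if l == "filter"]

    def to_dict(self) -> dict:
        return {
            "volume_shape": list(self.volume_shape),
            "boxes": [
                {**box.to_dict(), "label": label, "filter_type": ftype}
                for box, label, ftype in zip(self.boxes, self.labels, self.filter_type)
            ],
        }


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    NIfTI images are reoriented to closest-canonical axes before the data
    array is taken, so a load of an already-canonical file is a no-op on the
    voxel grid. DICOM series must share one SeriesInstanceUID, carry rescale
    slope/intercept, and have uniform slice spacing (5% tolerance).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with an RAS-diagonal affine built from spacing."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _load_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise GeometryError(f"no DICOM files under {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise GeometryError(f"directory mixes {len(uids)} DICOM series")
    for ds in slices:
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise CalibrationError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; cannot calibrate to HU"
            )

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zpos) > 1:
        steps = np.diff(zpos)
        if steps.min() <= 0:
            raise GeometryError("duplicate or unordered slice positions")
        if (steps.max() - steps.min()) / steps.mean() > 0.05:
            raise GeometryError(
                f"inconsistent slice spacing: steps span "
                f"[{steps.min():.3f}, {steps.max():.3f}] mm (gap in series?)"
            )
        dz = float(steps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    hu = np.stack(
        [
            ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
            for ds in slices
        ],
        axis=-1,
    )  # (row, col, z)
    # pixel_array is (row=y, col=x); move to (x, y, z)
    hu = np.transpose(hu, (1, 0, 2))
    py, px = (float(v) for v in slices[0].PixelSpacing)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return CTVolume(voxels=hu, spacing=(px, py, dz), origin=origin)


def load_annotations(path: str | Path) -> Annotation:
    """Parse an annotation JSON file (see :meth:`Annotation.to_dict` schema)."""
    with open(path) as fh:
        raw = json.load(fh)
    boxes, labels, ftypes = [], [], []
    for entry in raw.get("boxes", []):
        boxes.append(BoundingBox3D(min=tuple(entry["min"]), max=tuple(entry["max"])))
        labels.append(entry["label"])
        ftypes.append(entry.get("filter_type"))
    return Annotation(
        volume_shape=tuple(raw["volume_shape"]),
        boxes=boxes,
        labels=labels,
        filter_type=ftypes,
    )


def save_annotations(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ann.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
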