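"""Crop normalization and training-time augmentation.

Z-score normalization maps each crop to zero mean / unit variance so that
every training sample has a comparable intensity distribution regardless of
how much metal it contains. Augmentation enlarges the training set with
small integer shifts along all three axes (default [-3, 3] voxels) and small
in-plane rotations (default 2-5 degrees, random sign); both emulate patient
positioning variation. Augmentation is for training only — inference sees
un-augmented crops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["AugmentSpec", "zscore_normalize", "augment"]


@dataclass
class AugmentSpec:
    """Ranges for random shift (voxels, symmetric) and rotation (degrees)."""

    shift_range: tuple[int, int] = (-3, 3)
    rot_range_deg: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.shift_range
        if lo != -hi or lo > 0:
            raise ValueError(f"shift range must be symmetric [-s, s], got {self.shift_range}")
        rlo, rhi = self.rot_range_deg
        if not (0 <= rlo <= rhi):
            raise ValueError(f"rotation range must satisfy 0 <= lo <= hi, got {self.rot_range_deg}")


def zscore_normalize(crop: np.ndarray) -> np.ndarray:
    """(x - mean) / std; a constant input maps to all zeros."""
    crop = np.asarray(crop, dtype=np.float64)
    if crop.size == 0:
        raise ValueError("empty crop")
    sd = crop.std()
    if sd == 0.0:
        logger.debug("constant crop in zscore_normalize; returning zeros")
        return np.zeros_like(crop)
    return (crop - crop.mean()) / sd


def augment(crop: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Random integer shift on (x, y, z) plus a random in-plane rotation.

    The rotation is about the z axis (axial plane), magnitude drawn uniformly
    in ``rot_range_deg`` with random sign, linear interpolation; voxels
    vacated by either transform are filled with the crop minimum.
    """
    crop = np.asarray(crop, dtype=np.float64)
    fill = float(crop.min())
    lo, hi = spec.shift_range
    shift = rng.integers(lo, hi + 1, size=3)
    out = np.full_like(crop, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax in range(3):
        s = int(shift[ax])
        n = crop.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax], src[ax] = slice(s, n), slice(0, n - s)
        else:
            dst[ax], src[ax] = slice(0, n + s), slice(-s, n)
    out[tuple(dst)] = crop[tuple(src)]

    rlo, rhi = spec.rot_range_deg
    angle = float(rng.uniform(rlo, rhi)) * (1 if rng.random() < 0.5 else -1)
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=fill
        )
    return out
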