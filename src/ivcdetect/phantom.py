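"""Seeded synthetic abdominal-CT phantoms with ground truth.

The generator emulates the intensity regimes and shape contrasts the
detection method depends on, not anatomy: a noisy soft-tissue body
(~40 +/- 15 HU) inside an air border (-1000 HU), an optional posterior bone
column (~1100 HU), and metallic objects painted at 2200-3000 HU — above the
+2000 HU metal threshold, as real implants are. Object kinds:

* ``filter_plain``    — a conical cage of 4-8 thin struts converging to a
                        superior apex (the shape of a caval filter);
* ``filter_hooked``   — the same cage plus a short curved retrieval hook
                        above the apex; the hook is the only voxel-level
                        difference between the two filter classes, mirroring
                        how a hook at the superior pole marks a filter as
                        retrievable;
* ``clip``            — a compact surgical-clip blob;
* ``stent``           — a hollow metal tube along z;
* ``spine_rod``       — a long z-aligned rod inside the bone column
                        (spinal fusion hardware).

Everything is deterministic under the spec seed. Randomized datasets jitter
object placement, size (+/-25%), strut count and metal HU per sample, and
keep objects disjoint in their x intervals so dual-projection triangulation
is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .candidates import extract_candidates, crop_at, DEFAULT_CROP_SIZE
from .ct_io import Annotation, BoundingBox3D, CTVolume

OBJECT_KINDS = ("filter_hooked", "filter_plain", "clip", "stent", "spine_rod")
METAL_HU_RANGE = (2200.0, 3000.0)

__all__ = [
    "ObjectSpec",
    "PhantomSpec",
    "PhantomSample",
    "PhantomSpecError",
    "generate_phantom",
    "generate_dataset",
    "make_detection_crops",
    "make_type_crops",
]


class PhantomSpecError(ValueError):
    pass


@dataclass
class ObjectSpec:
    kind: str
    center: tuple[int, int, int]
    size: float  # characteristic dimension: cage radius, clip half-width, ...
    metal_hu: float | None = None  # None -> sampled uniformly in [2200, 3000]

    def __post_init__(self) -> None:
        if self.kind not in OBJECT_KINDS:
            raise PhantomSpecError(f"unknown object kind {self.kind!r}")
        if self.metal_hu is not None and self.metal_hu < 2000:
            raise PhantomSpecError("metal_hu must be >= 2000 HU")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_mean: float = 40.0
    tissue_sd: float = 15.0
    air_hu: float = -1000.0
    bone_hu: float = 1100.0
    include_bone: bool = True
    noise_sd: float = 5.0
    objects: list[ObjectSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class PhantomSample:
    volume: CTVolume
    annotation: Annotation
    spec: PhantomSpec


def _paint_line(coords: set, p0, p1) -> None:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = int(np.ceil(2 * np.linalg.norm(p1 - p0))) + 1
    for t in np.linspace(0.0, 1.0, n):
        q = p0 + t * (p1 - p0)
        coords.add(tuple(int(round(v)) for v in q))


def _filter_voxels(
    center, radius: float, height: float, n_struts: int, phase: float, hooked: bool,
    hook_angle: float,
) -> set:
    """Conical wire cage: struts from a superior apex to an inferior rim.

    The apex sits at ``center_z + height/2`` (superior); for hooked filters a
    quarter-circle retrieval hook (radius ~4 voxels) rises above the apex.
    """
    cx, cy, cz = center
    apex = (cx, cy, cz + height / 2.0)
    coords: set = set()
    for k in range(n_struts):
        ang = phase + 2 * np.pi * k / n_struts
        base = (cx + radius * np.cos(ang), cy + radius * np.sin(ang), cz - height / 2.0)
        _paint_line(coords, apex, base)
    if hooked:
        r_h = 4.0
        for theta in np.linspace(0.0, np.pi / 2, 12):
            q = (
                apex[0] + r_h * (1 - np.cos(theta)) * np.cos(hook_angle),
                apex[1] + r_h * (1 - np.cos(theta)) * np.sin(hook_angle),
                apex[2] + 1 + r_h * np.sin(theta),
            )
            coords.add(tuple(int(round(v)) for v in q))
    return coords


def _clip_voxels(center, size: float) -> set:
    cx, cy, cz = center
    s = max(1, int(round(size)))
    return {
        (x, y, z)
        for x in range(cx - s, cx + s + 1)
        for y in range(cy - s, cy + s + 1)
        for z in range(cz - s - 1, cz + s + 2)
    }


def _stent_voxels(center, radius: float, height: float) -> set:
    cx, cy, cz = center
    coords: set = set()
    for z in range(int(cz - height / 2), int(cz + height / 2) + 1):
        for ang in np.linspace(0, 2 * np.pi, int(8 * radius), endpoint=False):
            coords.add(
                (int(round(cx + radius * np.cos(ang))),
                 int(round(cy + radius * np.sin(ang))), z)
            )
    return coords


def _rod_voxels(center, radius: float, length: float) -> set:
    cx, cy, cz = center
    coords: set = set()
    r = int(np.ceil(radius))
    for z in range(int(cz - length / 2), int(cz + length / 2) + 1):
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                if dx * dx + dy * dy <= radius * radius:
                    coords.add((cx + dx, cy + dy, z))
    return coords


def _object_voxels(obj: ObjectSpec, rng: np.random.Generator) -> set:
    if obj.kind in ("filter_hooked", "filter_plain"):
        n_struts = int(rng.integers(4, 9))
        phase = float(rng.uniform(0, 2 * np.pi))
        hook_angle = float(rng.uniform(0, 2 * np.pi))
        return _filter_voxels(
            obj.center,
            radius=obj.size,
            height=obj.size * 10.0 / 3.0,
            n_struts=n_struts,
            phase=phase,
            hooked=obj.kind == "filter_hooked",
            hook_angle=hook_angle,
        )
    if obj.kind == "clip":
        return _clip_voxels(obj.center, obj.size)
    if obj.kind == "stent":
        return _stent_voxels(obj.center, radius=obj.size, height=obj.size * 3.5)
    if obj.kind == "spine_rod":
        return _rod_voxels(obj.center, radius=obj.size, length=obj.size * 30.0)
    raise PhantomSpecError(obj.kind)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a phantom and its ground-truth annotation, deterministically."""
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.shape
    vol = rng.normal(spec.tissue_mean, spec.tissue_sd, size=spec.shape)

    # elliptical body cross-section; outside is air
    xs, ys = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    body = ((xs - X / 2) / (0.46 * X)) ** 2 + ((ys - Y / 2) / (0.42 * Y)) ** 2 <= 1.0
    vol[~body] = spec.air_hu

    if spec.include_bone:
        bx, by, br = X // 2, int(0.76 * Y), max(6, X // 16)
        bone = (xs - bx) ** 2 + (ys - by) ** 2 <= br**2
        vol[bone & body] = spec.bone_hu

    boxes, labels, ftypes = [], [], []
    for obj in spec.objects:
        hu = obj.metal_hu
        if hu is None:
            hu = float(rng.uniform(*METAL_HU_RANGE))
        coords = _object_voxels(obj, rng)
        arr = np.array(sorted(coords))
        if (arr < 0).any() or (arr >= np.array(spec.shape)).any():
            raise PhantomSpecError(
                f"object {obj.kind} at {obj.center} extends outside the volume"
            )
        box = BoundingBox3D(min=tuple(arr.min(axis=0)), max=tuple(arr.max(axis=0) + 1))
        for prev in boxes:
            inter = all(
                min(box.max[a], prev.max[a]) > max(box.min[a], prev.min[a])
                for a in range(3)
            )
            if inter:
                raise PhantomSpecError(
                    f"object {obj.kind} at {obj.center} overlaps a previous object"
                )
        vol[arr[:, 0], arr[:, 1], arr[:, 2]] = hu
        boxes.append(box)
        is_filter = obj.kind.startswith("filter")
        labels.append("filter" if is_filter else "metal")
        ftypes.append(
            None
            if not is_filter
            else ("retrievable" if obj.kind == "filter_hooked" else "non_retrievable")
        )

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = np.clip(vol, -1024.0, 3095.0).astype(np.float32)

    annotation = Annotation(
        volume_shape=spec.shape, boxes=boxes, labels=labels, filter_type=ftypes
    )
    return PhantomSample(
        volume=CTVolume(voxels=vol, spacing=spec.spacing),
        annotation=annotation,
        spec=spec,
    )


# x slots keep object x intervals disjoint so triangulation is unambiguous;
# the filter takes a central slot (caval position), confounders the rest.
_FILTER_SLOTS = (0.38, 0.62)
_CONFOUNDER_SLOTS = (0.13, 0.88)


def _random_filter_object(rng, shape, kind) -> ObjectSpec:
    X, Y, Z = shape
    size = 9.0 * float(rng.uniform(0.75, 1.25))
    cx = int(X * rng.choice(_FILTER_SLOTS)) + int(rng.integers(-3, 4))
    cy = int(Y * 0.45) + int(rng.integers(-5, 6))
    cz = int(rng.integers(int(0.35 * Z), int(0.6 * Z)))
    return ObjectSpec(kind=kind, center=(cx, cy, cz), size=size)


def _random_confounders(rng, shape, n: int) -> list[ObjectSpec]:
    X, Y, Z = shape
    out = []
    slots = list(rng.permutation(len(_CONFOUNDER_SLOTS)))
    kinds = list(rng.choice(["clip", "stent", "spine_rod"], size=n))
    for i, kind in enumerate(kinds):
        if kind == "spine_rod":
            size = 2.0 * float(rng.uniform(0.75, 1.25))
            center = (X // 2, int(0.76 * Y), int(rng.integers(int(0.3 * Z), int(0.7 * Z))))
        else:
            frac = _CONFOUNDER_SLOTS[slots[i % len(slots)]]
            size = (2.0 if kind == "clip" else 5.0) * float(rng.uniform(0.75, 1.25))
            cx = int(X * frac) + int(rng.integers(-3, 4))
            cy = int(Y * 0.5) + int(rng.integers(-10, 11))
            cz = int(rng.integers(int(0.2 * Z), int(0.8 * Z)))
            center = (cx, cy, cz)
        out.append(ObjectSpec(kind=kind, center=center, size=size))
    # only one spine rod fits the bone column; drop extras
    seen_rod = False
    dedup = []
    for obj in out:
        if obj.kind == "spine_rod":
            if seen_rod:
                continue
            seen_rod = True
        dedup.append(obj)
    return dedup


def generate_dataset(
    n_per_class: int,
    classes: tuple[str, ...] = ("filter_hooked", "filter_plain"),
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    confounders: tuple[int, int] = (0, 3),
):
    """Balanced randomized phantom set; returns (samples, manifest).

    Each sample holds one filter of the requested class plus 0-3 metallic
    confounders; placement, size (+/-25%), strut count and metal HU vary per
    sample. The manifest records every resolved spec.
    """
    if n_per_class < 1:
        raise PhantomSpecError("n_per_class must be >= 1")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    samples, manifest = [], []
    sid = 0
    for cls in classes:
        for _ in range(n_per_class):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            objs = [_random_filter_object(rng, base.shape, cls)]
            n_conf = int(rng.integers(confounders[0], confounders[1] + 1))
            objs += _random_confounders(rng, base.shape, n_conf)
            spec = replace(base, objects=objs, seed=sub_seed)
            for attempt in range(20):
                try:
                    sample = generate_phantom(spec)
                    break
                except PhantomSpecError:
                    # rare overlap from jitter: reroll confounders
                    objs = [objs[0]] + _random_confounders(
                        rng, base.shape, len(objs) - 1
                    )
                    spec = replace(base, objects=objs, seed=sub_seed)
            else:
                raise PhantomSpecError("could not place objects without overlap")
            samples.append(sample)
            manifest.append(
                {
                    "id": sid,
                    "class": cls,
                    "seed": sub_seed,
                    "n_objects": len(objs),
                    "objects": ";".join(o.kind for o in objs),
                    "filter_center": list(objs[0].center),
                    "filter_size": round(objs[0].size, 3),
                }
            )
            sid += 1
    return samples, manifest


def make_detection_crops(
    n_per_class: int,
    seed: int = 0,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    base_spec: PhantomSpec | None = None,
):
    """Labeled candidate crops for filter/no-filter training.

    Runs real stage-1 candidate extraction on randomized phantoms and labels
    each candidate by whether its center falls inside a ground-truth filter
    box. Returns exactly ``n_per_class`` positives and negatives.
    """
    crops, labels = [], []
    n_pos = n_neg = 0
    chunk = 0
    while n_pos < n_per_class or n_neg < n_per_class:
        samples, _ = generate_dataset(
            n_per_class=max(4, n_per_class // 4),
            classes=("filter_hooked", "filter_plain"),
            base_spec=base_spec,
            seed=seed + 7919 * chunk,
            confounders=(1, 3),
        )
        chunk += 1
        for sample in samples:
            truth = sample.annotation.filter_boxes()
            for cand in extract_candidates(sample.volume, crop_size=crop_size):
                is_filter = any(b.contains_point(cand.center) for b in truth)
                if is_filter and n_pos < n_per_class:
                    crops.append(cand.crop)
                    labels.append(1)
                    n_pos += 1
                elif not is_filter and n_neg < n_per_class:
                    crops.append(cand.crop)
                    labels.append(0)
                    n_neg += 1
            if n_pos >= n_per_class and n_neg >= n_per_class:
                break
        if chunk > 50:
            raise RuntimeError("failed to harvest enough candidates")
    return crops, labels


def make_type_crops(
    n_per_class: int,
    seed: int = 0,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    base_spec: PhantomSpec | None = None,
):
    """Filter-centered crops for retrievable (hooked, label 1) vs
    non-retrievable (plain, label 0) training."""
    samples, _ = generate_dataset(
        n_per_class=n_per_class,
        classes=("filter_hooked", "filter_plain"),
        base_spec=base_spec,
        seed=seed,
        confounders=(0, 2),
    )
    crops, labels = [], []
    for sample in samples:
        for box, label, ftype in zip(
            sample.annotation.boxes,
            sample.annotation.labels,
            sample.annotation.filter_type,
        ):
            if label != "filter":
                continue
            center = tuple(int(round(c)) for c in box.center)
            crops.append(crop_at(sample.volume, center, crop_size))
            labels.append(1 if ftype == "retrievable" else 0)
    return crops, labels
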