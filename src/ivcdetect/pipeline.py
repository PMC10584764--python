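"""End-to-end orchestration of the three stages.

``run_detection`` chains candidate generation, per-candidate classification,
a confidence gate (default 0.7: a prediction counts as a filter only above
it), and 3-D non-maximum suppression. ``run_type_classification`` re-crops
each confirmed detection with the type-stage HU floor of 0 (keeping metal
and surrounding tissue) and classifies retrievable vs non-retrievable. An
empty detection list means "no filter present". The whole pipeline is a pure
function of (volume, checkpoints, config).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import models
from .candidates import (
    DEFAULT_CROP_SIZE,
    DEFAULT_HU_THRESHOLD,
    DEFAULT_MIN_COMPONENT_PX,
    crop_at,
    extract_candidates,
)
from .ct_io import BoundingBox3D, CTVolume

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "TypePrediction",
    "PipelineConfig",
    "iou",
    "nms",
    "run_detection",
    "run_type_classification",
    "detections_to_json",
]


@dataclass
class Detection:
    """A confirmed filter location: box + softmax confidence + source id."""

    box: BoundingBox3D
    confidence: float
    candidate_id: int


@dataclass
class TypePrediction:
    """Retrievable probability for one detection; label at the cut-off."""

    detection_id: int
    p_retrievable: float
    label: str  # "retrievable" | "non_retrievable"


@dataclass
class PipelineConfig:
    confidence_threshold: float = 0.7
    nms_iou_threshold: float = 0.5
    type_cutoff: float = 0.5
    candidate_mode: str = "all"  # all | top1
    hu_threshold: float = DEFAULT_HU_THRESHOLD
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "nms_iou_threshold", "type_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.candidate_mode not in ("all", "top1"):
            raise ValueError(f"candidate_mode must be all|top1, got {self.candidate_mode}")


def iou(a: BoundingBox3D, b: BoundingBox3D) -> float:
    """Intersection over union of two half-open 3-D boxes, on voxel counts."""
    inter = 1
    for ax in range(3):
        lo = max(a.min[ax], b.min[ax])
        hi = min(a.max[ax], b.max[ax])
        if hi <= lo:
            return 0.0
        inter *= hi - lo
    union = a.volume() + b.volume() - inter
    return inter / union


def nms(
    detections: list[Detection],
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.7,
) -> list[Detection]:
    """Confidence gate then greedy non-maximum suppression.

    Detections below the confidence threshold are removed; the rest are
    scanned in descending confidence (ties: larger box, then lower candidate
    id) and any later box with IoU >= ``iou_threshold`` against a kept box is
    suppressed. Output pairwise IoU is therefore < ``iou_threshold``.
    """
    alive = [d for d in detections if d.confidence >= confidence_threshold]
    alive.sort(key=lambda d: (-d.confidence, -d.box.volume(), d.candidate_id))
    kept: list[Detection] = []
    for det in alive:
        if all(iou(det.box, k.box) < iou_threshold for k in kept):
            kept.append(det)
    return kept


def _clip_box(box: BoundingBox3D, shape) -> BoundingBox3D:
    return BoundingBox3D(
        min=tuple(max(0, m) for m in box.min),
        max=tuple(min(s, m) for m, s in zip(box.max, shape)),
    )


def run_detection(
    volume: CTVolume,
    model: models._BaseClassifier,
    config: PipelineConfig | None = None,
) -> list[Detection]:
    """Stage 1 + stage 2: candidates -> classify -> gate -> NMS.

    Returns an empty list (meaning "no filter present") when no voxel
    exceeds the metal threshold — the classifier is never invoked then.
    """
    config = config or PipelineConfig()
    cands = extract_candidates(
        volume,
        hu_threshold=config.hu_threshold,
        crop_size=config.crop_size,
        min_component_px=config.min_component_px,
    )
    if not cands:
        return []
    arch = model.config.architecture
    inputs = [
        models.prepare_input(
            c, arch, hu_floor=models.DETECTION_HU_FLOOR, n_slices=model.config.n_slices
        )
        for c in cands
    ]
    preds = models.predict_batch(model, inputs)
    raw = [
        Detection(
            box=_clip_box(c.box, volume.shape),
            confidence=p.probabilities[1],
            candidate_id=c.component_id,
        )
        for c, p in zip(cands, preds)
    ]
    out = nms(raw, config.nms_iou_threshold, config.confidence_threshold)
    logger.info("detection: %d candidates -> %d detections", len(cands), len(out))
    return out


def run_type_classification(
    volume: CTVolume,
    detections: list[Detection],
    type_model: models._BaseClassifier,
    config: PipelineConfig | None = None,
) -> list[TypePrediction]:
    """Stage 3: classify each detection (or only the most confident in
    ``top1`` mode) as retrievable vs non-retrievable."""
    config = config or PipelineConfig()
    if not detections:
        return []
    order = range(len(detections))
    if config.candidate_mode == "top1":
        order = [int(np.argmax([d.confidence for d in detections]))]
    out = []
    for i in order:
        det = detections[i]
        center = tuple(int(round(c)) for c in det.box.center)
        crop = crop_at(volume, center, config.crop_size)
        x = models.prepare_input(
            crop,
            type_model.config.architecture,
            hu_floor=models.TYPE_HU_FLOOR,
            n_slices=type_model.config.n_slices,
        )
        pred = models.predict(type_model, x)
        p_ret = pred.probabilities[1]
        out.append(
            TypePrediction(
                detection_id=i,
                p_retrievable=p_ret,
                label="retrievable" if p_ret >= config.type_cutoff else "non_retrievable",
            )
        )
    return out


def detections_to_json(
    volume_id: str,
    detections: list[Detection],
    type_predictions: list[TypePrediction] | None = None,
) -> str:
    """Serialize pipeline output; stable formatting for reproducible runs."""
    types = {tp.detection_id: tp for tp in (type_predictions or [])}
    payload = {
        "volume": volume_id,
        "detections": [
            {
                "box": det.box.to_dict(),
                "confidence": round(det.confidence, 9),
                "candidate_id": det.candidate_id,
                "type": (
                    {
                        "p_retrievable": round(types[i].p_retrievable, 9),
                        "label": types[i].label,
                    }
                    if i in types
                    else None
                ),
            }
            for i, det in enumerate(detections)
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)
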