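"""Stage 2/3 classifiers: filter/no-filter and retrievable/non-retrievable.

Two architectures, both binary softmax classifiers over a candidate crop S:

* ``mip2d`` — the crop is collapsed to its axial maximum intensity
  projection and classified by a 2-D CNN: backbone feature extractor, a
  fully connected layer, dropout 0.5, and a 2-node softmax output.
* ``recurrent`` — the crop is read as a sequence of axial slices; a shared
  per-slice CNN backbone produces one feature vector per slice, and a stack
  of gated recurrent units (16 then 8, dropout 0.5 between) aggregates the
  sequence before the 2-node softmax head. Padded slices carry an ignore
  mask so the padding value never influences the output.

Training minimizes binary cross-entropy with Adam (beta1 0.9, beta2 0.999)
at a fixed learning rate — 1e-4 for filter detection, 1e-5 for filter-type
classification — with early stopping on validation loss. The ``tiny``
backbone (three 3x3 conv blocks) trains in seconds on a CPU; a VGG-16
backbone is part of the configuration surface but requires a deep-learning
runtime with pretrained weights, which this build does not ship.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .candidates import CandidateRegion
from .preprocess import zscore_normalize

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-7
DETECTION_LR = 1e-4
TYPE_LR = 1e-5
DETECTION_HU_FLOOR = -1024.0   # keep everything
TYPE_HU_FLOOR = 0.0            # keep metal and the tissue around it

__all__ = [
    "ClassifierConfig",
    "Prediction",
    "TrainHistory",
    "SliceSequence",
    "ConfigError",
    "DataError",
    "bce_loss",
    "build_classifier",
    "prepare_input",
    "train_classifier",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class ClassifierConfig:
    architecture: str = "mip2d"            # mip2d | recurrent
    backbone: str = "tiny"                 # tiny | vgg16
    pretrained: bool = False
    input_hw: tuple[int, int] = (64, 64)
    n_slices: int = 20                     # recurrent sequence length
    fc_width: int = 256
    feature_dim: int = 32                  # per-slice feature vector (recurrent)
    dropout: float = 0.5
    gru_units: tuple[int, int] = (16, 8)
    learning_rate: float = DETECTION_LR
    batch_size: int = 16
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_epochs: int = 50
    patience: int = 5
    class_weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("mip2d", "recurrent"):
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        if self.backbone not in ("tiny", "vgg16"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if any(u <= 0 for u in self.gru_units):
            raise ConfigError("gru_units must be positive")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "ClassifierConfig":
        """Defaults per task: detection lr 1e-4, type lr 1e-5."""
        if task == "detection":
            overrides.setdefault("learning_rate", DETECTION_LR)
        elif task == "type":
            overrides.setdefault("learning_rate", TYPE_LR)
        else:
            raise ConfigError(f"unknown task {task!r}")
        return cls(**overrides)


@dataclass
class Prediction:
    """Softmax output: (p_negative, p_positive), argmax label, confidence."""

    probabilities: tuple[float, float]
    label: int
    confidence: float


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopping_reason: str = ""


@dataclass
class SliceSequence:
    """Fixed-length axial-slice sequence with a 0/1 validity mask."""

    slices: np.ndarray  # (T, H, W)
    mask: np.ndarray    # (T,)


def bce_loss(true_labels, predicted_probs) -> float:
    """Binary cross-entropy: -(1/N) sum[y log p + (1-y) log(1-p)].

    ``predicted_probs`` are probabilities of the positive class, clipped to
    [1e-7, 1 - 1e-7] before the logs.
    """
    y = np.asarray(true_labels, dtype=np.float64)
    p = np.asarray(predicted_probs, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probs")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _tiny_backbone(rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    """Three conv blocks; returns (layers, spatial downsampling factor)."""
    layers = nn.Sequential(
        [
            nn.Conv2D(1, 8, rng=rng),
            nn.ReLU(),
            nn.MaxPool2D(),
            nn.Conv2D(8, 16, rng=rng),
            nn.ReLU(),
            nn.MaxPool2D(),
            nn.Conv2D(16, 16, rng=rng),
            nn.ReLU(),
            nn.MaxPool2D(),
        ]
    )
    return layers, 8


class _BaseClassifier:
    config: ClassifierConfig

    def params(self):
        raise NotImplementedError

    def forward_logits(self, batch, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(v.size for _, v, _ in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [v.copy() for _, v, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (_, v, _), w in zip(self.params(), weights):
            v[...] = w


class Mip2DClassifier(_BaseClassifier):
    """Backbone -> FC -> dropout(0.5) -> 2-node softmax head."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        backbone, factor = _tiny_backbone(self.rng)
        h, w = config.input_hw
        flat = 16 * (h // factor) * (w // factor)
        if flat <= 0:
            raise ConfigError(f"input {config.input_hw} too small for the backbone")
        self.net = nn.Sequential(
            backbone.layers
            + [
                nn.Flatten(),
                nn.Dense(flat, config.fc_width, rng=self.rng),
                nn.ReLU(),
                nn.Dropout(config.dropout, rng=self.rng),
                nn.Dense(config.fc_width, 2, rng=self.rng),
            ]
        )

    def params(self):
        return self.net.params()

    def forward_logits(self, batch, train=False):
        x = np.asarray(batch, dtype=np.float32)[:, None, :, :]  # B,1,H,W
        return self.net.forward(x, train=train)

    def backward(self, grad):
        self.net.backward(grad)


class RecurrentClassifier(_BaseClassifier):
    """Shared per-slice backbone -> GRU(16) -> dropout -> GRU(8) -> head."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        backbone, factor = _tiny_backbone(self.rng)
        h, w = config.input_hw
        flat = 16 * (h // factor) * (w // factor)
        if flat <= 0:
            raise ConfigError(f"input {config.input_hw} too small for the backbone")
        self.backbone = nn.Sequential(
            backbone.layers
            + [
                nn.Flatten(),
                nn.Dense(flat, config.feature_dim, rng=self.rng),
                nn.ReLU(),
            ]
        )
        u1, u2 = config.gru_units
        self.gru1 = nn.GRU(config.feature_dim, u1, return_sequences=True, rng=self.rng)
        self.drop = nn.Dropout(config.dropout, rng=self.rng)
        self.gru2 = nn.GRU(u1, u2, return_sequences=False, rng=self.rng)
        self.head = nn.Dense(u2, 2, rng=self.rng)

    def params(self):
        out = []
        for prefix, mod in [
            ("backbone", self.backbone),
            ("gru1", self.gru1),
            ("drop", self.drop),
            ("gru2", self.gru2),
            ("head", self.head),
        ]:
            out.extend((f"{prefix}.{n}", v, g) for n, v, g in mod.params())
        return out

    def forward_logits(self, batch, train=False):
        seqs, mask = batch  # (B,T,H,W), (B,T)
        B, T, H, W = seqs.shape
        x = np.asarray(seqs, dtype=np.float32).reshape(B * T, 1, H, W)
        feats = self.backbone.forward(x, train=train).reshape(B, T, -1)
        h1 = self.gru1.forward(feats, train=train, mask=mask)
        h1 = self.drop.forward(h1, train=train)
        h2 = self.gru2.forward(h1, train=train, mask=mask)
        self._bt = (B, T)
        return self.head.forward(h2, train=train)

    def backward(self, grad):
        B, T = self._bt
        g = self.head.backward(grad)
        g = self.gru2.backward(g)
        g = self.drop.backward(g)
        g = self.gru1.backward(g)
        g = self.backbone.backward(g.reshape(B * T, -1))


def build_classifier(config: ClassifierConfig) -> _BaseClassifier:
    """Construct a classifier from its configuration.

    Only the ``tiny`` backbone is buildable here: the VGG-16 option needs a
    deep-learning runtime hosting the pretrained ImageNet weights.
    """
    if config.backbone == "vgg16":
        raise ConfigError(
            "backbone 'vgg16' is a configuration placeholder: it requires a "
            "deep-learning runtime with pretrained weights; use backbone='tiny'"
        )
    if config.pretrained:
        raise ConfigError("no pretrained weights exist for the tiny backbone")
    cls = Mip2DClassifier if config.architecture == "mip2d" else RecurrentClassifier
    model = cls(config)
    logger.info(
        "built %s/%s classifier with %d parameters",
        config.architecture,
        config.backbone,
        model.n_parameters(),
    )
    return model


def prepare_input(
    candidate: CandidateRegion | np.ndarray,
    architecture: str,
    hu_floor: float = DETECTION_HU_FLOOR,
    n_slices: int = 20,
):
    """Turn a candidate crop into a model input.

    Voxels below ``hu_floor`` are raised to it first (the type stage uses
    floor 0 HU to keep metal and surrounding tissue while discarding air and
    lung). ``mip2d`` then takes the z-score-normalized axial MIP; ``recurrent``
    takes ``n_slices`` evenly strided axial slices, each normalized, padding
    (with an ignore mask) when the crop has fewer slices.
    """
    crop = candidate.crop if isinstance(candidate, CandidateRegion) else candidate
    crop = np.maximum(np.asarray(crop, dtype=np.float64), hu_floor)
    if architecture == "mip2d":
        return zscore_normalize(crop.max(axis=2))
    if architecture == "recurrent":
        nz = crop.shape[2]
        idx = (np.arange(n_slices) * nz) // n_slices if nz >= n_slices else np.arange(nz)
        slices = np.stack([zscore_normalize(crop[:, :, k]) for k in idx])
        mask = np.ones(len(idx))
        if len(idx) < n_slices:
            pad = n_slices - len(idx)
            slices = np.concatenate([slices, np.zeros((pad,) + slices.shape[1:])])
            mask = np.concatenate([mask, np.zeros(pad)])
        return SliceSequence(slices=slices, mask=mask)
    raise ValueError(f"unknown architecture {architecture!r}")


def _batchify(inputs, architecture: str):
    if architecture == "mip2d":
        return np.stack(inputs)
    seqs = np.stack([s.slices for s in inputs]).astype(np.float32)
    mask = np.stack([s.mask for s in inputs]).astype(np.float32)
    return (seqs, mask)


def _forward_probs(model, inputs, architecture, batch_size=64):
    probs = []
    for i in range(0, len(inputs), batch_size):
        logits = model.forward_logits(
            _batchify(inputs[i : i + batch_size], architecture), train=False
        )
        probs.append(nn.softmax(logits))
    return np.concatenate(probs)


def train_classifier(train_set, val_set, config: ClassifierConfig):
    """Train a classifier; returns (model, TrainHistory).

    ``train_set``/``val_set`` are ``(inputs, labels)`` pairs where inputs are
    prepared model inputs (see :func:`prepare_input`) and labels are 0/1.
    Minimizes binary cross-entropy with Adam at the configured fixed learning
    rate; stops when validation loss has not improved for ``patience`` epochs
    and restores the best-validation weights.
    """
    tr_inputs, tr_labels = list(train_set[0]), np.asarray(train_set[1], dtype=int)
    va_inputs, va_labels = list(val_set[0]), np.asarray(val_set[1], dtype=int)
    if len(tr_inputs) == 0 or len(va_inputs) == 0:
        raise DataError("training and validation sets must be non-empty")
    if len(set(tr_labels.tolist())) < 2:
        raise DataError("training set contains a single class")

    model = build_classifier(config)
    opt = nn.Adam(
        model.params(),
        lr=config.learning_rate,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
    )
    rng = np.random.default_rng(config.seed + 1)

    sample_w = np.ones(len(tr_labels))
    if config.class_weighted:
        for c in (0, 1):
            sel = tr_labels == c
            sample_w[sel] = len(tr_labels) / (2.0 * sel.sum())

    history = TrainHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(tr_inputs))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            batch = _batchify([tr_inputs[j] for j in sel], config.architecture)
            labels = tr_labels[sel]
            w = sample_w[sel]
            logits = model.forward_logits(batch, train=True)
            probs = nn.softmax(logits)
            losses.append(bce_loss(labels, probs[:, 1]))
            onehot = np.eye(2, dtype=np.float32)[labels]
            grad = ((probs - onehot) * w[:, None] / len(sel)).astype(np.float32)
            model.backward(grad)
            opt.step()
        train_loss = float(np.mean(losses))
        val_probs = _forward_probs(model, va_inputs, config.architecture)
        val_loss = bce_loss(va_labels, val_probs[:, 1])
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopping_reason = (
                    f"validation loss failed to improve for {config.patience} epochs"
                )
                break
    if not history.stopping_reason:
        history.stopping_reason = f"reached max_epochs ({config.max_epochs})"
    model.set_weights(best_weights)
    return model, history


def predict(model: _BaseClassifier, model_input) -> Prediction:
    """Inference on one prepared input; dropout disabled, deterministic."""
    arch = model.config.architecture
    probs = _forward_probs(model, [model_input], arch)[0]
    label = int(np.argmax(probs))
    return Prediction(
        probabilities=(float(probs[0]), float(probs[1])),
        label=label,
        confidence=float(probs[label]),
    )


def predict_batch(model: _BaseClassifier, inputs) -> list[Prediction]:
    probs = _forward_probs(model, list(inputs), model.config.architecture)
    return [
        Prediction(
            probabilities=(float(p[0]), float(p[1])),
            label=int(np.argmax(p)),
            confidence=float(p.max()),
        )
        for p in probs
    ]


def save_checkpoint(model: _BaseClassifier, history: TrainHistory | None, path) -> None:
    """Weights as .npz plus a JSON sidecar with config and training metrics."""
    path = Path(path)
    arrays = {name: v for name, v, _ in model.params()}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": asdict(model.config),
        "n_parameters": model.n_parameters(),
        "history": asdict(history) if history is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_checkpoint(path) -> _BaseClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["config"]
    for key in ("input_hw", "gru_units"):
        cfg[key] = tuple(cfg[key])
    config = ClassifierConfig(**cfg)
    model = build_classifier(config)
    with np.load(path.with_suffix(".npz")) as data:
        weights = {k: data[k] for k in data.files}
    for name, v, _ in model.params():
        v[...] = weights[name]
    return model
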