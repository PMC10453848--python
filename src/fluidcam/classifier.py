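"""Per-pathology binary classifiers in the Inception-ResNet style.

One binary model is trained per pathology (IRF, SRF, PED). The network is
the residual-inception pattern: a convolutional stem, then three stages of
residual inception blocks (A, B, C) separated by spatial reduction blocks,
then global average pooling, dropout and a 2-way softmax. Block counts per
stage follow the published presets — ``standard`` (10, 20, 10), ``small``
(8, 7, 4) — plus a ``tiny`` (1, 1, 1) preset with reduced widths and input
size for desk-scale training. Branch filter widths inside the blocks are
not published for the small variant and are shared across presets here;
the parameter count roughly halves from ``standard`` to ``small`` through
the block counts alone.

Grayscale B-scans are bilinearly resized to ``input_size`` and replicated
to 3 channels before the forward pass. Training minimizes categorical
cross entropy with Adam (default learning rate 1e-4); initialization is
random with a stated seed, and ``set_weights`` accepts externally supplied
pretrained weights.

The classifier exposes the model protocol the CAM module needs: the
activations of the final convolutional stage and the gradient of any class
logit with respect to them (analytic here, since only global average
pooling and a linear layer sit between the two).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import ConfigError, DataError, ShapeError
from .types import PATHOLOGIES

_PRESETS = {
    # (blocks_a, blocks_b, blocks_c, stem_width, branch_width, input_size, lr)
    "standard": (10, 20, 10, 64, 48, 450, 1e-4),
    "small": (8, 7, 4, 64, 48, 450, 1e-4),
    "tiny": (1, 1, 1, 8, 8, 64, 3e-3),
}


@dataclass(frozen=True)
class ModelConfig:
    n_blocks_a: int = 10
    n_blocks_b: int = 20
    n_blocks_c: int = 10
    input_size: int = 450
    n_classes: int = 2
    learning_rate: float = 1e-4
    preset: str = "standard"
    stem_width: int = 64
    branch_width: int = 48
    dropout: float = 0.2

    def __post_init__(self):
        if min(self.n_blocks_a, self.n_blocks_b, self.n_blocks_c) < 1:
            raise ConfigError("block counts must be >= 1")
        if self.n_classes != 2:
            raise ConfigError("binary classifiers only: n_classes must be 2")
        if self.preset not in _PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "ModelConfig":
        if preset not in _PRESETS:
            raise ConfigError(f"unknown preset {preset!r}")
        a, b, c, sw, bw, size, lr = _PRESETS[preset]
        kw = dict(
            n_blocks_a=a, n_blocks_b=b, n_blocks_c=c,
            stem_width=sw, branch_width=bw, input_size=size,
            learning_rate=lr, preset=preset,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class PredictionVector:
    """Softmax class scores; ``positive_score`` is the pathology-present
    probability (class index 1)."""

    y_hat: np.ndarray
    positive_score: float


@dataclass(frozen=True)
class TrainingExample:
    image: np.ndarray  # 2-D grayscale
    y: np.ndarray  # one-hot target, length 2

    def __post_init__(self):
        y = np.asarray(self.y)
        if y.shape != (2,) or not np.isclose(y.sum(), 1.0) or set(np.unique(y)) - {0.0, 1.0}:
            raise ShapeError("y must be a one-hot vector of length 2")


def make_examples(images: np.ndarray, labels: np.ndarray) -> list[TrainingExample]:
    """Wrap (n, h, w) images and 0/1 labels as TrainingExamples."""
    eye = np.eye(2)
    return [TrainingExample(img, eye[int(lab)]) for img, lab in zip(images, labels)]


def cce_loss(y, y_hat) -> float:
    """Categorical cross entropy, natural log, predictions clamped to
    [1e-7, 1] to avoid log(0)."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ShapeError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(-(y * np.log(np.clip(y_hat, 1e-7, 1.0))).sum())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _branch(rng, *convs):
    layers = []
    for cin, cout, k, stride in convs:
        layers += [nn.Conv2d(cin, cout, k, stride, rng=rng), nn.ReLU()]
    return nn.Sequential(*layers)


def _inception_resnet_block(rng, channels, f, n_branches):
    """Residual inception block: parallel conv branches, 1x1 linear
    projection back to ``channels``, scaled residual add, ReLU."""
    if n_branches == 3:
        par = nn.Parallel(
            _branch(rng, (channels, f, 1, 1)),
            _branch(rng, (channels, f, 1, 1), (f, f, 3, 1)),
            _branch(rng, (channels, f, 1, 1), (f, f, 3, 1), (f, f, 3, 1)),
        )
        width = 3 * f
    else:
        par = nn.Parallel(
            _branch(rng, (channels, f, 1, 1)),
            _branch(rng, (channels, f, 1, 1), (f, f, 3, 1)),
        )
        width = 2 * f
    proj = nn.Conv2d(width, channels, 1, 1, rng=rng)
    return nn.Sequential(nn.Residual(nn.Sequential(par, proj), scale=0.2), nn.ReLU())


def _reduction_a(rng, channels, f):
    return nn.Parallel(
        nn.MaxPool2x2(),
        _branch(rng, (channels, f, 3, 2)),
        _branch(rng, (channels, f, 1, 1), (f, f, 3, 1), (f, f, 3, 2)),
    )


def _reduction_b(rng, channels, f):
    return nn.Parallel(
        nn.MaxPool2x2(),
        _branch(rng, (channels, f, 1, 1), (f, f, 3, 2)),
        _branch(rng, (channels, f, 1, 1), (f, f, 3, 1), (f, f, 3, 2)),
    )


class PathologyClassifier:
    """Binary CNN with the CAM model protocol.

    The CAM target layer is the output of the last Inception-C block (the
    final convolutional stage before global pooling). Because the head is
    GAP -> dropout (identity at inference) -> linear, the gradient of a
    class logit w.r.t. those activations is exactly
    ``W[class, k] / (h * w)`` per channel, which `cam_score_and_grad`
    returns.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, pathology: str | None = None):
        self.config = config
        self.pathology = pathology
        self.training_log: list[dict] = []
        rng = np.random.default_rng(seed)
        sw, f = config.stem_width, config.branch_width

        stem = nn.Sequential(
            nn.Conv2d(3, sw, 3, 2, rng=rng), nn.ReLU(),
            nn.Conv2d(sw, sw, 3, 1, rng=rng), nn.ReLU(),
            nn.MaxPool2x2(),
        )
        ca = sw
        blocks_a = [_inception_resnet_block(rng, ca, f, 3) for _ in range(config.n_blocks_a)]
        cb = ca + 2 * f
        blocks_b = [_inception_resnet_block(rng, cb, f, 2) for _ in range(config.n_blocks_b)]
        cc = cb + 2 * f
        blocks_c = [_inception_resnet_block(rng, cc, f, 2) for _ in range(config.n_blocks_c)]

        self.features = nn.Sequential(
            stem, *blocks_a, _reduction_a(rng, ca, f),
            *blocks_b, _reduction_b(rng, cb, f), *blocks_c,
        )
        self.n_features = cc
        self.gap = nn.GlobalAvgPool()
        self.drop = nn.Dropout(config.dropout)
        self.fc = nn.Dense(cc, config.n_classes, rng=rng)

    # ------------------------------------------------------------------ core
    def params(self):
        return self.features.params() + self.fc.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def preprocess(self, image: np.ndarray) -> np.ndarray:
        """Grayscale 2-D image -> (3, S, S), bilinearly resized, per-image
        standardized (zero mean, unit variance), replicated to 3 channels."""
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 2:
            raise ShapeError("expected a 2-D grayscale image")
        s = self.config.input_size
        if img.shape != (s, s):
            img = resize(img, (s, s), order=1, preserve_range=True, anti_aliasing=False)
        img = (img - img.mean()) / (img.std() + 1e-8)
        return np.repeat(img[None], 3, axis=0)

    def forward_logits(self, x: np.ndarray, *, train=False, rng=None) -> np.ndarray:
        a = self.features.forward(x, train=train, rng=rng)
        g = self.gap.forward(a, train=train, rng=rng)
        d = self.drop.forward(g, train=train, rng=rng)
        return self.fc.forward(d, train=train, rng=rng)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.drop.backward(d)
        d = self.gap.backward(d)
        self.features.backward(d)

    def predict(self, image: np.ndarray) -> PredictionVector:
        x = self.preprocess(image)[None]
        probs = softmax(self.forward_logits(x))[0]
        return PredictionVector(y_hat=probs, positive_score=float(probs[1]))

    # ------------------------------------------------------- CAM protocol
    def cam_activations(self, image: np.ndarray) -> np.ndarray:
        x = self.preprocess(image)[None]
        return self.features.forward(x)[0]

    def cam_score_from_activations(self, activations: np.ndarray, target_class: int) -> float:
        a = np.asarray(activations, dtype=np.float64)
        g = a.mean(axis=(1, 2))
        return float(g @ self.fc.W.value[target_class] + self.fc.b.value[target_class])

    def cam_score(self, image: np.ndarray, target_class: int) -> float:
        return self.cam_score_from_activations(self.cam_activations(image), target_class)

    def cam_score_and_grad(self, image: np.ndarray, target_class: int):
        a = self.cam_activations(image)
        k, h, w = a.shape
        score = self.cam_score_from_activations(a, target_class)
        grad = np.broadcast_to(
            self.fc.W.value[target_class][:, None, None] / (h * w), a.shape
        ).copy()
        return score, a, grad

    # --------------------------------------------------------- persistence
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ConfigError("weight list does not match this architecture")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ConfigError(f"weight shape {w.shape} != expected {p.value.shape}")
            p.value[...] = w

    def save(self, path) -> None:
        meta = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez_compressed(
            path,
            preset=self.config.preset,
            pathology=self.pathology or "",
            **meta,
        )

    @classmethod
    def load(cls, path, config: ModelConfig | None = None) -> "PathologyClassifier":
        data = np.load(path, allow_pickle=False)
        preset = str(data["preset"])
        cfg = config or ModelConfig.from_preset(preset)
        model = cls(cfg, pathology=str(data["pathology"]) or None)
        n = len([k for k in data.files if k.startswith("w")])
        model.set_weights([data[f"w{i}"] for i in range(n)])
        return model


def build_classifier(
    config: ModelConfig, seed: int = 0, pathology: str | None = None
) -> PathologyClassifier:
    """Construct a randomly initialized classifier from a config."""
    if pathology is not None and pathology not in PATHOLOGIES:
        raise ConfigError(f"unknown pathology {pathology!r}")
    return PathologyClassifier(config, seed=seed, pathology=pathology)


def predict(model: PathologyClassifier, image: np.ndarray) -> PredictionVector:
    """Softmax class scores for one B-scan; ``positive_score`` is the
    pathology-present probability. Scores above 0.5 (strictly) admit the
    slice to the CAM stage downstream."""
    return model.predict(image)


def train(
    model: PathologyClassifier,
    dataset,
    epochs: int,
    seed: int,
    *,
    batch_size: int = 16,
    learning_rate: float | None = None,
    log_csv=None,
) -> PathologyClassifier:
    """Seeded Adam training minimizing categorical cross entropy.

    ``dataset`` is a sequence of TrainingExamples. The model is updated in
    place and returned; per-epoch loss and accuracy are appended to
    ``model.training_log`` (and optionally written as CSV).
    """
    dataset = list(dataset)
    if not dataset:
        raise DataError("empty training dataset")
    if epochs == 0:
        return model
    rng = np.random.default_rng(seed)
    x = np.stack([model.preprocess(ex.image) for ex in dataset])
    y = np.stack([np.asarray(ex.y, dtype=np.float64) for ex in dataset])
    opt = nn.Adam(model.params(), lr=learning_rate or model.config.learning_rate)

    for epoch in range(epochs):
        order = rng.permutation(len(dataset))
        total_loss = 0.0
        correct = 0
        for start in range(0, len(dataset), batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, train=True, rng=rng)
            probs = softmax(logits)
            total_loss += sum(cce_loss(t, p) for t, p in zip(yb, probs))
            correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            opt.zero_grad()
            model.backward_from_logits((probs - yb) / len(idx))
            opt.step()
        entry = {
            "epoch": epoch,
            "loss": total_loss / len(dataset),
            "accuracy": correct / len(dataset),
        }
        model.training_log.append(entry)
    if log_csv is not None:
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "accuracy"])
            writer.writeheader()
            writer.writerows(model.training_log)
    return model


def training_accuracy(model: PathologyClassifier, dataset) -> float:
    """Inference-mode accuracy over a TrainingExample sequence."""
    dataset = list(dataset)
    x = np.stack([model.preprocess(ex.image) for ex in dataset])
    y = np.stack([ex.y for ex in dataset])
    probs = softmax(model.forward_logits(x))
    return float((probs.argmax(1) == y.argmax(1)).mean())
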