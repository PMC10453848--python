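"""Gated convolution-deconvolution despeckler.

An encoder of ``n_encoder_layers`` convolutions is mirrored by a decoder
of the same depth. Each encoder output ``e_i`` is split by a learnable
gating scalar ``g_i`` (sigmoid-parameterized, hence always in [0, 1]):
``g_i * e_i`` is sent over the skip connection to the mirrored decoder
layer, and ``(1 - g_i) * e_i`` continues down the encoder. With all gates
at 0 the decoder therefore sees only the bottleneck path.

Training minimizes mean squared error between the decoder output and the
clean target on speckled/clean image pairs (e.g. from the phantom
generator). Kernel sizes (3x3), widths and loss are this package's
defaults; only the topology (5 conv layers, mirrored decoder, gated
skips) is prescribed.

The denoiser is an optional pre-processing stage: the volume pipeline can
run on raw images ("noisy" path) or on denoised ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigError, DataError, ShapeError


def _default_widths(n: int) -> tuple[int, ...]:
    base = (32, 64, 128, 256, 256)
    if n <= len(base):
        return base[:n]
    return base + (base[-1],) * (n - len(base))


@dataclass(frozen=True)
class DenoiserConfig:
    n_encoder_layers: int = 5
    gate_init: float = 0.5
    seed: int = 0
    widths: tuple[int, ...] | None = None
    kernel: int = 3

    def __post_init__(self):
        if self.n_encoder_layers < 1:
            raise ConfigError("n_encoder_layers must be >= 1")
        if not 0.0 <= self.gate_init <= 1.0:
            raise ConfigError("gate_init must lie in [0, 1]")
        if self.widths is not None and len(self.widths) != self.n_encoder_layers:
            raise ConfigError("widths must have one entry per encoder layer")


class Denoiser:
    """Same-resolution gated encoder-decoder over single-channel images."""

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.widths or _default_widths(config.n_encoder_layers)
        chans = (1,) + tuple(widths)
        k = config.kernel
        self.enc = [
            nn.Conv2d(chans[i], chans[i + 1], k, 1, rng=rng)
            for i in range(len(widths))
        ]
        self.dec = [
            nn.Conv2d(chans[i + 1], chans[i], k, 1, rng=rng)
            for i in range(len(widths))
        ]
        # Gate scalars, stored pre-sigmoid so g stays in (0, 1) by construction.
        g0 = float(np.clip(config.gate_init, 1e-6, 1 - 1e-6))
        logit = np.log(g0 / (1.0 - g0))
        self.gate_params = [nn.Param(np.array(logit)) for _ in widths]
        self._relu_enc = [nn.ReLU() for _ in widths]
        self._relu_dec = [nn.ReLU() for _ in widths[1:]]
        self.trained_shape: tuple[int, int] | None = None

    # ----------------------------------------------------------------- misc
    @property
    def n_skips(self) -> int:
        return len(self.enc)

    @property
    def gates(self) -> list[float]:
        return [
            float(1.0 / (1.0 + np.exp(-np.clip(p.value, -500, 500))))
            for p in self.gate_params
        ]

    def params(self):
        out = []
        for lay in self.enc + self.dec:
            out.extend(lay.params())
        out.extend(self.gate_params)
        return out

    # -------------------------------------------------------------- forward
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) float in [0, 1] -> same-shape reconstruction."""
        gates = [
            1.0 / (1.0 + np.exp(-np.clip(p.value, -500, 500)))
            for p in self.gate_params
        ]
        a = x
        skips = []
        es = []
        for conv, relu, g in zip(self.enc, self._relu_enc, gates):
            e = relu.forward(conv.forward(a))
            es.append(e)
            skips.append(g * e)
            a = (1.0 - g) * e
        d = a
        self._cache = (es, gates)
        n = len(self.enc)
        for i in range(n - 1, -1, -1):
            d = self.dec[i].forward(d + skips[i])
            if i > 0:
                d = self._relu_dec[i - 1].forward(d)
        return d

    def backward(self, dout: np.ndarray) -> None:
        es, gates = self._cache
        n = len(self.enc)
        d = dout
        dins = [None] * n  # gradient w.r.t. (d_i + skip_i), deepest last
        for i in range(n):
            if i > 0:
                d = self._relu_dec[i - 1].backward(d)
            d = self.dec[i].backward(d)
            dins[i] = d
        # ``d`` now holds the gradient w.r.t. the bottleneck path a_n.
        da = d
        for i in range(n - 1, -1, -1):
            g = gates[i]
            de = (1.0 - g) * da + g * dins[i]
            dg = float((es[i] * (dins[i] - da)).sum())
            self.gate_params[i].grad += dg * g * (1.0 - g)
            da = self.enc[i].backward(self._relu_enc[i].backward(de))

    # ---------------------------------------------------------- persistence
    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        own = self.params()
        if len(own) != len(weights):
            raise ConfigError("weight list does not match this architecture")
        for p, w in zip(own, weights):
            p.value[...] = np.asarray(w)

    def save(self, path):
        np.savez_compressed(
            path,
            n_encoder_layers=self.config.n_encoder_layers,
            widths=np.asarray(self.config.widths or _default_widths(self.config.n_encoder_layers)),
            kernel=self.config.kernel,
            **{f"w{i}": w for i, w in enumerate(self.get_weights())},
        )

    @classmethod
    def load(cls, path) -> "Denoiser":
        data = np.load(path, allow_pickle=False)
        cfg = DenoiserConfig(
            n_encoder_layers=int(data["n_encoder_layers"]),
            widths=tuple(int(w) for w in data["widths"]),
            kernel=int(data["kernel"]),
        )
        model = cls(cfg)
        n = len([k for k in data.files if k.startswith("w")])
        model.set_weights([data[f"w{i}"] for i in range(n)])
        return model


def build_denoiser(config: DenoiserConfig | None = None) -> Denoiser:
    return Denoiser(config or DenoiserConfig())


def denoise(model: Denoiser | None, image: np.ndarray) -> np.ndarray:
    """Run the despeckler on one 8-bit grayscale image.

    ``model=None`` is the bypass path: the image is returned unchanged
    (the pipeline's "noisy model" route). Output is clipped to [0, 255]
    and returned as uint8 at the input shape.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ShapeError("expected a 2-D grayscale image")
    if model is None:
        return img.astype(np.uint8)
    if model.trained_shape is not None and img.shape != model.trained_shape:
        raise ShapeError(
            f"image shape {img.shape} != training resolution {model.trained_shape}"
        )
    x = img.astype(np.float64)[None, None] / 255.0
    out = model.forward(x)[0, 0] * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def train_denoiser(
    model: Denoiser,
    noisy: np.ndarray,
    clean: np.ndarray,
    epochs: int,
    seed: int,
    *,
    batch_size: int = 8,
    learning_rate: float = 1e-3,
) -> Denoiser:
    """MSE training on (n, h, w) speckled/clean 8-bit pairs."""
    noisy = np.asarray(noisy)
    clean = np.asarray(clean)
    if noisy.shape != clean.shape or noisy.ndim != 3:
        raise DataError("noisy and clean must be matching (n, h, w) stacks")
    if noisy.shape[0] == 0:
        raise DataError("empty training set")
    rng = np.random.default_rng(seed)
    x = noisy.astype(np.float64)[:, None] / 255.0
    t = clean.astype(np.float64)[:, None] / 255.0
    opt = nn.Adam(model.params(), lr=learning_rate)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            xb, tb = x[idx], t[idx]
            out = model.forward(xb)
            opt.zero_grad()
            model.backward((out - tb) / out.size)
            opt.step()
    model.trained_shape = noisy.shape[1:]
    return model


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB between two 8-bit images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError("images must share a shape")
    mse = float(((a - b) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)
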