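"""Class-activation-map techniques, Otsu binarization, and majority fusion.

Five CAM techniques share one contract: given a model, an image and a
target class, return a HeatMap in [0, 1] at the analysis resolution (the
input image's shape by default). All techniques weight the channels of the
activations ``A^k`` of the model's final convolutional stage:

* Grad-CAM          — w_k = spatial mean of dy_c/dA^k,
* Grad-CAM++        — w_k = sum of alpha_kij * ReLU(dy_c/dA^k_ij) with
                      per-pixel alpha built from higher derivatives,
* Score-CAM         — gradient-free; w = channel softmax of the score gain
                      when the input is masked by each normalized map,
* Ablation-CAM      — w_k = (y_c - y_c^(k)) / y_c with channel k zeroed,
* Self-Matching-CAM — w_k = cosine match of each normalized upsampled map
                      against the normalized input image.

The map is ReLU(sum_k w_k A^k), bilinearly upsampled, then min-max
normalized (an all-zero map stays all-zero; a flat positive map becomes
all ones). Heat maps are binarized with Otsu's threshold over 256 uniform
bins of [0, 1], and the ensemble rule marks a pixel foreground when at
least 3 of the 5 binarized maps agree.

Models must expose the final-stage activations and class scores; see the
method list probed by ``_require``. ``PathologyClassifier`` implements it,
and so can any small test double.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import CapabilityError, InputError, ShapeError
from .types import BinaryMask, HeatMap, as_heatmap_array, as_mask_array

TECHNIQUES = ("gradcam", "gradcampp", "scorecam", "ablationcam", "selfmatching")


def _require(model, *methods):
    for name in methods:
        if not callable(getattr(model, name, None)):
            raise CapabilityError(f"model does not expose required method {name!r}")


def _upsample(m: np.ndarray, shape) -> np.ndarray:
    if m.shape == tuple(shape):
        return np.asarray(m, dtype=np.float64)
    return _sk_resize(
        np.asarray(m, dtype=np.float64), shape, order=1,
        preserve_range=True, anti_aliasing=False,
    )


def normalize_heatmap(m: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; idempotent.

    A flat map normalizes to all ones if positive, all zeros otherwise,
    so empty (all-zero) relevance stays empty.
    """
    m = np.asarray(m, dtype=np.float64)
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-300:
        return np.where(m > 0, 1.0, 0.0)
    return (m - lo) / (hi - lo)


def _finish(raw: np.ndarray, technique: str, image: np.ndarray, out_shape, **meta) -> HeatMap:
    shape = tuple(out_shape) if out_shape is not None else np.asarray(image).shape
    vals = normalize_heatmap(_upsample(np.maximum(raw, 0.0), shape))
    return HeatMap(values=vals, technique=technique, **meta)


def grad_cam(model, image, target_class, *, out_shape=None, **meta) -> HeatMap:
    """Gradient-weighted CAM: channel weights are the spatial means of the
    class-score gradient at the final convolutional stage."""
    _require(model, "cam_score_and_grad")
    _, acts, grad = model.cam_score_and_grad(image, target_class)
    weights = grad.mean(axis=(1, 2))
    raw = np.tensordot(weights, acts, axes=1)
    return _finish(raw, "gradcam", image, out_shape, **meta)


def grad_cam_pp(model, image, target_class, *, out_shape=None, **meta) -> HeatMap:
    """Grad-CAM++ with per-pixel alpha weights.

    alpha_kij = d2 / (2*d2 + sum_ab(A_ab) * d3), where d2 and d3 are the
    second and third derivatives of the class score w.r.t. A_kij. Models
    may expose ``cam_higher_grads`` returning (A, d1, d2, d3); otherwise
    the score is taken as locally linear in A (d2 = d3 = 0), for which the
    alpha -> 1/2 reduction applies wherever the first derivative is
    nonzero (and 0/0 -> 0 where everything vanishes).
    """
    if callable(getattr(model, "cam_higher_grads", None)):
        acts, d1, d2, d3 = model.cam_higher_grads(image, target_class)
    else:
        _require(model, "cam_score_and_grad")
        _, acts, d1 = model.cam_score_and_grad(image, target_class)
        d2 = np.zeros_like(d1)
        d3 = np.zeros_like(d1)
    asum = acts.sum(axis=(1, 2))[:, None, None]
    den = 2.0 * d2 + asum * d3
    alpha = np.where(
        den != 0.0, np.divide(d2, den, out=np.zeros_like(d2), where=den != 0.0),
        np.where(d1 != 0.0, 0.5, 0.0),
    )
    weights = (alpha * np.maximum(d1, 0.0)).sum(axis=(1, 2))
    raw = np.tensordot(weights, acts, axes=1)
    return _finish(raw, "gradcampp", image, out_shape, **meta)


def score_cam(model, image, target_class, *, out_shape=None, **meta) -> HeatMap:
    """Score-CAM: forward passes only. Each activation map, upsampled and
    normalized, masks the input; channel weights are the softmax over the
    masked-minus-baseline class scores (baseline: all-zero input)."""
    _require(model, "cam_activations", "cam_score")
    image = np.asarray(image, dtype=np.float64)
    acts = model.cam_activations(image)
    baseline = model.cam_score(np.zeros_like(image), target_class)
    scores = np.empty(acts.shape[0])
    for k in range(acts.shape[0]):
        saliency = normalize_heatmap(_upsample(acts[k], image.shape))
        scores[k] = model.cam_score(image * saliency, target_class)
    z = scores - baseline
    z = z - z.max()
    weights = np.exp(z)
    weights /= weights.sum()
    raw = np.tensordot(weights, acts, axes=1)
    return _finish(raw, "scorecam", image, out_shape, **meta)


def ablation_cam(model, image, target_class, *, out_shape=None, **meta) -> HeatMap:
    """Ablation-CAM: w_k is the fractional score drop when channel k is
    zeroed. Guarded to all-zero weights when |y_c| < 1e-12."""
    _require(model, "cam_activations", "cam_score_from_activations")
    acts = model.cam_activations(image)
    y = model.cam_score_from_activations(acts, target_class)
    weights = np.zeros(acts.shape[0])
    if abs(y) >= 1e-12:
        for k in range(acts.shape[0]):
            ablated = acts.copy()
            ablated[k] = 0.0
            yk = model.cam_score_from_activations(ablated, target_class)
            weights[k] = (y - yk) / y
    raw = np.tensordot(weights, acts, axes=1)
    return _finish(raw, "ablationcam", image, out_shape, **meta)


def self_matching_cam(model, image, target_class, *, out_shape=None, **meta) -> HeatMap:
    """Self-Matching-CAM: each channel's upsampled, normalized activation
    map is matched against the normalized input image; the cosine
    similarity is the channel weight."""
    _require(model, "cam_activations")
    image = np.asarray(image, dtype=np.float64)
    acts = model.cam_activations(image)
    ref = normalize_heatmap(image).ravel()
    ref_norm = np.linalg.norm(ref)
    weights = np.zeros(acts.shape[0])
    for k in range(acts.shape[0]):
        up = normalize_heatmap(_upsample(acts[k], image.shape)).ravel()
        denom = np.linalg.norm(up) * ref_norm
        if denom > 0:
            weights[k] = float(up @ ref) / denom
    raw = np.tensordot(weights, acts, axes=1)
    return _finish(raw, "selfmatching", image, out_shape, **meta)


_CAM_FUNCS = {
    "gradcam": grad_cam,
    "gradcampp": grad_cam_pp,
    "scorecam": score_cam,
    "ablationcam": ablation_cam,
    "selfmatching": self_matching_cam,
}


def otsu_binarize(heatmap, **meta) -> BinaryMask:
    """Binarize a [0, 1] heat map at Otsu's threshold.

    Values are quantized to 256 uniform bins; the threshold t* maximizes
    the between-class variance, ties broken toward the smallest t*, and
    the mask keeps strictly greater levels. A constant map yields an
    all-false mask.
    """
    values = as_heatmap_array(heatmap)
    if values.size == 0:
        raise ShapeError("empty heat map")
    levels = np.minimum((values * 256.0).astype(np.int64), 255)
    if levels.min() == levels.max():
        mask = np.zeros(values.shape, dtype=bool)
    else:
        hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
        n = hist.sum()
        w0 = np.cumsum(hist)
        mu = np.cumsum(hist * np.arange(256))
        mu_total = mu[-1]
        w1 = n - w0
        valid = (w0 > 0) & (w1 > 0)
        between = np.zeros(256)
        between[valid] = (mu_total * w0[valid] / n - mu[valid]) ** 2 / (
            w0[valid] * w1[valid] / n
        )
        t_star = int(np.argmax(between))
        mask = levels > t_star
    prov = heatmap.technique if isinstance(heatmap, HeatMap) else meta.pop("provenance", "")
    if isinstance(heatmap, HeatMap):
        meta.setdefault("slice_ref", heatmap.slice_ref)
    return BinaryMask(values=mask, provenance=prov, **meta)


def ensemble_cam(masks: Sequence, **meta) -> BinaryMask:
    """Majority fusion: a pixel is foreground when >= 3 of the 5 binarized
    CAMs agree (sum the five 0/1 maps, threshold at three)."""
    masks = [as_mask_array(m) for m in masks]
    if len(masks) != 5:
        raise InputError(f"ensemble fusion needs exactly 5 masks, got {len(masks)}")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise InputError("all masks must share a shape")
    votes = np.sum(np.stack(masks).astype(np.int8), axis=0)
    meta.setdefault("provenance", "ensemble")
    return BinaryMask(values=votes >= 3, **meta)


def cam_binary_mask(model, image, technique: str, target_class, *, out_shape=None, **meta) -> BinaryMask:
    """One technique (or the 5-way ensemble) straight to a binary mask."""
    if technique in _CAM_FUNCS:
        hm = _CAM_FUNCS[technique](model, image, target_class, out_shape=out_shape, **meta)
        return otsu_binarize(hm)
    if technique == "ensemble":
        parts = [
            otsu_binarize(fn(model, image, target_class, out_shape=out_shape, **meta))
            for fn in _CAM_FUNCS.values()
        ]
        return ensemble_cam(parts, slice_ref=meta.get("slice_ref", ("", 0)))
    raise InputError(f"unknown technique {technique!r}; choose from {TECHNIQUES + ('ensemble',)}")
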