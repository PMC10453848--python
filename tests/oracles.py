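"""Independent brute-force oracles used by the unit and acceptance suites.

Each oracle re-derives an operation's result by direct enumeration or
naive loops, sharing no code with the implementation it checks (only the
resize helper, which both sides treat as a fixed primitive).
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize


def normalize(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-300:
        return np.where(m > 0, 1.0, 0.0)
    return (m - lo) / (hi - lo)


def upsample(m, shape):
    if np.shape(m) == tuple(shape):
        return np.asarray(m, dtype=np.float64)
    return _sk_resize(np.asarray(m, dtype=np.float64), shape, order=1,
                      preserve_range=True, anti_aliasing=False)


def finish(raw, shape):
    return normalize(upsample(np.maximum(raw, 0.0), shape))


def oracle_grad_cam(acts, grad, out_shape):
    k = acts.shape[0]
    raw = np.zeros(acts.shape[1:])
    for i in range(k):
        raw += grad[i].mean() * acts[i]
    return finish(raw, out_shape)


def oracle_grad_cam_pp(acts, d1, d2, d3, out_shape):
    """Per-pixel loop over the alpha formula, with the same degenerate
    conventions: den == 0 -> alpha = 1/2 if d1 != 0 else 0."""
    kk, hh, ww = acts.shape
    raw = np.zeros((hh, ww))
    for k in range(kk):
        asum = acts[k].sum()
        w = 0.0
        for i in range(hh):
            for j in range(ww):
                den = 2.0 * d2[k, i, j] + asum * d3[k, i, j]
                if den != 0.0:
                    alpha = d2[k, i, j] / den
                elif d1[k, i, j] != 0.0:
                    alpha = 0.5
                else:
                    alpha = 0.0
                w += alpha * max(d1[k, i, j], 0.0)
        raw += w * acts[k]
    return finish(raw, out_shape)


def oracle_score_cam(model, image, target, out_shape):
    acts = model.cam_activations(image)
    base = model.cam_score(np.zeros_like(image), target)
    gains = []
    for k in range(acts.shape[0]):
        sal = normalize(upsample(acts[k], image.shape))
        gains.append(model.cam_score(image * sal, target) - base)
    gains = np.asarray(gains)
    e = np.exp(gains - gains.max())
    w = e / e.sum()
    raw = sum(w[k] * acts[k] for k in range(acts.shape[0]))
    return finish(raw, out_shape)


def oracle_ablation_cam(model, image, target, out_shape):
    acts = model.cam_activations(image)
    y = model.cam_score_from_activations(acts, target)
    weights = np.zeros(acts.shape[0])
    if abs(y) >= 1e-12:
        for k in range(acts.shape[0]):
            a2 = acts.copy()
            a2[k] = 0.0
            weights[k] = (y - model.cam_score_from_activations(a2, target)) / y
    raw = sum(weights[k] * acts[k] for k in range(acts.shape[0]))
    return finish(raw, out_shape), weights


def oracle_otsu_threshold(levels: np.ndarray) -> int:
    """Exhaustive search minimizing within-class variance over all 256
    thresholds; smallest threshold on ties."""
    best_t, best_v = 0, np.inf
    flat = levels.ravel()
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        v = 0.0
        if lo.size:
            v += lo.size * lo.astype(np.float64).var()
        if hi.size:
            v += hi.size * hi.astype(np.float64).var()
        if v < best_v - 1e-9:
            best_v, best_t = v, t
    return best_t


def oracle_majority(masks) -> np.ndarray:
    votes = np.zeros(masks[0].shape, dtype=int)
    for m in masks:
        votes += m.astype(int)
    return votes >= 3


def oracle_region_grow(image, seeds, threshold, connectivity=8, reference="seed"):
    """Independent re-derivation of seeded growing.

    reference='seed': the grown region is the connected component (within
    the predicate mask |I - I(seed)| < tau, plus the seed itself) that
    contains the seed — computed via connected-component labeling, not a
    search. reference='neighbor': fixed-point iteration admitting any
    pixel adjacent to the region whose intensity is within tau of that
    adjoining region pixel.
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if connectivity == 4
        else np.ones((3, 3), dtype=int)
    )
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    out = np.zeros((h, w), dtype=bool)
    for r0, c0 in seeds:
        if reference == "seed":
            pred = np.abs(img - img[r0, c0]) < threshold
            pred[r0, c0] = True
            labeled, _ = ndimage.label(pred, structure=structure)
            out |= labeled == labeled[r0, c0]
        else:
            region = np.zeros((h, w), dtype=bool)
            region[r0, c0] = True
            changed = True
            while changed:
                changed = False
                rows, cols = np.nonzero(region)
                for r, c in zip(rows, cols):
                    for dr, dc in offs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and not region[rr, cc]
                                and abs(img[rr, cc] - img[r, c]) < threshold):
                            region[rr, cc] = True
                            changed = True
            out |= region
    return out
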