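"""Refinement of binarized CAM output into fluid-region masks.

Two refiners are offered, both exploiting that fluid pockets are dark:

* seeded region growing — contours of the CAM mask yield seed points
  (component centroids); regions grow breadth-first, admitting a
  neighboring pixel when its intensity differs from the reference by
  strictly less than a threshold (default 15 gray levels),
* selective thresholding — the image is masked by the CAM mask and only
  pixels inside a low-intensity band (default [20, 50], inclusive) are
  kept.

Both are suited to IRF and SRF; for PED (a layer detachment, not a dark
pocket) the raw CAM mask is used unrefined — the ``"none"`` method.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError
from .types import BinaryMask, as_mask_array


@dataclass(frozen=True)
class SeedPoint:
    row: int
    col: int
    source_contour_id: int


@dataclass(frozen=True)
class RegionGrowConfig:
    """``reference="seed"`` compares each candidate against the intensity
    of its originating seed; ``"neighbor"`` against the adjoining region
    pixel. Inclusion is strict: |difference| < threshold."""

    intensity_threshold: float = 15.0
    connectivity: int = 8
    reference: str = "seed"

    def __post_init__(self):
        if self.intensity_threshold < 0:
            raise InputError("intensity_threshold must be >= 0")
        if self.connectivity not in (4, 8):
            raise InputError("connectivity must be 4 or 8")
        if self.reference not in ("seed", "neighbor"):
            raise InputError("reference must be 'seed' or 'neighbor'")


@dataclass(frozen=True)
class SelectiveThresholdConfig:
    band_low: float = 20.0
    band_high: float = 50.0
    inclusive: bool = True

    def __post_init__(self):
        if not 0 <= self.band_low <= self.band_high <= 255:
            raise InputError("band must satisfy 0 <= low <= high <= 255")


def extract_seeds(mask) -> list[SeedPoint]:
    """One seed per connected component: the rounded centroid, snapped to
    the nearest component pixel when it falls outside (non-convex blobs).
    An empty mask yields an empty list."""
    m = as_mask_array(mask)
    labeled, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    seeds = []
    for comp_id in range(1, n + 1):
        comp = labeled == comp_id
        cy, cx = ndimage.center_of_mass(comp)
        r, c = int(round(cy)), int(round(cx))
        if not comp[r, c]:
            rows, cols = np.nonzero(comp)
            j = np.argmin((rows - cy) ** 2 + (cols - cx) ** 2)
            r, c = int(rows[j]), int(cols[j])
        seeds.append(SeedPoint(row=r, col=c, source_contour_id=comp_id - 1))
    return seeds


_NEIGHBORS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGHBORS_8 = _NEIGHBORS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def region_grow(image: np.ndarray, seeds, config: RegionGrowConfig | None = None) -> BinaryMask:
    """Breadth-first region growing from seed points; the union over all
    seeds is returned. Deterministic for a fixed configuration."""
    config = config or RegionGrowConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InputError("image must be 2-D")
    h, w = img.shape
    offsets = _NEIGHBORS_4 if config.connectivity == 4 else _NEIGHBORS_8
    tau = config.intensity_threshold
    out = np.zeros((h, w), dtype=bool)
    for seed in seeds:
        r0, c0 = int(seed.row), int(seed.col)
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise InputError(f"seed ({r0}, {c0}) outside {h}x{w} image")
        region = np.zeros((h, w), dtype=bool)
        region[r0, c0] = True
        seed_val = img[r0, c0]
        frontier = deque([(r0, c0)])
        while frontier:
            r, c = frontier.popleft()
            ref = seed_val if config.reference == "seed" else img[r, c]
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not region[rr, cc]:
                    if abs(img[rr, cc] - ref) < tau:
                        region[rr, cc] = True
                        frontier.append((rr, cc))
        out |= region
    return BinaryMask(values=out, provenance="region_grow")


def selective_threshold(
    image: np.ndarray, cam_mask, config: SelectiveThresholdConfig | None = None
) -> BinaryMask:
    """Keep CAM-mask pixels whose intensity falls in the fluid band.

    The region of interest is the pixel-wise product image * mask; a pixel
    is retained iff it is inside the mask and its value lies within
    [band_low, band_high] (strict inequalities when inclusive=False).
    """
    config = config or SelectiveThresholdConfig()
    img = np.asarray(image, dtype=np.float64)
    m = as_mask_array(cam_mask)
    if img.shape != m.shape:
        raise InputError(f"image shape {img.shape} != mask shape {m.shape}")
    roi = img * m
    if config.inclusive:
        band = (roi >= config.band_low) & (roi <= config.band_high)
    else:
        band = (roi > config.band_low) & (roi < config.band_high)
    return BinaryMask(values=m & band, provenance="selective")


def roi_histogram(image: np.ndarray, cam_mask) -> np.ndarray:
    """256-bin intensity histogram over mask-true pixels (zero-count bins
    included); the counts sum to the mask's pixel count."""
    img = np.asarray(image)
    m = as_mask_array(cam_mask)
    if img.shape != m.shape:
        raise InputError(f"image shape {img.shape} != mask shape {m.shape}")
    vals = np.clip(img[m].astype(np.int64), 0, 255)
    return np.bincount(vals, minlength=256)


def refine_mask(
    image: np.ndarray,
    cam_mask,
    method: str = "selective",
    *,
    region_config: RegionGrowConfig | None = None,
    selective_config: SelectiveThresholdConfig | None = None,
) -> BinaryMask:
    """Dispatch: 'region_grow', 'selective', or 'none' (raw CAM mask,
    the documented choice for PED)."""
    if method == "none":
        return BinaryMask(values=as_mask_array(cam_mask), provenance="cam")
    if method == "selective":
        return selective_threshold(image, cam_mask, selective_config)
    if method == "region_grow":
        seeds = extract_seeds(cam_mask)
        return region_grow(image, seeds, region_config)
    raise InputError(f"unknown post-processing method {method!r}")
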