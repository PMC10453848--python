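"""Synthetic OCT C-scan phantoms with exact lesion ground truth.

Each B-scan phantom emulates the gross appearance of a retinal cross
section: a dark vitreous above, a bright inner limiting membrane (ILM)
band, a mid-gray retinal slab, a very bright retinal pigment epithelium
(RPE) band, and a moderately bright choroid below. Fluid lesions are
rendered as dark ellipses whose interior intensities fall in a low
grayscale band (default 25-50), the contrast cue the downstream selective
thresholding stage exploits:

* ``IRF`` — ellipse fully inside the retinal slab,
* ``SRF`` — ellipse resting on top of the RPE band,
* ``PED`` — ellipse straddling the RPE, which is redrawn as a detachment
  bump over the lesion.

Speckle is modeled as i.i.d. multiplicative gamma noise (brightness
preserving by default, ``scale = 1/shape``), applied after the noise-free
render. The generator is fully determined by ``PhantomSpec.seed``.

The phantom makes no claim of anatomical realism (layer counts, curvature
and lesion shapes are placeholders); it exists so that every stage of the
pipeline is testable with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .types import PATHOLOGIES, CScan, VoxelGeometry


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic C-scan generator.

    ``lesion_counts`` maps a pathology to the number of lesions drawn on
    each slice that carries that pathology; ``lesion_slice_fraction`` is
    the fraction of slices (per pathology, independently) that do.
    """

    height: int = 128
    width: int = 256
    n_slices: int = 32
    lesion_counts: Mapping[str, int] = field(
        default_factory=lambda: {"IRF": 1, "SRF": 1, "PED": 1}
    )
    lesion_intensity_range: tuple[int, int] = (25, 50)
    background_band_intensities: tuple[float, ...] = (190.0, 220.0)
    slab_intensity: float = 120.0
    choroid_intensity: float = 90.0
    floor_intensity: float = 5.0
    speckle_shape: float = 4.0
    speckle_scale: float = 0.25
    lesion_slice_fraction: float = 0.6
    seed: int = 0
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self):
        if min(self.height, self.width, self.n_slices) < 1:
            raise ParameterError("height, width and n_slices must be >= 1")
        lo, hi = self.lesion_intensity_range
        if not (0 <= lo <= hi <= 255):
            raise ParameterError("lesion_intensity_range must satisfy 0 <= lo <= hi <= 255")
        if self.speckle_shape <= 0 or self.speckle_scale <= 0:
            raise ParameterError("speckle shape and scale must be positive")
        for p in self.lesion_counts:
            if p not in PATHOLOGIES:
                raise ParameterError(f"unknown pathology {p!r}")
        if not 0.0 <= self.lesion_slice_fraction <= 1.0:
            raise ParameterError("lesion_slice_fraction must lie in [0, 1]")


@dataclass
class PhantomOutput:
    """Generator output: speckled C-scan, noise-free render, masks, labels.

    ``masks[p]`` is an (n_slices, h, w) boolean stack marking lesion
    interiors exactly; ``labels[p][i]`` is True iff ``masks[p][i]`` is
    nonempty.
    """

    cscan: CScan
    clean: np.ndarray  # (n, h, w) uint8 noise-free render
    masks: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    def labels_frame(self) -> pd.DataFrame:
        """Per-slice labels in the canonical CSV layout."""
        n = self.cscan.n_slices
        return pd.DataFrame(
            {
                "scan_id": [self.cscan.scan_id] * n,
                "slice_index": np.arange(n),
                **{p: self.labels[p].astype(int) for p in PATHOLOGIES},
            }
        )


def apply_speckle(
    image: np.ndarray,
    shape: float,
    scale: float,
    seed: int,
    *,
    clip: bool = True,
    quantize: bool = True,
) -> np.ndarray:
    """Multiply ``image`` by i.i.d. gamma(shape, scale) noise per pixel.

    With ``scale = 1/shape`` the noise has unit mean and is brightness
    preserving in expectation. By default the result is clipped to
    [0, 255] and rounded to integers, matching the 8-bit image contract;
    pass ``clip=False, quantize=False`` to study the raw noise model.
    """
    if shape <= 0 or scale <= 0:
        raise ParameterError("gamma shape and scale must be positive")
    img = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    out = img * rng.gamma(shape, scale, size=img.shape)
    if clip:
        out = np.clip(out, 0.0, 255.0)
    if quantize:
        out = np.rint(out)
    return out


def _band_profile(rows: np.ndarray, center: np.ndarray, peak: float, sigma: float = 1.6):
    return peak * np.exp(-((rows - center[None, :]) ** 2) / (2.0 * sigma**2))


def _ellipse_mask(h, w, cy, cx, a, b):
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return ((rows - cy) / a) ** 2 + ((cols - cx) / b) ** 2 <= 1.0


def _render_slice(spec: PhantomSpec, rng: np.random.Generator, lesions: dict[str, int]):
    """Noise-free render of one B-scan plus exact per-pathology masks."""
    h, w = spec.height, spec.width
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)

    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    r_top = 0.26 * h + 0.04 * h * np.sin(2.0 * np.pi * cols / w + phase1)
    r_bot = 0.68 * h + 0.03 * h * np.sin(2.0 * np.pi * cols / w + phase2)

    img = np.full((h, w), spec.floor_intensity)
    in_slab = (rows >= r_top[None, :]) & (rows < r_bot[None, :])
    img[in_slab] = spec.slab_intensity
    below = rows >= r_bot[None, :]
    img[below] = spec.choroid_intensity

    peaks = spec.background_band_intensities
    ilm_peak = peaks[0] if len(peaks) > 0 else 190.0
    rpe_peak = peaks[-1] if len(peaks) > 1 else 220.0
    img += _band_profile(rows, r_top, ilm_peak)

    masks = {p: np.zeros((h, w), dtype=bool) for p in PATHOLOGIES}
    lo, hi = spec.lesion_intensity_range
    rpe_center = r_bot.copy()

    for pathology, count in lesions.items():
        for _ in range(count):
            cx = int(rng.integers(w // 6, w - w // 6))
            a = float(rng.uniform(max(2.0, h / 18), h / 10))
            b = float(rng.uniform(max(3.0, w / 18), w / 8))
            top_c, bot_c = r_top[cx], r_bot[cx]
            slab_thickness = bot_c - top_c
            if 2 * a + 6 >= slab_thickness or 2 * b + 6 >= w:
                raise GenerationError(
                    f"{pathology} lesion (2a={2 * a:.1f}, 2b={2 * b:.1f}) does not fit "
                    f"the slab (thickness {slab_thickness:.1f}) of a {h}x{w} slice"
                )
            if pathology == "IRF":
                cy = float(rng.uniform(top_c + a + 3, bot_c - a - 3))
            elif pathology == "SRF":
                cy = bot_c - a - 2.0
            else:  # PED: straddle the RPE line
                cy = bot_c
            ell = _ellipse_mask(h, w, cy, cx, a, b)
            img[ell] = 0.0
            img[ell] += rng.integers(lo, hi + 1, size=int(ell.sum()))
            masks[pathology] |= ell
            if pathology == "PED":
                # Detach the RPE band: lift it over the lesion's upper arc.
                span = np.abs(cols - cx) <= b
                lift = np.zeros(w)
                lift[span] = a * np.sqrt(1.0 - ((cols[span] - cx) / b) ** 2)
                rpe_center = np.minimum(rpe_center, r_bot - lift)

    img += _band_profile(rows, rpe_center, rpe_peak)
    # Bands may bleed into lesion interiors at the boundary; restore the
    # lesion pixels so masks mark interiors exactly at the drawn intensity.
    for p in PATHOLOGIES:
        m = masks[p]
        img[m] = np.clip(img[m], lo, hi)
    return np.clip(img, 0.0, 255.0), masks


def generate_cscan(spec: PhantomSpec, scan_id: str = "phantom") -> PhantomOutput:
    """Generate one C-scan (clean + speckled) with masks and labels."""
    rng = np.random.default_rng(spec.seed)
    n, h, w = spec.n_slices, spec.height, spec.width

    carries = {
        p: rng.random(n) < spec.lesion_slice_fraction for p in spec.lesion_counts
    }
    clean = np.empty((n, h, w), dtype=np.uint8)
    masks = {p: np.zeros((n, h, w), dtype=bool) for p in PATHOLOGIES}
    for i in range(n):
        lesions = {
            p: c for p, c in spec.lesion_counts.items() if c > 0 and carries[p][i]
        }
        img, slice_masks = _render_slice(spec, rng, lesions)
        clean[i] = np.rint(img).astype(np.uint8)
        for p in PATHOLOGIES:
            masks[p][i] = slice_masks[p]

    noise_seed = int(rng.integers(0, 2**31 - 1))
    noisy = apply_speckle(
        clean.astype(np.float64), spec.speckle_shape, spec.speckle_scale, noise_seed
    ).astype(np.uint8)

    labels = {p: masks[p].any(axis=(1, 2)) for p in PATHOLOGIES}
    cscan = CScan(scan_id=scan_id, slices=noisy, geometry=spec.geometry)
    return PhantomOutput(cscan=cscan, clean=clean, masks=masks, labels=labels)


def make_classification_slices(
    n_positive: int,
    n_negative: int,
    pathology: str = "IRF",
    *,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    noisy: bool = True,
):
    """Balanced slice set for training a binary pathology classifier.

    Returns ``(images, labels)`` where ``images`` is (n, h, w) uint8 and
    ``labels`` is (n,) int with 1 = pathology present. Slices are shuffled
    deterministically.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for present, count in ((1, n_positive), (0, n_negative)):
        for _ in range(count):
            lesions = {pathology: spec.lesion_counts.get(pathology, 1)} if present else {}
            img, _ = _render_slice(spec, rng, lesions)
            if noisy:
                img = apply_speckle(
                    img, spec.speckle_shape, spec.speckle_scale,
                    int(rng.integers(0, 2**31 - 1)),
                )
            images.append(img.astype(np.uint8))
            labels.append(present)
    order = rng.permutation(len(images))
    return np.stack(images)[order], np.asarray(labels)[order]
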