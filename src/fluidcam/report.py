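"""Rendered slice panels: the functional replacement for a viewer GUI.

For each selected slice a panel PNG is written showing, left to right:
the input B-scan, the CAM heat map overlaid on it, the binary map, and
(when available) the ground-truth mask. The computed volume is carried in
the file name. Panels are composed with plain array operations so the
output bytes are deterministic for fixed inputs.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .types import as_heatmap_array, as_mask_array

_SEP_WIDTH = 4


def _to_rgb(gray: np.ndarray) -> np.ndarray:
    g = np.asarray(gray, dtype=np.uint8)
    return np.repeat(g[:, :, None], 3, axis=2)


def _overlay(image: np.ndarray, heat: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    cmap = colormaps["viridis"]
    colored = (cmap(np.clip(heat, 0.0, 1.0))[:, :, :3] * 255).astype(np.float64)
    base = _to_rgb(image).astype(np.float64)
    return np.clip((1 - alpha) * base + alpha * colored, 0, 255).astype(np.uint8)


def _mask_panel(mask: np.ndarray) -> np.ndarray:
    return _to_rgb(mask.astype(np.uint8) * 255)


def render_report(
    image: np.ndarray,
    heatmap,
    binary_mask,
    gt_mask=None,
    *,
    volume_mm3: float | None = None,
    out_dir,
    slice_index: int = 0,
    scan_id: str = "scan",
) -> Path:
    """Write one slice panel; returns the written path.

    Four panels with ground truth, three without. The predicted volume,
    when given, is encoded in the file name (micro-mm^3 precision).
    """
    image = np.asarray(image, dtype=np.uint8)
    heat = as_heatmap_array(heatmap)
    mask = as_mask_array(binary_mask)
    panels = [_to_rgb(image), _overlay(image, heat), _mask_panel(mask)]
    if gt_mask is not None:
        panels.append(_mask_panel(as_mask_array(gt_mask)))
    sep = np.full((image.shape[0], _SEP_WIDTH, 3), 255, dtype=np.uint8)
    strip = panels[0]
    for p in panels[1:]:
        strip = np.concatenate([strip, sep, p], axis=1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol = "" if volume_mm3 is None else f"_vol{volume_mm3:.6f}mm3"
    path = out_dir / f"{scan_id}_slice{slice_index:03d}{vol}.png"
    iio.imwrite(path, strip)
    return path
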