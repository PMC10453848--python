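"""Reading and writing image stacks, masks, labels and configs.

Canonical on-disk formats: multipage TIFF (8-bit grayscale) or a directory
of zero-padded PNG slices for C-scans and mask stacks (masks as 0/255),
CSV for per-slice labels (columns scan_id, slice_index, IRF, SRF, PED with
0/1 values), YAML for run configuration. Round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, InputError
from .types import PATHOLOGIES, CScan, VoxelGeometry

_LABEL_COLUMNS = ["scan_id", "slice_index", "IRF", "SRF", "PED"]


def _check_uint8(arr: np.ndarray, what: str) -> np.ndarray:
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{what} must be 8-bit grayscale, got dtype {arr.dtype}; "
            "convert to uint8 before loading"
        )
    return arr


def read_cscan(path, *, geometry: VoxelGeometry | None = None, scan_id: str | None = None) -> CScan:
    """Load a C-scan from a multipage TIFF or a directory of PNG slices.

    Slice order follows TIFF page order, or lexicographic filename order
    for a directory. Mixed slice shapes or non-8-bit data are rejected.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FormatError(f"no PNG slices found in {path}")
        slices = [_check_uint8(np.asarray(iio.imread(f)), str(f)) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise FormatError(f"mixed or non-grayscale slice shapes in {path}: {shapes}")
        stack = np.stack(slices)
    else:
        stack = np.asarray(tifffile.imread(path))
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise FormatError(f"{path} is not a grayscale stack (shape {stack.shape})")
        _check_uint8(stack, str(path))
    return CScan(
        scan_id=scan_id or path.stem,
        slices=stack,
        geometry=geometry or VoxelGeometry(),
    )


def write_cscan(cscan: CScan, path) -> None:
    """Write a C-scan as multipage TIFF (*.tif/*.tiff) or a PNG directory."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, cscan.slices, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(cscan.n_slices - 1)))
        for i, sl in enumerate(cscan.slices):
            iio.imwrite(path / f"{i:0{width}d}.png", sl)


def read_mask_stack(path) -> np.ndarray:
    """Load a 0/255 mask stack; returns (n, h, w) bool."""
    stack = read_cscan(path).slices
    return stack > 127


def write_mask_stack(masks: np.ndarray, path) -> None:
    masks = np.asarray(masks).astype(bool)
    write_cscan(
        CScan(scan_id=Path(str(path)).stem, slices=(masks * np.uint8(255))),
        path,
    )


def read_labels(path) -> pd.DataFrame:
    """Load per-slice pathology labels from CSV.

    Validates the header, 0/1 values, and uniqueness of
    (scan_id, slice_index); errors carry the offending line numbers
    (1-based, header = line 1).
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse labels file {path}: {exc}") from exc
    missing = [c for c in _LABEL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"labels file {path} lacks columns {missing}")
    frame = frame[_LABEL_COLUMNS]
    for col in PATHOLOGIES:
        bad = ~frame[col].isin([0, 1])
        if bad.any():
            lines = (frame.index[bad] + 2).tolist()
            raise FormatError(
                f"labels file {path}: column {col} has values outside {{0,1}} "
                f"at line(s) {lines}"
            )
    dup = frame.duplicated(subset=["scan_id", "slice_index"])
    if dup.any():
        lines = (frame.index[dup] + 2).tolist()
        raise FormatError(f"labels file {path}: duplicate (scan_id, slice_index) at line(s) {lines}")
    frame[list(PATHOLOGIES)] = frame[list(PATHOLOGIES)].astype(bool)
    return frame


def write_labels(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out[list(PATHOLOGIES)] = out[list(PATHOLOGIES)].astype(int)
    out[_LABEL_COLUMNS].to_csv(path, index=False)


def labels_for_scan(frame: pd.DataFrame, scan_id: str, pathology: str, n_slices: int) -> np.ndarray:
    """Per-slice boolean labels for one scan; missing slices are an error."""
    sub = frame[frame["scan_id"] == scan_id].set_index("slice_index")
    missing = sorted(set(range(n_slices)) - set(sub.index))
    if missing:
        raise InputError(f"labels for scan {scan_id!r} missing slices {missing}")
    return sub.loc[np.arange(n_slices), pathology].to_numpy(dtype=bool)


def load_geometry(path) -> VoxelGeometry:
    """Read voxel geometry from YAML: keys dx, dy, dz in micrometres."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return VoxelGeometry(
        dx=float(data.get("dx", 11.7)),
        dy=float(data.get("dy", 47.2)),
        dz=float(data.get("dz", 2.0)),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
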