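"""Core in-memory containers.

Conventions used package-wide: slice index is 0-based; pixel coordinates are
(row, col), 0-based; the canonical pixel type is 8-bit grayscale (0-255).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ShapeError

#: The three fluid-related pathologies quantified by the pipeline.
PATHOLOGIES = ("IRF", "SRF", "PED")


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one image pixel, in micrometres.

    ``dx`` is the lateral (within B-scan column) spacing, ``dy`` the slice
    spacing between consecutive B-scans, and ``dz`` the axial spacing. The
    defaults are the spectral-domain scanner geometry used throughout:
    11.7 x 47.2 x 2.0 um^3 per pixel.
    """

    dx: float = 11.7
    dy: float = 47.2
    dz: float = 2.0

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise InputError("voxel dimensions must be positive")

    @property
    def pixel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz


@dataclass
class CScan:
    """An ordered stack of equally-shaped 8-bit grayscale B-scans."""

    scan_id: str
    slices: np.ndarray  # (n_slices, height, width), uint8
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ShapeError("slices must be a non-empty (n, h, w) stack")
        if self.slices.dtype != np.uint8:
            raise ShapeError(f"slices must be uint8, got {self.slices.dtype}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]


@dataclass
class HeatMap:
    """Per-pixel relevance in [0, 1] for one B-scan and one pathology."""

    values: np.ndarray
    technique: str
    slice_ref: tuple[str, int] = ("", 0)
    target_class: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("heat map must be 2-D")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise InputError("heat map values must lie in [0, 1]")


@dataclass
class BinaryMask:
    """A boolean pixel set, with the technique (or 'ground_truth') it came from."""

    values: np.ndarray
    slice_ref: tuple[str, int] = ("", 0)
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ShapeError("mask must be 2-D")


def as_mask_array(mask) -> np.ndarray:
    """Accept a BinaryMask or a raw boolean array; return the bool array."""
    if isinstance(mask, BinaryMask):
        return mask.values
    return np.asarray(mask).astype(bool)


def as_heatmap_array(hm) -> np.ndarray:
    if isinstance(hm, HeatMap):
        return hm.values
    return np.asarray(hm, dtype=np.float64)
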