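"""Overlap metrics, classification metrics, and fluid-volume computation.

Volumes treat every mask pixel as a cuboid of scanner-specific size
(default 11.7 x 47.2 x 2.0 um^3) and sum pixel volumes over all slices of
a C-scan; results are reported in mm^3 (1 mm^3 = 1e9 um^3). Volumetric
IoU/Dice are computed on the stacked 3-D masks of a scan, and cohort
summaries aggregate per (pathology, technique, post-processing method)
with population standard deviations.

A treated eye is categorized a Responder when the post-treatment fluid
volume drops by strictly more than 10% of the pre-treatment volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .cam import cam_binary_mask
from .denoiser import denoise
from .errors import ConfigError, InputError, ShapeError, UndefinedMetricError
from .postproc import RegionGrowConfig, SelectiveThresholdConfig, refine_mask
from .types import CScan, VoxelGeometry, as_mask_array

UM3_PER_MM3 = 1e9


# --------------------------------------------------------------- overlap
def _overlap_counts(a, b):
    a = as_mask_array(a)
    b = as_mask_array(b)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.logical_and(a, b).sum())
    return inter, int(a.sum()), int(b.sum())


def jaccard(a, b, *, empty_value: float = 1.0) -> float:
    """|A n B| / |A u B|; two empty masks score ``empty_value`` (1 by
    convention, configurable)."""
    inter, na, nb = _overlap_counts(a, b)
    union = na + nb - inter
    return empty_value if union == 0 else inter / union


def dice(a, b, *, empty_value: float = 1.0) -> float:
    """2 |A n B| / (|A| + |B|); two empty masks score ``empty_value``."""
    inter, na, nb = _overlap_counts(a, b)
    total = na + nb
    return empty_value if total == 0 else 2.0 * inter / total


# -------------------------------------------------------- classification
@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision, sensitivity (recall), specificity and F1.

    Metrics with a zero denominator are ``None`` (undefined). Values are
    kept at full precision; use ``rounded`` for table-style reporting.
    """

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None

    def rounded(self, decimals: int = 4) -> "ClassificationMetrics":
        rnd = lambda v: None if v is None else round(v, decimals)
        return ClassificationMetrics(*(rnd(getattr(self, f)) for f in (
            "accuracy", "precision", "sensitivity", "specificity", "f1")))


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Standard confusion-matrix metrics; F1 = 2TP / (2TP + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("all confusion counts are zero")
    div = lambda num, den: None if den == 0 else num / den
    return ClassificationMetrics(
        accuracy=div(c.tp + c.tn, c.total),
        precision=div(c.tp, c.tp + c.fp),
        sensitivity=div(c.tp, c.tp + c.fn),
        specificity=div(c.tn, c.tn + c.fp),
        f1=div(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape:
        raise InputError("label arrays must share a shape")
    return ConfusionCounts(
        tp=int((t & p).sum()), fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()),
    )


# ----------------------------------------------------------------- volume
def pixel_volume(g: VoxelGeometry) -> float:
    """Cuboid volume of one pixel, in um^3 (default 11.7*47.2*2.0 = 1104.48)."""
    return g.pixel_volume_um3


def mask_volume_mm3(masks, g: VoxelGeometry) -> float:
    """Volume of a boolean mask (any shape) in mm^3: pixel count times
    pixel volume."""
    count = int(np.asarray(masks).astype(bool).sum())
    return count * pixel_volume(g) / UM3_PER_MM3


def responder_status(pre_volume: float, post_volume: float) -> str:
    """'Responder' iff the fluid volume dropped by strictly more than 10%."""
    if pre_volume <= 0:
        raise UndefinedMetricError("pre-treatment volume must be positive")
    reduction = (pre_volume - post_volume) / pre_volume
    return "Responder" if reduction > 0.10 else "Nonresponder"


@dataclass
class VolumeReport:
    scan_id: str
    pathology: str
    technique: str
    postproc_method: str
    predicted_volume_mm3: float
    ground_truth_volume_mm3: float | None
    volumetric_iou: float | None
    volumetric_dice: float | None
    n_positive_slices: int
    predicted_masks: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_row(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "pathology": self.pathology,
            "technique": self.technique,
            "postproc_method": self.postproc_method,
            "predicted_volume_mm3": self.predicted_volume_mm3,
            "ground_truth_volume_mm3": self.ground_truth_volume_mm3,
            "volumetric_iou": self.volumetric_iou,
            "volumetric_dice": self.volumetric_dice,
            "n_positive_slices": self.n_positive_slices,
        }


def _nearest_mask_resize(mask: np.ndarray, shape) -> np.ndarray:
    if mask.shape == tuple(shape):
        return mask
    return _sk_resize(
        mask.astype(np.float64), shape, order=0, preserve_range=True,
        anti_aliasing=False,
    ) > 0.5


def cscan_volume(
    cscan: CScan,
    model=None,
    technique: str = "ensemble",
    postproc_method: str = "selective",
    *,
    pathology: str = "IRF",
    gate: float = 0.5,
    geometry: VoxelGeometry | None = None,
    gt_masks: np.ndarray | None = None,
    gt_labels=None,
    restrict_to_true_positives: bool = False,
    denoiser_model=None,
    intensity_slices: np.ndarray | None = None,
    gate_labels=None,
    cam_masks=None,
    region_config: RegionGrowConfig | None = None,
    selective_config: SelectiveThresholdConfig | None = None,
) -> VolumeReport:
    """Per-C-scan fluid volume from the CAM pipeline.

    For every slice whose pathology-present score exceeds ``gate``
    (strictly), a CAM heat map is produced at the model's input
    resolution, Otsu-binarized, nearest-neighbor resized back to the
    B-scan resolution, refined by the chosen post-processing method on the
    slice intensities, and counted into the volume.

    Evaluation hooks: ``gate_labels`` replaces the classifier gate with
    known per-slice labels (oracle gating); ``cam_masks`` replaces the CAM
    stage with precomputed per-slice masks; ``restrict_to_true_positives``
    additionally requires ``gt_labels[i]`` to be true (the
    ground-truth-dependent evaluation mode); ``intensity_slices``
    substitutes the stack the refiners read intensities from (e.g. a
    denoised stack), defaulting to denoised slices when
    ``denoiser_model`` is given and the raw slices otherwise.
    """
    if model is not None and getattr(model, "pathology", None) not in (None, pathology):
        raise ConfigError(
            f"model was trained for {model.pathology!r}, requested {pathology!r}"
        )
    if model is None and cam_masks is None:
        raise ConfigError("either a model or precomputed cam_masks is required")
    if gate_labels is None and model is None:
        raise ConfigError("gating requires a model or gate_labels")
    geometry = geometry or cscan.geometry
    n = cscan.n_slices
    h, w = cscan.slice_shape

    if intensity_slices is None:
        if denoiser_model is not None:
            intensity_slices = np.stack(
                [denoise(denoiser_model, s) for s in cscan.slices]
            )
        else:
            intensity_slices = cscan.slices
    intensity_slices = np.asarray(intensity_slices)
    if intensity_slices.shape != cscan.slices.shape:
        raise ShapeError("intensity_slices must match the C-scan shape")

    pred = np.zeros((n, h, w), dtype=bool)
    n_positive = 0
    for i in range(n):
        if gate_labels is not None:
            gated = bool(gate_labels[i])
        else:
            gated = model.predict(intensity_slices[i]).positive_score > gate
        if restrict_to_true_positives:
            if gt_labels is None:
                raise ConfigError("restrict_to_true_positives needs gt_labels")
            gated = gated and bool(gt_labels[i])
        if not gated:
            continue
        n_positive += 1
        if cam_masks is not None:
            raw_mask = as_mask_array(cam_masks[i])
        else:
            raw_mask = cam_binary_mask(
                model, intensity_slices[i], technique, 1,
                out_shape=(model.config.input_size,) * 2,
            ).values
        raw_mask = _nearest_mask_resize(raw_mask, (h, w))
        pred[i] = refine_mask(
            intensity_slices[i], raw_mask, postproc_method,
            region_config=region_config, selective_config=selective_config,
        ).values

    predicted_volume = mask_volume_mm3(pred, geometry)
    gt_volume = iou = dsc = None
    if gt_masks is not None:
        gt = np.asarray(gt_masks).astype(bool)
        if gt.shape != pred.shape:
            raise ShapeError("gt_masks must match the C-scan shape")
        gt_volume = mask_volume_mm3(gt, geometry)
        iou = jaccard(pred, gt)
        dsc = dice(pred, gt)
    return VolumeReport(
        scan_id=cscan.scan_id,
        pathology=pathology,
        technique=technique if cam_masks is None else "oracle",
        postproc_method=postproc_method,
        predicted_volume_mm3=predicted_volume,
        ground_truth_volume_mm3=gt_volume,
        volumetric_iou=iou,
        volumetric_dice=dsc,
        n_positive_slices=n_positive,
        predicted_masks=pred,
    )


def cohort_summary(reports: Sequence[VolumeReport]) -> pd.DataFrame:
    """Mean and population standard deviation of IoU, Dice and volumes per
    (pathology, technique, post-processing method)."""
    if not reports:
        raise InputError("no reports to summarize")
    frame = pd.DataFrame([r.to_row() for r in reports])
    grouped = frame.groupby(["pathology", "technique", "postproc_method"])
    rows = []
    for key, g in grouped:
        row = dict(zip(["pathology", "technique", "postproc_method"], key))
        for col, name in (
            ("volumetric_iou", "iou"),
            ("volumetric_dice", "dice"),
            ("predicted_volume_mm3", "predicted_volume"),
            ("ground_truth_volume_mm3", "ground_truth_volume"),
        ):
            vals = g[col].dropna().to_numpy(dtype=float)
            row[f"{name}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{name}_std"] = vals.std(ddof=0) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
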