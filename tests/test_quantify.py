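"""Overlap and classification metrics, volume arithmetic, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidcam.errors import InputError, UndefinedMetricError
from fluidcam.quantify import (
    ConfusionCounts,
    VolumeReport,
    classification_metrics,
    cohort_summary,
    confusion_from_labels,
    cscan_volume,
    dice,
    jaccard,
    mask_volume_mm3,
    pixel_volume,
    responder_status,
)
from fluidcam.types import CScan, VoxelGeometry


def _mask(points, shape=(2, 2)):
    m = np.zeros(shape, dtype=bool)
    for p in points:
        m[p] = True
    return m


class TestOverlap:
    def test_identical_nonempty_masks(self):
        m = _mask([(0, 0), (1, 1)])
        assert jaccard(m, m) == 1.0
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a, b = _mask([(0, 0)]), _mask([(1, 1)])
        assert jaccard(a, b) == 0.0
        assert dice(a, b) == 0.0

    def test_hand_enumerated_pair(self):
        a = _mask([(0, 0), (0, 1)])
        b = _mask([(0, 1), (1, 1)])
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_empty_convention_and_override(self):
        e = np.zeros((3, 3), dtype=bool)
        assert jaccard(e, e) == 1.0
        assert dice(e, e) == 1.0
        assert jaccard(e, e, empty_value=0.0) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            jaccard(np.zeros((2, 2), dtype=bool), np.zeros((3, 3), dtype=bool))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_dice_jaccard_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) < rng.random()
        b = rng.random((8, 8)) < rng.random()
        j, d = jaccard(a, b), dice(a, b)
        assert 0.0 <= j <= d <= 1.0
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestClassificationMetrics:
    def test_undefined_sensitivity_with_no_positives(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert m.sensitivity is None
        assert m.precision is None
        assert m.specificity == 1.0
        assert m.accuracy == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(UndefinedMetricError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        c = ConfusionCounts(tp=30, fp=10, tn=50, fn=20)
        m = classification_metrics(c)
        harm = 2 / (1 / m.precision + 1 / m.sensitivity)
        assert m.f1 == pytest.approx(harm, abs=1e-12)

    def test_confusion_from_labels(self):
        t = np.array([1, 1, 0, 0, 1], dtype=bool)
        p = np.array([1, 0, 1, 0, 1], dtype=bool)
        c = confusion_from_labels(t, p)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)

    def test_rounded_view(self):
        m = classification_metrics(ConfusionCounts(1, 2, 3, 4))
        r = m.rounded(4)
        assert r.accuracy == round(m.accuracy, 4)


class TestVolume:
    def test_default_pixel_volume(self):
        assert pixel_volume(VoxelGeometry()) == pytest.approx(1104.48)

    def test_unit_geometry(self):
        assert pixel_volume(VoxelGeometry(1, 1, 1)) == 1.0

    def test_volume_linear_in_pixel_count(self, rng):
        g = VoxelGeometry()
        m = rng.random((10, 10)) < 0.5
        n = int(m.sum())
        assert mask_volume_mm3(m, g) == pytest.approx(n * 1104.48 / 1e9)

    def test_million_pixel_mask_in_mm3(self):
        m = np.ones((1000, 1000), dtype=bool)
        assert mask_volume_mm3(m, VoxelGeometry()) == pytest.approx(1.10448)

    def test_invalid_geometry(self):
        with pytest.raises(InputError):
            VoxelGeometry(dx=0.0)


class TestCscanVolume:
    def test_no_gated_slice_gives_zero_volume(self, phantom_cscan):
        out = phantom_cscan
        rep = cscan_volume(
            out.cscan, None, pathology="IRF",
            gate_labels=np.zeros(out.cscan.n_slices, dtype=bool),
            cam_masks=out.masks["IRF"], postproc_method="none",
        )
        assert rep.predicted_volume_mm3 == 0.0
        assert rep.n_positive_slices == 0

    def test_oracle_self_comparison_is_perfect(self, phantom_cscan):
        out = phantom_cscan
        rep = cscan_volume(
            out.cscan, None, pathology="IRF",
            gate_labels=out.labels["IRF"], cam_masks=out.masks["IRF"],
            postproc_method="none", gt_masks=out.masks["IRF"],
        )
        assert rep.volumetric_iou == 1.0
        assert rep.volumetric_dice == 1.0
        assert rep.predicted_volume_mm3 == pytest.approx(rep.ground_truth_volume_mm3)

    def test_dice_iou_identity_on_report(self, phantom_cscan, rng):
        out = phantom_cscan
        noisy_masks = [
            m | (rng.random(m.shape) < 0.01) for m in out.masks["IRF"]
        ]
        rep = cscan_volume(
            out.cscan, None, pathology="IRF",
            gate_labels=np.ones(out.cscan.n_slices, dtype=bool),
            cam_masks=noisy_masks, postproc_method="none",
            gt_masks=out.masks["IRF"],
        )
        j = rep.volumetric_iou
        assert rep.volumetric_dice == pytest.approx(2 * j / (1 + j), abs=1e-9)

    def test_volume_invariant_to_slice_order(self, phantom_cscan):
        out = phantom_cscan
        perm = np.random.default_rng(0).permutation(out.cscan.n_slices)
        shuffled = CScan("shuffled", out.cscan.slices[perm], out.cscan.geometry)
        a = cscan_volume(
            out.cscan, None, pathology="IRF", gate_labels=out.labels["IRF"],
            cam_masks=out.masks["IRF"], postproc_method="none",
        ).predicted_volume_mm3
        b = cscan_volume(
            shuffled, None, pathology="IRF", gate_labels=out.labels["IRF"][perm],
            cam_masks=[out.masks["IRF"][i] for i in perm], postproc_method="none",
        ).predicted_volume_mm3
        assert a == b

    def test_strict_gate_excludes_exact_half_score(self, phantom_cscan):
        out = phantom_cscan

        class HalfScoreModel:
            pathology = "IRF"

            def predict(self, image):
                from fluidcam.classifier import PredictionVector

                return PredictionVector(np.array([0.5, 0.5]), 0.5)

        rep = cscan_volume(
            out.cscan, HalfScoreModel(), pathology="IRF",
            cam_masks=out.masks["IRF"], postproc_method="none",
        )
        assert rep.n_positive_slices == 0

    def test_true_positive_restriction_needs_gt_labels(self, phantom_cscan):
        out = phantom_cscan
        from fluidcam.errors import ConfigError

        with pytest.raises(ConfigError):
            cscan_volume(
                out.cscan, None, pathology="IRF",
                gate_labels=out.labels["IRF"], cam_masks=out.masks["IRF"],
                postproc_method="none", restrict_to_true_positives=True,
            )


class TestCohortSummary:
    def _report(self, iou, vol=0.5, pathology="IRF", technique="gradcam",
                method="selective"):
        d = 2 * iou / (1 + iou)
        return VolumeReport(
            scan_id="s", pathology=pathology, technique=technique,
            postproc_method=method, predicted_volume_mm3=vol,
            ground_truth_volume_mm3=0.4, volumetric_iou=iou,
            volumetric_dice=d, n_positive_slices=3,
        )

    def test_single_report_zero_std(self):
        frame = cohort_summary([self._report(0.3)])
        assert frame.loc[0, "iou_std"] == 0.0

    def test_two_reports_population_std(self):
        frame = cohort_summary([self._report(0.2), self._report(0.4)])
        assert frame.loc[0, "iou_mean"] == pytest.approx(0.3)
        assert frame.loc[0, "iou_std"] == pytest.approx(0.1)

    def test_one_row_per_distinct_triple(self):
        reports = [
            self._report(0.2),
            self._report(0.3, technique="scorecam"),
            self._report(0.4, pathology="SRF"),
            self._report(0.5),
        ]
        assert len(cohort_summary(reports)) == 3

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            cohort_summary([])


class TestResponderStatus:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (1.0, 0.85, "Responder"),
            (1.0, 0.90, "Nonresponder"),  # exactly 10% is not enough
            (1.0, 1.20, "Nonresponder"),
            (1.0, 1.00, "Nonresponder"),
        ],
    )
    def test_ten_percent_rule_is_strict(self, pre, post, expected):
        assert responder_status(pre, post) == expected

    def test_zero_pretreatment_volume_undefined(self):
        with pytest.raises(UndefinedMetricError):
            responder_status(0.0, 0.1)
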