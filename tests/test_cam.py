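"""CAM kernels vs independent oracles; Otsu; ensemble fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidcam import cam
from fluidcam.errors import CapabilityError, InputError, ShapeError
from fluidcam.types import BinaryMask, HeatMap

from oracles import (
    normalize as oracle_normalize,
    oracle_ablation_cam,
    oracle_grad_cam,
    oracle_grad_cam_pp,
    oracle_majority,
    oracle_otsu_threshold,
    oracle_score_cam,
)


class ToyCamModel:
    """Fixed activations; class score = head[t] . GAP(A) (+ optional
    image-dependent term for forward-only techniques)."""

    def __init__(self, acts, head, image_term=None):
        self.acts = np.asarray(acts, dtype=np.float64)
        self.head = np.asarray(head, dtype=np.float64)
        self.image_term = image_term

    def cam_activations(self, image):
        return self.acts

    def cam_score_from_activations(self, a, target):
        return float(self.head[target] @ np.asarray(a).mean(axis=(1, 2)))

    def cam_score(self, image, target):
        s = self.cam_score_from_activations(self.acts, target)
        if self.image_term is not None:
            s += self.image_term(np.asarray(image, dtype=np.float64))
        return s

    def cam_score_and_grad(self, image, target):
        k, h, w = self.acts.shape
        grad = np.broadcast_to(
            self.head[target][:, None, None] / (h * w), self.acts.shape
        ).copy()
        return self.cam_score(image, target), self.acts, grad


class GradToy:
    """Arbitrary stored (score, activations, gradient) triple."""

    def __init__(self, score, acts, grad):
        self.score, self.acts, self.grad = score, acts, grad

    def cam_score_and_grad(self, image, target):
        return self.score, self.acts, self.grad


def _rand_model(rng, k=3, h=4, w=5):
    return ToyCamModel(rng.normal(size=(k, h, w)), rng.normal(size=(2, k)))


class TestGradCam:
    def test_mean_of_single_map_gives_normalized_relu_activation(self, rng):
        # y = mean(A): the gradient is constant 1/(hw), so the map is just
        # the (upsampled, normalized) positive part of A.
        acts = rng.normal(size=(1, 4, 4))
        model = GradToy(float(acts.mean()), acts, np.full((1, 4, 4), 1 / 16))
        hm = cam.grad_cam(model, np.zeros((8, 8)), 0)
        expected = oracle_normalize(
            np.maximum(
                np.asarray(
                    oracle_grad_cam(acts, np.full((1, 4, 4), 1 / 16), (8, 8))
                ),
                0,
            )
        )
        np.testing.assert_allclose(hm.values, expected, atol=1e-12)

    def test_constant_positive_maps_normalize_to_ones(self):
        acts = np.full((2, 4, 4), 3.0)
        model = GradToy(1.0, acts, np.full((2, 4, 4), 0.25))
        hm = cam.grad_cam(model, np.zeros((4, 4)), 0)
        np.testing.assert_array_equal(hm.values, np.ones((4, 4)))

    def test_agrees_with_naive_loop_oracle(self, rng):
        for _ in range(20):
            model = _rand_model(rng)
            img = rng.random((10, 12))
            hm = cam.grad_cam(model, img, 1)
            _, acts, grad = model.cam_score_and_grad(img, 1)
            np.testing.assert_allclose(
                hm.values, oracle_grad_cam(acts, grad, img.shape), atol=1e-6
            )

    def test_gradients_match_finite_differences(self, rng):
        """The analytic dA the protocol exposes matches central differences
        of the score function."""
        model = _rand_model(rng, k=2, h=3, w=3)
        img = np.zeros((3, 3))
        _, acts, grad = model.cam_score_and_grad(img, 0)
        eps = 1e-5
        for k in range(2):
            for i in range(3):
                for j in range(3):
                    ap = acts.copy()
                    ap[k, i, j] += eps
                    am = acts.copy()
                    am[k, i, j] -= eps
                    num = (
                        model.cam_score_from_activations(ap, 0)
                        - model.cam_score_from_activations(am, 0)
                    ) / (2 * eps)
                    assert abs(num - grad[k, i, j]) < 1e-3

    def test_missing_protocol_raises_capability_error(self):
        with pytest.raises(CapabilityError):
            cam.grad_cam(object(), np.zeros((4, 4)), 0)


class TestGradCamPP:
    def test_linear_score_reduces_to_half_weighted_relu_gradients(self, rng):
        # Linear score in A: all higher derivatives vanish, alpha = 1/2,
        # so the map is proportional to sum_k (0.5 * sum ReLU(grad)) A_k.
        model = _rand_model(rng)
        img = rng.random((8, 8))
        hm = cam.grad_cam_pp(model, img, 0)
        _, acts, grad = model.cam_score_and_grad(img, 0)
        weights = 0.5 * np.maximum(grad, 0).sum(axis=(1, 2))
        expected = oracle_normalize(
            np.asarray(
                oracle_grad_cam_pp(acts, grad, np.zeros_like(grad),
                                   np.zeros_like(grad), img.shape)
            )
        )
        np.testing.assert_allclose(hm.values, expected, atol=1e-12)
        raw = np.maximum(np.tensordot(weights, acts, axes=1), 0)
        from oracles import finish

        np.testing.assert_allclose(hm.values, finish(raw, img.shape), atol=1e-12)

    def test_all_negative_gradients_give_zero_map(self):
        acts = np.abs(np.random.default_rng(0).normal(size=(2, 4, 4)))
        model = GradToy(1.0, acts, -np.ones((2, 4, 4)))
        hm = cam.grad_cam_pp(model, np.zeros((4, 4)), 0)
        np.testing.assert_array_equal(hm.values, np.zeros((4, 4)))

    def test_higher_order_model_matches_per_pixel_loop_oracle(self, rng):
        class HigherOrderToy:
            def __init__(self, acts, d1, d2, d3):
                self.args = (acts, d1, d2, d3)

            def cam_higher_grads(self, image, target):
                return self.args

        for shape in [(1, 4, 4), (3, 4, 4)]:
            acts = rng.normal(size=shape)
            d1, d2, d3 = (rng.normal(size=shape) for _ in range(3))
            model = HigherOrderToy(acts, d1, d2, d3)
            hm = cam.grad_cam_pp(model, np.zeros((6, 6)), 0)
            np.testing.assert_allclose(
                hm.values, oracle_grad_cam_pp(acts, d1, d2, d3, (6, 6)), atol=1e-6
            )


class TestScoreCam:
    def test_constant_logit_model_gives_uniform_weights(self, rng):
        acts = rng.normal(size=(4, 3, 3))
        model = ToyCamModel(acts, np.zeros((2, 4)))  # score constant 0
        img = rng.random((6, 6))
        hm = cam.score_cam(model, img, 0)
        from oracles import finish

        np.testing.assert_allclose(
            hm.values, finish(acts.mean(axis=0), (6, 6)), atol=1e-10
        )

    def test_single_channel_weight_is_one(self, rng):
        acts = rng.normal(size=(1, 4, 4))
        model = ToyCamModel(acts, rng.normal(size=(2, 1)),
                            image_term=lambda im: float(im.sum()))
        img = rng.random((4, 4))
        hm = cam.score_cam(model, img, 1)
        np.testing.assert_allclose(
            hm.values, oracle_normalize(np.maximum(acts[0], 0)), atol=1e-12
        )

    def test_agrees_with_naive_loop_oracle(self, rng):
        for _ in range(10):
            model = ToyCamModel(
                rng.normal(size=(3, 4, 4)), rng.normal(size=(2, 3)),
                image_term=lambda im: float((im * np.arange(im.size).reshape(im.shape)).sum() / im.size),
            )
            img = rng.random((8, 8))
            hm = cam.score_cam(model, img, 1)
            np.testing.assert_allclose(
                hm.values, oracle_score_cam(model, img, 1, img.shape), atol=1e-6
            )


class TestAblationCam:
    def test_irrelevant_channel_gets_zero_weight(self, rng):
        head = np.array([[1.0, 0.0], [0.5, 0.0]])  # channel 1 never used
        model = ToyCamModel(np.abs(rng.normal(size=(2, 4, 4))) + 1.0, head)
        _, weights = oracle_ablation_cam(model, np.zeros((4, 4)), 0, (4, 4))
        assert weights[1] == pytest.approx(0.0, abs=1e-12)
        hm = cam.ablation_cam(model, np.zeros((4, 4)), 0)
        np.testing.assert_allclose(
            hm.values, oracle_ablation_cam(model, np.zeros((4, 4)), 0, (4, 4))[0],
            atol=1e-12,
        )

    def test_score_halving_channel_weight_half(self):
        # two channels with equal GAP contributions: ablating one halves y.
        acts = np.ones((2, 3, 3))
        model = ToyCamModel(acts, np.array([[1.0, 1.0], [0.0, 0.0]]))
        expected_map, weights = oracle_ablation_cam(model, np.zeros((3, 3)), 0, (3, 3))
        assert weights[0] == pytest.approx(0.5)
        assert weights[1] == pytest.approx(0.5)

    def test_agrees_with_loop_oracle_on_random_models(self, rng):
        for _ in range(20):
            model = _rand_model(rng)
            img = rng.random((6, 6))
            hm = cam.ablation_cam(model, img, 1)
            np.testing.assert_allclose(
                hm.values, oracle_ablation_cam(model, img, 1, img.shape)[0],
                atol=1e-6,
            )

    def test_zero_score_guard(self):
        model = ToyCamModel(np.ones((2, 3, 3)), np.zeros((2, 2)))
        hm = cam.ablation_cam(model, np.zeros((3, 3)), 0)
        np.testing.assert_array_equal(hm.values, np.zeros((3, 3)))


class TestSelfMatchingCam:
    def test_contract_range_shape_determinism(self, rng):
        model = _rand_model(rng)
        img = rng.random((9, 7)) * 255
        a = cam.self_matching_cam(model, img, 0)
        b = cam.self_matching_cam(model, img, 0)
        assert a.values.shape == img.shape
        assert a.values.min() >= 0.0 and a.values.max() <= 1.0
        np.testing.assert_array_equal(a.values, b.values)

    def test_trained_model_lesion_overlap_smoke(self, trained_tiny, phantom_cscan):
        out = phantom_cscan
        i = int(np.argmax(out.labels["IRF"]))
        hm = cam.self_matching_cam(trained_tiny, out.cscan.slices[i], 1)
        mask = cam.otsu_binarize(hm)
        inter = np.logical_and(mask.values, out.masks["IRF"][i]).sum()
        union = np.logical_or(mask.values, out.masks["IRF"][i]).sum()
        assert inter / union > 0.0


class TestOtsu:
    def test_bimodal_map_selects_upper_mode(self):
        values = np.concatenate([np.full(32, 0.1), np.full(32, 0.9)]).reshape(8, 8)
        mask = cam.otsu_binarize(HeatMap(values, "gradcam"))
        np.testing.assert_array_equal(mask.values, values > 0.5)

    def test_constant_map_yields_empty_mask(self):
        mask = cam.otsu_binarize(HeatMap(np.full((5, 5), 0.7), "gradcam"))
        assert not mask.values.any()

    def test_empty_map_rejected(self):
        with pytest.raises(ShapeError):
            cam.otsu_binarize(np.zeros((0, 0)))

    def test_matches_exhaustive_search_on_random_maps(self, rng):
        for _ in range(100):
            values = rng.random((12, 12))
            if rng.random() < 0.3:  # include coarsely quantized maps (ties)
                values = np.round(values * 8) / 8
            mask = cam.otsu_binarize(HeatMap(values, "gradcam"))
            levels = np.minimum((values * 256.0).astype(np.int64), 255)
            t = oracle_otsu_threshold(levels)
            np.testing.assert_array_equal(mask.values, levels > t)


class TestEnsemble:
    def test_three_of_five_votes_keep_a_pixel(self):
        base = [np.zeros((4, 4), dtype=bool) for _ in range(5)]
        for m in base[:3]:
            m[1, 1] = True
        for m in base[:2]:
            m[2, 2] = True
        fused = cam.ensemble_cam(base)
        assert fused.values[1, 1]
        assert not fused.values[2, 2]

    def test_matches_majority_oracle_on_random_quintets(self, rng):
        for _ in range(100):
            masks = [rng.random((8, 8)) < 0.5 for _ in range(5)]
            fused = cam.ensemble_cam(masks)
            np.testing.assert_array_equal(fused.values, oracle_majority(masks))

    def test_input_validation(self):
        masks = [np.zeros((3, 3), dtype=bool)] * 4
        with pytest.raises(InputError):
            cam.ensemble_cam(masks)
        bad = [np.zeros((3, 3), dtype=bool)] * 4 + [np.zeros((2, 2), dtype=bool)]
        with pytest.raises(InputError):
            cam.ensemble_cam(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**30), st.integers(0, 4))
    def test_permutation_invariant_and_monotone(self, seed, extra_idx):
        r = np.random.default_rng(seed)
        masks = [r.random((6, 6)) < 0.5 for _ in range(5)]
        fused = cam.ensemble_cam(masks).values
        perm = r.permutation(5)
        np.testing.assert_array_equal(
            cam.ensemble_cam([masks[i] for i in perm]).values, fused
        )
        grown = [m.copy() for m in masks]
        grown[extra_idx] |= r.random((6, 6)) < 0.3
        assert (cam.ensemble_cam(grown).values >= fused).all()


class TestNormalization:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_idempotent_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        m = r.normal(size=(6, 6)) * r.choice([0.0, 1.0])
        once = cam.normalize_heatmap(m)
        assert once.min() >= 0.0 and once.max() <= 1.0
        np.testing.assert_allclose(cam.normalize_heatmap(once), once, atol=1e-12)
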