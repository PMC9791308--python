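"""Hierarchical perturbation saliency: thresholds, refinement, stitching."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from histoweak.interpret_saliency import (
    HiPeConfig,
    SaliencyMap,
    hipe_saliency,
    saliency_segmentation,
    stitch_slide_saliency,
    threshold_class_variance,
    threshold_standard,
    variance,
)
from histoweak.tissue_seg import PatchGrid


class TestVariance:
    def test_constant_list_zero(self):
        assert variance([3.0, 3.0, 3.0]) == 0.0

    def test_hand_case(self):
        assert variance([1, 2, 3]) == pytest.approx(2 / 3)

    def test_scaling_identity(self, rng):
        x = rng.standard_normal(20)
        assert variance(4.0 * x) == pytest.approx(16.0 * variance(x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            variance([])


def mask_for(shape, sl):
    m = np.zeros(shape, dtype=bool)
    m[sl] = True
    return m


class TestThresholdStandard:
    def test_uniform_plane_passes(self):
        s = np.full((4, 4), 0.7)
        assert threshold_standard(s, mask_for((4, 4), np.s_[0:2, 0:2])) == 1

    def test_masked_max_reaches_midpoint(self):
        s = np.full((4, 4), 0.1)
        s[3, 3] = 0.9
        m = mask_for((4, 4), np.s_[3, 3])  # masked max = 0.9 >= midpoint 0.5
        assert threshold_standard(s, m) == 1

    def test_masked_region_below_midpoint(self):
        s = np.full((4, 4), 0.1)
        s[3, 3] = 0.9
        s[0, 0] = 0.4
        m = mask_for((4, 4), np.s_[0:2, 0:2])  # masked max 0.4 < 0.5
        assert threshold_standard(s, m) == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            threshold_standard(np.zeros((2, 2)), np.zeros((2, 2), bool))


class TestThresholdClassVariance:
    def test_identical_planes_pass(self):
        stack = np.tile(np.linspace(0, 1, 16).reshape(4, 4), (3, 1, 1))
        assert threshold_class_variance(stack, mask_for((4, 4), np.s_[0:2, 0:2])) == 1

    def test_local_disagreement_fails(self):
        # equal global ranges, one masked pixel where classes wildly disagree
        base = np.linspace(0, 1, 16).reshape(4, 4)
        stack = np.stack([base.copy(), base.copy()])
        stack[0, 0, 0] = 1.0
        stack[1, 0, 0] = 0.0
        m = mask_for((4, 4), np.s_[0, 0])
        # midpoints are both 0.5 (global ranges [0,1]) -> right side 0;
        # masked cross-class variance = var([1, 0]) = 0.25 > 0
        assert threshold_class_variance(stack, m) == 0

    def test_translated_planes_pass(self):
        # planes are global-range translates: midpoints differ, masked agrees
        base = np.linspace(0, 1, 16).reshape(4, 4)
        stack = np.stack([base, base + 2.0])
        m = mask_for((4, 4), np.s_[1, 1])
        # right side = var([0.5, 2.5]) = 1.0; masked var = var([x, x+2]) = 1.0
        assert threshold_class_variance(stack, m) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            threshold_class_variance(np.zeros((1, 4, 4)), np.ones((4, 4), bool))


class LinearToyModel:
    """C-logit linear model over a flat image; counts its own calls."""

    def __init__(self, W):
        self.W = np.asarray(W, dtype=np.float64)
        self.calls = 0

    def __call__(self, image):
        self.calls += 1
        return self.W @ np.asarray(image, dtype=np.float64).ravel()


class TestHipeSaliency:
    def test_constant_model_all_zero_stack(self):
        model = lambda img: np.array([1.0, -2.0])
        out = hipe_saliency(model, np.random.default_rng(0).random((16, 16)),
                            HiPeConfig(min_cell=2))
        assert np.all(out.stack == 0.0)

    def test_deterministic(self, rng):
        img = rng.random((16, 16))
        W = rng.standard_normal((2, 256))
        cfg = HiPeConfig(min_cell=2, perturbation="mean_fill")
        s1 = hipe_saliency(LinearToyModel(W), img, cfg).stack
        s2 = hipe_saliency(LinearToyModel(W), img, cfg).stack
        assert np.array_equal(s1, s2)

    def test_ranking_matches_occlusion_oracle(self, rng):
        img = rng.random((8, 8))
        W = rng.standard_normal((2, 64))
        cfg = HiPeConfig(initial_cells=4, min_cell=1, perturbation="fade")
        out = hipe_saliency(LinearToyModel(W), img, cfg, threshold="standard")
        # brute-force single-pixel occlusion deltas
        model = LinearToyModel(W)
        base = model(img)
        for c in range(2):
            deltas = np.empty(64)
            for i in range(64):
                pert = img.copy().ravel()
                pert[i] = 0.0
                deltas[i] = (base - model(pert.reshape(8, 8)))[c]
            rho = spearmanr(out.stack[c].ravel(), deltas).statistic
            assert rho >= 0.8

    def test_deeper_refinement_never_fewer_calls(self, rng):
        img = rng.random((16, 16))
        W = rng.standard_normal((2, 256))
        calls = []
        for depth in (1, 2, 3):
            m = LinearToyModel(W)
            hipe_saliency(m, img, HiPeConfig(min_cell=1, max_depth=depth),
                          threshold="exhaustive")
            calls.append(m.calls)
        assert calls == sorted(calls)

    def test_class_variance_fewer_calls_than_exhaustive(self, rng):
        img = rng.random((16, 16))
        W = rng.standard_normal((3, 256))
        m1, m2 = LinearToyModel(W), LinearToyModel(W)
        cfg = HiPeConfig(min_cell=1, perturbation="fade")
        hipe_saliency(m1, img, cfg, threshold="class_variance")
        hipe_saliency(m2, img, cfg, threshold="exhaustive")
        assert m1.calls < m2.calls

    def test_model_call_count_recorded(self, rng):
        m = LinearToyModel(rng.standard_normal((2, 64)))
        out = hipe_saliency(m, rng.random((8, 8)), HiPeConfig(min_cell=4))
        assert out.meta["model_calls"] == m.calls


class TestStitching:
    def test_single_patch_identity(self, rng):
        stack = rng.random((3, 8, 8))
        grid = PatchGrid("s", 0, 8, np.array([[0, 0]]))
        out = stitch_slide_saliency([SaliencyMap(stack)], grid)
        assert np.allclose(out.stack[:, :8, :8], stack)

    def test_adjacent_patches_seam_exact(self, rng):
        a, b = rng.random((3, 8, 8)), rng.random((3, 8, 8))
        grid = PatchGrid("s", 0, 8, np.array([[0, 0], [8, 0]]))
        out = stitch_slide_saliency([SaliencyMap(a), SaliencyMap(b)], grid)
        assert np.allclose(out.stack[:, :8, :8], a)
        assert np.allclose(out.stack[:, :8, 8:16], b)

    def test_collision_rejected(self, rng):
        maps = [SaliencyMap(rng.random((3, 8, 8))) for _ in range(2)]
        grid = PatchGrid("s", 0, 8, np.array([[0, 0], [4, 0]]))
        with pytest.raises(ValueError, match="collides"):
            stitch_slide_saliency(maps, grid)

    def test_empty_grid_empty_canvas(self):
        grid = PatchGrid("s", 0, 8, np.zeros((0, 2), dtype=np.int64))
        out = stitch_slide_saliency([], grid, canvas_shape=(16, 16))
        assert out.stack.shape[1:] == (16, 16)
        assert np.all(out.stack == 0)


class TestSaliencySegmentation:
    def test_dominant_plane_uniform_label(self):
        stack = np.stack([np.full((4, 4), 2.0), np.ones((4, 4)), np.ones((4, 4))])
        labels, rgb = saliency_segmentation(SaliencyMap(stack))
        assert np.all(labels == 1)
        assert np.all(rgb == np.array([255, 0, 0]))

    def test_half_split_boundary_at_column(self):
        a = np.zeros((4, 8))
        a[:, :4] = 1.0
        b = np.zeros((4, 8))
        b[:, 4:] = 1.0
        c = np.full((4, 8), 0.1)
        labels, _ = saliency_segmentation(SaliencyMap(np.stack([a, b, c])))
        assert np.all(labels[:, :4] == 1)
        assert np.all(labels[:, 4:] == 2)

    def test_positive_scaling_invariance(self, rng):
        stack = rng.random((3, 6, 6)) + 0.1
        l1, _ = saliency_segmentation(SaliencyMap(stack))
        scaled = stack.copy()
        scaled[0] *= 7.5  # min-max normalization removes positive scale
        l2, _ = saliency_segmentation(SaliencyMap(scaled))
        assert np.array_equal(l1, l2)

    def test_all_zero_stack_background(self):
        labels, rgb = saliency_segmentation(SaliencyMap(np.zeros((3, 4, 4))))
        assert np.all(labels == 0)
        assert np.all(rgb == 255)

    def test_tissue_mask_limits_foreground(self, rng):
        stack = rng.random((3, 4, 4)) + 0.5
        tissue = np.zeros((4, 4), bool)
        tissue[0, 0] = True
        labels, _ = saliency_segmentation(SaliencyMap(stack), tissue_mask=tissue)
        assert labels[0, 0] > 0
        assert np.all(labels[1:, :] == 0)
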