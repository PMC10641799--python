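"""Grad-CAM channel weights, map nonnegativity and mask binarization."""

import numpy as np
import pytest

from octlam.backbone import BackboneConfig
from octlam.cam import batch_generate_masks, cam_to_mask, gradcam
from octlam.preprocess import Volume
from conftest import numerical_gradient


class ToyTapModel:
    """Duck-typed model with a single 2-channel 3x3x3 tap.

    The activations are a fixed nonlinear function of the input and the
    class score a nonlinear function of the activations, so the chain rule
    through the backward pass is exercised end to end.
    """

    class _Cfg:
        stage_taps = ("stage4",)

    cfg = _Cfg()

    def __init__(self, rng, head="tanh"):
        self.w = rng.normal(size=(2, 2, 3, 3, 3))
        self.head = head
        self._acts = None

    def _score_from_acts(self, acts, c):
        if self.head == "tanh":
            return float((self.w[c] * np.tanh(acts)).sum())
        # mean-pool head: the score is the spatial mean of channel 0
        return float(acts[0].mean())

    def forward(self, x, train=False):
        a = np.stack([x[0, 0], x[0, 0] ** 2])  # (2, D, H, W)
        self._acts = a
        return np.array([[self._score_from_acts(a, c) for c in range(2)]])

    def features(self):
        return {"stage4": self._acts[None]}

    def backward(self, dlogits, capture=None):
        a = self._acts
        if self.head == "tanh":
            g = sum(dlogits[0, c] * self.w[c] * (1 - np.tanh(a) ** 2) for c in range(2))
        else:
            g = np.zeros_like(a)
            g[0] = dlogits[0, 0] / a[0].size
        self.tap_grads = {"stage4": g[None]}


@pytest.fixture()
def toy_volume(rng):
    # (H, W, D) = (3, 3, 3) so the tap sees a 3x3x3 grid
    return rng.normal(size=(3, 3, 3))


def test_alpha_matches_central_difference_oracle(rng, toy_volume):
    """Channel weights equal spatially pooled score gradients (FD oracle)."""
    model = ToyTapModel(rng)
    for c in (0, 1):
        cm = gradcam(model, toy_volume, class_index=c)
        acts = model._acts.copy()
        z = acts[0].size
        alpha_fd = np.empty(2)
        for k in range(2):
            def score():
                return model._score_from_acts(acts, c)
            g = numerical_gradient(score, acts[k], eps=1e-6)
            alpha_fd[k] = g.sum() / z
        assert cm.Z == z
        np.testing.assert_allclose(cm.alpha, alpha_fd, atol=1e-3)


def test_cam_nonnegative_everywhere(rng, toy_volume):
    cm = gradcam(ToyTapModel(rng), toy_volume, class_index=1)
    assert (cm.values >= 0).all()


def test_mean_pool_head_cam_proportional_to_channel0(rng, toy_volume):
    """Score = spatial mean of channel 0 => CAM is proportional to ReLU(A^0)."""
    model = ToyTapModel(rng, head="mean")
    cm = gradcam(model, toy_volume, class_index=0)
    a0 = model._acts[0]
    np.testing.assert_allclose(cm.values, np.maximum(a0, 0) / a0.size, atol=1e-12)


def test_detached_class_gives_zero_cam(rng, toy_volume):
    """A class whose score ignores the activations has an all-zero map."""
    model = ToyTapModel(rng, head="mean")
    cm = gradcam(model, toy_volume, class_index=1)  # mean head only wires class 0
    assert np.all(cm.values == 0)


def test_invalid_class_and_tap_rejected(rng, toy_volume):
    with pytest.raises(ValueError):
        gradcam(ToyTapModel(rng), toy_volume, class_index=5)


class TestCamToMask:
    def test_threshold_boundary_49_and_50(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0] = 255.0  # anchors the max so normalization is identity
        vals[1, 1, 1] = 49.0
        vals[2, 2, 2] = 50.0
        mask = cam_to_mask(vals, (4, 4, 4), threshold=50.0)
        m = np.moveaxis(mask.values, -1, 0)  # back to (D, H, W)
        assert m[1, 1, 1] == 0
        assert m[2, 2, 2] == 1
        assert m[0, 0, 0] == 1

    def test_half_max_cam_masks_the_max_half(self):
        vals = np.zeros((2, 2, 2))
        vals[0] = 7.0  # half the voxels at the max
        mask = cam_to_mask(vals, (2, 2, 2), threshold=50.0)
        m = np.moveaxis(mask.values, -1, 0)
        assert np.all(m[0] == 1) and np.all(m[1] == 0)

    def test_ones_count_non_increasing_in_threshold(self, rng):
        vals = rng.random((3, 3, 3)) * 10
        counts = [
            cam_to_mask(vals, (6, 6, 6), threshold=t).values.sum()
            for t in range(0, 256, 16)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_cam_falls_back_to_all_ones(self, caplog):
        with caplog.at_level("WARNING"):
            mask = cam_to_mask(np.full((2, 2, 2), 3.0), (5, 5, 5))
        assert np.all(mask.values == 1)
        assert mask.values.shape == (5, 5, 5)
        assert "constant" in caplog.text

    def test_mask_shape_and_binary_values(self, rng):
        mask = cam_to_mask(rng.random((3, 3, 2)), (48, 48, 16))
        assert mask.values.shape == (48, 48, 16)
        assert set(np.unique(mask.values)) <= {0, 1}


class TestBatchGenerateMasks:
    @pytest.fixture()
    def tiny_model(self, rng):
        from octlam.backbone import build_backbone

        return build_backbone(BackboneConfig(depth=18, base_channels=2), rng)

    @pytest.fixture()
    def volumes(self, rng):
        return [
            Volume(data=rng.random((24, 24, 8)), patient_id=f"P{i}", eye_id="OD", label=i % 2)
            for i in range(4)
        ]

    def test_one_mask_per_volume(self, tiny_model, volumes):
        masks = batch_generate_masks(tiny_model, volumes)
        assert len(masks) == 4
        for v in volumes:
            assert masks[(v.patient_id, "OD")].values.shape == v.data.shape

    def test_cache_hit_is_identical(self, tiny_model, volumes, tmp_path):
        m1 = batch_generate_masks(tiny_model, volumes, cache_dir=tmp_path)
        files = sorted(tmp_path.glob("*.npz"))
        assert len(files) == 4
        payloads = [f.read_bytes() for f in files]
        m2 = batch_generate_masks(tiny_model, volumes, cache_dir=tmp_path)
        assert [f.read_bytes() for f in sorted(tmp_path.glob("*.npz"))] == payloads
        for k in m1:
            np.testing.assert_array_equal(m1[k].values, m2[k].values)

    def test_missing_label_under_true_label_policy(self, tiny_model, rng):
        v = Volume(data=rng.random((24, 24, 8)), patient_id="P", eye_id="OD", label=None)
        with pytest.raises(ValueError):
            batch_generate_masks(tiny_model, [v], label_policy="true_label")
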