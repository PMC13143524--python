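"""The fusion model: branch encoding, attention fusion, head, variants."""

import numpy as np
import pytest

from ocufusion.model import (
    AttentionFusion,
    ClassificationHead,
    CSFNetModel,
    ModelConfig,
    VARIANTS,
    build_variant,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from ocufusion.nn.attention import softmax


def _tiny_cfg(variant="csfnet", **kw):
    base = dict(variant=variant, backbone="tiny", feature_dim=16, image_size=32)
    base.update(kw)
    return ModelConfig(**base)


def _batch(rng, n=2, size=32):
    return {
        s: rng.normal(size=(n, size, size, 3)).astype(np.float32)
        for s in ("rgb", "hsv", "ycbcr")
    }


class TestEncodeBranches:
    def test_shapes_and_independence(self, rng):
        model = build_variant("csfnet", _tiny_cfg())
        batch = _batch(rng)
        feats = model.encode_branches(batch)
        assert set(feats) == {"rgb", "hsv", "ycbcr"}
        assert all(f.shape == (2, 16) for f in feats.values())
        # perturbing only the HSV plane changes only F_HSV
        batch2 = dict(batch)
        batch2["hsv"] = batch["hsv"] + 1.0
        feats2 = model.encode_branches(batch2)
        np.testing.assert_array_equal(feats["rgb"], feats2["rgb"])
        np.testing.assert_array_equal(feats["ycbcr"], feats2["ycbcr"])
        assert not np.array_equal(feats["hsv"], feats2["hsv"])

    def test_no_weight_sharing_across_branches(self):
        model = build_variant("csfnet", _tiny_cfg())
        ids = [
            {id(p) for p in model.branches[s].parameters()}
            for s in ("rgb", "hsv", "ycbcr")
        ]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_zeroed_final_linear_yields_bias_embedding(self, rng):
        """With the embedding linear's weights zeroed, branch features equal
        its bias (pushed through the trailing activation) for any input."""
        model = build_variant("csfnet", _tiny_cfg())
        branch = model.branches["rgb"]
        lin = [m for m in branch.modules() if m.__class__.__name__ == "Linear"][-1]
        lin.weight.data[...] = 0.0
        lin.bias.data[...] = rng.normal(size=lin.bias.data.shape).astype(np.float32)
        f1 = branch(rng.normal(size=(1, 32, 32, 3)).astype(np.float32))
        f2 = branch(rng.normal(size=(1, 32, 32, 3)).astype(np.float32) * 5)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_allclose(f1[0], np.maximum(lin.bias.data, 0.0))


class TestAttentionFusionModule:
    def test_single_token_identity_exact(self, rng):
        fusion = AttentionFusion(8, mode="single-token")
        f = rng.normal(size=(4, 24)).astype(np.float32)
        out = fusion(f)
        assert np.array_equal(out, f @ fusion.attn.w_v.data + fusion.attn.b_v.data)

    def test_identity_value_projection_passthrough(self, rng):
        fusion = AttentionFusion(8, mode="single-token")
        fusion.attn.w_v.data[...] = np.eye(24, dtype=np.float32)
        fusion.attn.b_v.data[...] = 0.0
        f = rng.normal(size=(4, 24)).astype(np.float32)
        np.testing.assert_array_equal(fusion(f), f)

    def test_three_token_mode_round_trip_shape(self, rng):
        fusion = AttentionFusion(8, mode="three-token")
        f = rng.normal(size=(4, 24)).astype(np.float32)
        assert fusion(f).shape == (4, 24)
        assert fusion.attn.dim == 8  # per-token projections


class TestClassificationHead:
    def test_equal_logits_give_uniform_probabilities(self):
        logits = np.full((3, 6), 1.7)
        np.testing.assert_allclose(softmax(logits, axis=1), 1 / 6, atol=1e-9)

    def test_probabilities_sum_to_one_and_argmax_matches_logits(self, rng):
        logits = rng.normal(size=(1000, 6))
        p = softmax(logits, axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p.argmax(axis=1), logits.argmax(axis=1))

    def test_head_parameter_count(self):
        # 3072->1024 (+BN) -> 512 (+BN) -> 6, biases throughout
        assert ClassificationHead(3072).num_parameters() == 3_677_702


class TestVariants:
    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_variant("fusion-super")

    def test_rgb_only_accepts_plain_rgb_batch(self, rng):
        model = build_variant("rgb-only", _tiny_cfg("rgb-only"))
        x = rng.normal(size=(2, 32, 32, 3)).astype(np.float32)
        assert model.forward(x).shape == (2, 6)

    def test_no_attention_count_differs_by_fusion_block(self):
        full = count_parameters(build_variant("csfnet"))
        plain = count_parameters(build_variant("fusion-no-attention"))
        assert full - plain == 3 * (3072 * 3072 + 3072)

    def test_se_fusion_matches_hand_gate_on_toy_vector(self, rng):
        """SE recalibration equals input * sigmoid-gate computed by an
        independent hand implementation (length-8 toy, reduction 4)."""
        from ocufusion.model import SEVector

        se = SEVector(8, reduction=4)
        x = rng.normal(size=(3, 8)).astype(np.float32)
        w1, b1 = se.fc1.weight.data, se.fc1.bias.data
        w2, b2 = se.fc2.weight.data, se.fc2.bias.data
        gate = 1.0 / (1.0 + np.exp(-(np.maximum(x @ w1 + b1, 0) @ w2 + b2)))
        np.testing.assert_allclose(se(x), x * gate, atol=1e-6)

    @pytest.mark.parametrize("tag", ["fusion-se", "fusion-cbam-channel", "fusion-eca", "fusion-nam"])
    def test_channel_fusion_variants_forward_and_train(self, tag, rng):
        model = build_variant(tag, _tiny_cfg(tag))
        batch = _batch(rng)
        logits = model.forward(batch, training=True)
        assert logits.shape == (2, 6)
        model.zero_grad()
        model.backward(np.ones_like(logits))
        fusion_grads = [np.abs(p.grad).sum() for p in model.fusion.parameters()]
        assert any(g > 0 for g in fusion_grads)

    def test_baseline_variants_forward(self, rng):
        x = rng.normal(size=(1, 64, 64, 3)).astype(np.float32)
        for tag in ("baseline-resnet50", "baseline-efficientnet"):
            model = build_variant(tag, ModelConfig(variant=tag, image_size=64))
            assert model.forward(x).shape == (1, 6)

    def test_variant_registry_complete(self):
        assert set(VARIANTS) == {
            "csfnet", "rgb-only", "fusion-no-attention", "fusion-se",
            "fusion-cbam-channel", "fusion-eca", "fusion-nam",
            "baseline-resnet50", "baseline-efficientnet", "baseline-vit",
        }


class TestGradientFlow:
    def test_gradient_reaches_all_branches_and_value_projection(self, rng):
        model = build_variant("csfnet", _tiny_cfg())
        batch = _batch(rng)
        logits = model.forward(batch, training=True)
        model.zero_grad()
        model.backward(np.ones_like(logits))
        assert np.abs(model.fusion.attn.w_v.grad).max() > 0
        assert np.all(model.fusion.attn.w_q.grad == 0)  # single-token property
        for s in ("rgb", "hsv", "ycbcr"):
            grads = [np.abs(p.grad).sum() for p in model.branches[s].parameters()]
            assert sum(grads) > 0, f"no gradient reached the {s} branch"

    def test_eval_forward_deterministic(self, rng):
        model = build_variant("csfnet", _tiny_cfg(dropout=0.5))
        batch = _batch(rng)
        a = model.forward(batch, training=False)
        b = model.forward(batch, training=False)
        np.testing.assert_array_equal(a, b)


class TestCheckpoint:
    def test_round_trip_preserves_outputs_and_metadata(self, tmp_path, rng):
        from ocufusion.colorspace import NormalizationStats

        model = build_variant("csfnet", _tiny_cfg())
        batch = _batch(rng)
        ref = model.forward(batch)
        path = tmp_path / "ck.npz"
        save_checkpoint(model, path, norm_stats=NormalizationStats.identity(),
                        extra={"epoch": 3})
        loaded, stats, extra = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.forward(batch), ref)
        assert extra["epoch"] == 3
        assert stats is not None and loaded.class_names == model.class_names


class TestPretrainedGate:
    def test_pretrained_without_weights_file_raises(self):
        cfg = _tiny_cfg(pretrained=True)
        with pytest.raises(ValueError, match="weights file"):
            build_variant("csfnet", cfg)
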