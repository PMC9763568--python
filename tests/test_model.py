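import numpy as np
import pytest

from seuneter import nn
from seuneter.model import (
    ModelConfig,
    SeDeepUnet,
    build_model,
    load_checkpoint,
    save_checkpoint,
    se_block,
)


def tiny_config(**overrides):
    base = dict(in_channels=1, n_classes=3, depth=2, base_channels=4,
                max_channels=64, se_reduction=2, seed=0)
    base.update(overrides)
    return ModelConfig(**base)


class TestArchitecture:
    def test_default_bottleneck_is_1024_at_16(self):
        desc, _ = build_model(ModelConfig(), (512, 512))
        assert desc.bottleneck["out_shape"] == (1024, 16, 16)
        head = desc.stages[-1]
        assert head["out_shape"] == (16, 512, 512)

    def test_default_channel_schedule_doubles_to_1024(self):
        cfg = ModelConfig()
        assert [cfg.channels_at(i) for i in range(6)] == [32, 64, 128, 256, 512, 1024]
        desc, _ = build_model(cfg, (512, 512))
        downs = [s for s in desc.stages if s["kind"] in ("down", "bottleneck")]
        assert len(downs) == 5
        assert len([s for s in desc.stages if s["kind"] == "up"]) == 5

    def test_depth1_halving_rule(self):
        desc, net = build_model(ModelConfig(depth=1, base_channels=8, n_classes=5,
                                            se_reduction=2), (32, 32))
        assert desc.bottleneck["out_shape"] == (16, 16, 16)
        out = net.predict_logits(np.zeros((1, 1, 32, 32)))
        assert out.shape == (1, 5, 32, 32)

    def test_channel_cap_at_max_channels(self):
        cfg = ModelConfig(depth=4, base_channels=8, max_channels=32, se_reduction=2)
        assert [cfg.channels_at(i) for i in range(5)] == [8, 16, 32, 32, 32]

    def test_indivisible_input_rejected_at_build(self):
        with pytest.raises(ValueError, match="2\\^depth"):
            build_model(tiny_config(), (30, 30))

    def test_parameter_count_matches_closed_form(self):
        # independent oracle: sum the conv/BN/SE/upconv parameter formulas
        cfg = tiny_config()  # depth 2, base 4 -> channels 4, 8, 16
        desc, net = build_model(cfg, (16, 16))

        def dconv(cin, cout, r):
            conv = (cin * 9 * cout + cout) + (cout * 9 * cout + cout)
            bn = 2 * cout + 2 * cout
            hid = max(1, cout // r)
            se = (cout * hid + hid) + (hid * cout + cout)
            return conv + bn + se

        expected = dconv(1, 4, 2) + dconv(4, 8, 2) + dconv(8, 16, 2)  # stem + 2 downs
        expected += (16 * 8 * 4 + 8) + dconv(16, 8, 2)  # up1: upconv + dconv
        expected += (8 * 4 * 4 + 4) + dconv(8, 4, 2)  # up2
        expected += 4 * 3 + 3  # 1x1 head
        assert desc.total_parameters == expected

    def test_skip_shapes_match_encoder_outputs(self):
        desc, _ = build_model(tiny_config(), (32, 32))
        enc = {s["out_shape"][1:]: s["out_shape"][0] for s in desc.stages if s["kind"] in ("stem", "down")}
        for s in desc.stages:
            if s["kind"] == "up":
                assert enc[s["out_shape"][1:]] == s["out_shape"][0]


class TestSeBlock:
    def test_zero_features_stay_zero(self):
        rng = np.random.default_rng(0)
        blk = nn.SEBlock(4, 2, rng)
        out = blk(np.zeros((1, 4, 3, 3)))
        assert np.all(out == 0.0)

    def test_hand_computed_two_channel_rescaling(self):
        feat = np.array([[[[1.0, 2.0], [3.0, 4.0]], [[-1.0, 0.0], [1.0, 2.0]]]])
        w1 = np.array([[0.5, -0.25]])
        b1 = np.array([0.1])
        w2 = np.array([[2.0], [-1.0]])
        b2 = np.array([0.0, 0.5])
        # brute-force arithmetic: squeeze means are 2.5 and 0.5
        z = np.array([2.5, 0.5])
        h = max(0.0, 0.5 * 2.5 - 0.25 * 0.5 + 0.1)  # 1.225
        s0 = 1 / (1 + np.exp(-(2.0 * h + 0.0)))
        s1 = 1 / (1 + np.exp(-(-1.0 * h + 0.5)))
        out = se_block(feat, (w1, b1, w2, b2))
        assert np.allclose(out[0, 0], feat[0, 0] * s0)
        assert np.allclose(out[0, 1], feat[0, 1] * s1)

    def test_output_is_spatially_constant_multiple_per_channel(self):
        rng = np.random.default_rng(1)
        blk = nn.SEBlock(3, 2, rng)
        x = rng.normal(size=(2, 3, 5, 5))
        out = blk(x)
        ratio = out / x
        for n in range(2):
            for c in range(3):
                assert np.allclose(ratio[n, c], ratio[n, c].flat[0])
                assert 0.0 < ratio[n, c].flat[0] < 1.0

    def test_weight_shape_mismatch_rejected(self):
        feat = np.zeros((1, 4, 2, 2))
        w1 = np.zeros((2, 3))  # expects C=3, features have C=4
        with pytest.raises(ValueError, match="channels"):
            se_block(feat, (w1, np.zeros(2), np.zeros((4, 2)), np.zeros(4)))


class TestForward:
    def test_batch_shape_contract(self, schema):
        _, net = build_model(tiny_config(n_classes=16), (64, 64))
        out = net.predict_logits(np.random.default_rng(0).normal(size=(2, 1, 64, 64)))
        assert out.shape == (2, 16, 64, 64)

    def test_eval_mode_deterministic(self):
        _, net = build_model(tiny_config(), (16, 16))
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16))
        assert np.array_equal(net.predict_logits(x), net.predict_logits(x))

    def test_outputs_finite_for_random_input(self):
        _, net = build_model(tiny_config(), (16, 16))
        x = np.random.default_rng(5).normal(scale=10.0, size=(2, 1, 16, 16))
        assert np.all(np.isfinite(net.predict_logits(x)))

    def test_non_finite_input_rejected(self):
        _, net = build_model(tiny_config(), (16, 16))
        x = np.zeros((1, 1, 16, 16))
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            net.forward(x)

    def test_bilinear_upsampling_mode(self):
        _, net = build_model(tiny_config(upsample_mode="bilinear"), (16, 16))
        out = net.predict_logits(np.random.default_rng(0).normal(size=(1, 1, 16, 16)))
        assert out.shape == (1, 3, 16, 16)
        assert np.all(np.isfinite(out))

    def test_disabling_se_recovers_plain_unet(self):
        _, net = build_model(tiny_config(use_se=False), (16, 16))
        assert not any(isinstance(l, nn.SEBlock)
                       for l in net.stem.layers)  # type: ignore[attr-defined]
        out = net.predict_logits(np.zeros((1, 1, 16, 16)))
        assert out.shape == (1, 3, 16, 16)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central-difference check of d(sum(out*R))/dtheta on sampled weights."""
        _, net = build_model(tiny_config(), (8, 8))
        net.train(True)
        x = np.random.default_rng(0).normal(size=(2, 1, 8, 8))
        R = np.random.default_rng(1).normal(size=(2, 3, 8, 8))
        net.forward(x)
        net.zero_grad()
        net.backward(R)
        params = list(net.params())
        rng = np.random.default_rng(2)
        checked = 0
        for pi in rng.choice(len(params), size=10, replace=False):
            p = params[pi]
            idx = tuple(int(rng.integers(0, s)) for s in p.data.shape)
            eps, orig = 1e-6, p.data[idx]
            p.data[idx] = orig + eps
            f1 = float((net.forward(x) * R).sum())
            p.data[idx] = orig - eps
            f2 = float((net.forward(x) * R).sum())
            p.data[idx] = orig
            num = (f1 - f2) / (2 * eps)
            assert abs(num - p.grad[idx]) < 1e-5 + 1e-4 * abs(num), p.name
            checked += 1
        assert checked == 10


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        _, net = build_model(tiny_config(seed=3), (16, 16))
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16))
        net.train(True)
        net.forward(x)  # move BatchNorm running stats off their defaults
        ref = net.predict_logits(x)
        save_checkpoint(net, tmp_path / "ck.npz", extra={"note": "t"})
        net2, extra = load_checkpoint(tmp_path / "ck.npz")
        assert extra == {"note": "t"}
        assert np.allclose(net2.predict_logits(x), ref)
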