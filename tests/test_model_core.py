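"""Architecture tests: pyramid, shared encoder, stages, variants, counting."""

import numpy as np
import pytest

from litemrinet import (ConfigurationError, DimensionError, LiteMRINet,
                        ModelConfig, build_pyramid, build_variant,
                        count_trainable_parameters, load_checkpoint,
                        save_checkpoint, nn)


class TestBuildPyramid:
    def test_level_shapes(self):
        img = np.zeros((256, 256, 3))
        p = build_pyramid(img)
        assert p.level_0.shape == (256, 256, 3)
        assert p.level_1.shape == (128, 128, 3)
        assert p.level_2.shape == (64, 64, 3)

    def test_level0_is_input_unchanged(self, rng):
        img = rng.random((64, 64, 3))
        p = build_pyramid(img)
        assert p.level_0 is img

    def test_constant_image_stays_constant(self):
        p = build_pyramid(np.full((64, 64, 3), 0.5))
        for level in p:
            assert np.allclose(level, 0.5)

    def test_checkerboard_area_average(self):
        # per-pixel checkerboard: every 2x2 window holds two a's and two b's,
        # so area averaging gives the constant (a+b)/2 (hand-average the four
        # pixels under each output pixel)
        a, b = 0.2, 0.8
        cells = np.indices((64, 64)).sum(axis=0) % 2
        img = np.where(cells, b, a)[:, :, None] * np.ones((1, 1, 3))
        p = build_pyramid(img)
        assert np.allclose(p.level_1, (a + b) / 2)
        assert np.allclose(p.level_2, (a + b) / 2)

    @pytest.mark.parametrize("shape", [(65, 65, 3), (64, 32, 3)])
    def test_bad_shapes_raise_naming_offender(self, shape):
        with pytest.raises(DimensionError, match=r"\d+"):
            build_pyramid(np.zeros(shape))


class TestSharedEncoder:
    def test_feature_map_shapes(self):
        model = LiteMRINet(ModelConfig(input_size=64), seed=0).eval()
        pyr = build_pyramid(np.zeros((1, 64, 64, 3), dtype=np.float32))
        with nn.no_grad():
            f0, f1, f2 = model.encode(pyr)
        assert f0.shape == (1, 64, 64, 64)
        assert f1.shape == (1, 32, 32, 64)
        assert f2.shape == (1, 16, 16, 64)

    def test_identity_kernel_passthrough(self):
        # center-1 kernel, zero bias, ReLU on nonnegative input: identity at
        # both the full and the half scale
        conv = nn.Conv2d(1, 1, 3)
        conv.weight.data[...] = 0
        conv.weight.data[1, 1, 0, 0] = 1.0
        conv.bias.data[...] = 0
        x = np.arange(16, dtype=np.float64).reshape(1, 4, 4, 1)
        for scale in (x, x[:, ::2, ::2, :]):
            out = conv(nn.Tensor(scale)).relu().data
            assert np.array_equal(out, scale)

    def test_single_weight_store(self):
        model = LiteMRINet(ModelConfig(input_size=64), seed=0)
        enc_params = [n for n, _ in model.named_parameters() if n.startswith("encoder.")]
        assert len(enc_params) > 0
        assert model._encoders is None  # exactly one store

    def test_perturbing_one_weight_changes_all_scales(self, rng):
        model = LiteMRINet(ModelConfig(input_size=64), seed=0).eval()
        img = rng.random((1, 64, 64, 3), dtype=np.float32)
        pyr = build_pyramid(img)
        with nn.no_grad():
            before = [f.data.copy() for f in model.encode(pyr)]
            model.encoder.layers[0].conv.weight.data[0, 0, 0, 0] += 0.5
            after = [f.data for f in model.encode(pyr)]
        for b, a in zip(before, after):
            assert not np.allclose(b, a)


class TestStagesAndDecoder:
    def test_transformer_stage_shapes(self, rng):
        cfg = ModelConfig(input_size=256)
        model = LiteMRINet(cfg, seed=0).eval()
        with nn.no_grad():
            f = nn.Tensor(rng.random((1, 64, 64, 64), dtype=np.float32))
            t1 = model.stage1(f)
            assert t1.shape == (1, 32, 32, 64)
            t2 = model.stage2(t1)
            assert t2.shape == (1, 16, 16, 64)

    def test_odd_side_raises(self, rng):
        model = LiteMRINet(ModelConfig(input_size=64), seed=0)
        with pytest.raises(DimensionError):
            model.stage1(nn.Tensor(rng.random((1, 5, 5, 64))))

    def test_decoder_mismatched_skip_names_stage(self, tiny_model_config, rng):
        model = LiteMRINet(tiny_model_config, seed=0)
        c = tiny_model_config.base_channels
        bottom = nn.Tensor(rng.random((1, 1, 1, c), dtype=np.float32))
        bad_skip = nn.Tensor(rng.random((1, 5, 5, c), dtype=np.float32))
        with pytest.raises(DimensionError, match="s16->s8"):
            model.decoder.stages[0](bottom, bad_skip)

    def test_full_forward_logits_shape(self, rng):
        model = LiteMRINet(ModelConfig(input_size=64), seed=0).eval()
        img = rng.random((64, 64, 3), dtype=np.float32)
        with nn.no_grad():
            out = model(img)
        assert out.shape == (64, 64, 2)

    def test_inference_determinism(self, rng):
        model = LiteMRINet(ModelConfig(input_size=64), seed=1).eval()
        img = rng.random((64, 64, 3), dtype=np.float32)
        with nn.no_grad():
            a = model(img).data
            b = model(img).data
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("variant", ["cnn_only", "transformer_cnn",
                                         "transformer_sharecnn"])
    def test_all_variants_share_output_contract(self, variant, rng):
        cfg = ModelConfig(input_size=64, variant=variant)
        model = LiteMRINet(cfg, seed=0).eval()
        with nn.no_grad():
            out = model(rng.random((64, 64, 3), dtype=np.float32))
        assert out.shape == (64, 64, 2)


class TestParameterCounting:
    def test_single_conv_closed_form(self):
        conv = nn.Conv2d(3, 64, 3)
        assert sum(p.size for p in conv.parameters()) == 3 * 64 * 9 + 64 == 1792

    def test_shared_encoder_closed_form(self):
        model = LiteMRINet(ModelConfig(), seed=0)
        # 1792 + 9 * 36928 (64->64 3x3 + bias) + 10 * 128 (BN affine pairs)
        assert model.shared_encoder_parameter_count() == 1792 + 9 * 36928 + 10 * 128
        assert model.shared_encoder_parameter_count() == 335424

    def test_default_under_budget(self):
        assert count_trainable_parameters(ModelConfig()) <= 1_610_000

    def test_unshared_minus_shared_is_two_encoder_copies(self):
        shared = count_trainable_parameters(build_variant("transformer_sharecnn"))
        unshared = count_trainable_parameters(build_variant("transformer_cnn"))
        assert unshared - shared == 2 * 335424

    def test_size_agnostic_without_positional_embeddings(self):
        c64 = ModelConfig(input_size=64, use_positional_embedding=False)
        c256 = ModelConfig(input_size=256, use_positional_embedding=False)
        assert count_trainable_parameters(c64) == count_trainable_parameters(c256)

    def test_counting_independent_of_batch(self, rng):
        model = LiteMRINet(ModelConfig(input_size=64), seed=0)
        n0 = model.num_parameters()
        model.eval()
        with nn.no_grad():
            model(rng.random((2, 64, 64, 3), dtype=np.float32))
        assert model.num_parameters() == n0


class TestVariants:
    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ConfigurationError, match="transformer_sharecnn"):
            build_variant("nope")

    def test_cnn_only_has_no_attention_parameters(self):
        model = LiteMRINet(build_variant("cnn_only"), seed=0)
        names = [n for n, _ in model.named_parameters()]
        assert not any("attn" in n or "qkv" in n for n in names)

    def test_transformer_cnn_has_three_stores(self):
        model = LiteMRINet(ModelConfig(input_size=64, variant="transformer_cnn"),
                           seed=0)
        assert model.encoder is None
        assert len(model._encoders) == 3


class TestGradientSharing:
    def test_one_step_on_one_scale_changes_all_scales(self, rng):
        cfg = ModelConfig(input_size=32, base_channels=8, shared_depth=2,
                          transformer_depths=(1, 1), attention_heads=2)
        model = LiteMRINet(cfg, seed=0).eval()
        img = rng.random((1, 32, 32, 3), dtype=np.float32)
        pyr = build_pyramid(img)
        with nn.no_grad():
            before = [f.data.copy() for f in model.encode(pyr)]
        loss = (model.encode(pyr)[1] ** 2).sum()  # loss from half scale only
        model.zero_grad()
        loss.backward()
        opt = nn.Adam(model.parameters(), lr=1e-2)
        opt.step()
        with nn.no_grad():
            after = [f.data for f in model.encode(pyr)]
        for b, a in zip(before, after):
            assert not np.allclose(b, a)


class TestConfigAndCheckpoint:
    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(input_size=100)
        with pytest.raises(ConfigurationError):
            ModelConfig(attention_heads=7)
        with pytest.raises(ConfigurationError):
            ModelConfig(variant="bogus")

    def test_config_file_roundtrip(self, tmp_path, tiny_model_config):
        path = tmp_path / "model.yaml"
        tiny_model_config.to_file(path)
        loaded = ModelConfig.from_file(path)
        assert loaded == tiny_model_config

    def test_checkpoint_roundtrip_is_self_describing(self, tmp_path,
                                                     tiny_model_config, rng):
        model = LiteMRINet(tiny_model_config, seed=5)
        img = rng.random((16, 16, 3), dtype=np.float32)
        pred = model.predict(img)
        path = save_checkpoint(model, tmp_path / "ckpt")
        restored = load_checkpoint(path)
        assert restored.config == tiny_model_config
        assert np.array_equal(restored.predict(img), pred)
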