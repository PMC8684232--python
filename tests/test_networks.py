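"""Architecture contracts of the encoder, context extractors and heads,
plus a finite-difference check of the hand-written backward passes."""

import numpy as np
import pytest

import lesionrefine as lr
from lesionrefine import nn
from lesionrefine.networks import ModelConfig, TwoStageModel


def tiny_config(context="aspp", dtype="float64"):
    return ModelConfig(crop_size=32, widths=(3, 4, 5, 6), ctx_channels=6,
                       c_low_reduced=3, c_high_reduced=4, context=context,
                       seed=1, dtype=dtype)


class TestShapesAndDeterminism:
    @pytest.mark.parametrize("crop", [96, 256])
    def test_feature_strides_and_output_size(self, crop):
        m = TwoStageModel(ModelConfig(crop_size=crop))
        x = m.preprocess(np.zeros((1, crop, crop, 3), np.uint8))
        b, ctx = m.sbox_forward(x)
        assert b.shape == (1, 1, crop, crop)
        assert ctx.shape[2:] == (crop // 16, crop // 16)
        c = m.click_forward(ctx, np.zeros((1, 2, crop, crop)))
        assert c.shape == (1, 1, crop, crop)
        assert np.isfinite(b).all() and np.isfinite(c).all()

    def test_low_level_features_are_stride_4(self):
        m = TwoStageModel(ModelConfig(crop_size=96))
        x = m.preprocess(np.zeros((1, 96, 96, 3), np.uint8))
        low, high = m.encoder.forward(x)
        assert low.shape[2:] == (24, 24) and high.shape[2:] == (6, 6)

    def test_same_seed_gives_identical_parameters(self):
        a = TwoStageModel(ModelConfig(seed=42))
        b = TwoStageModel(ModelConfig(seed=42))
        for pa, pb in zip(a.params_sbox() + a.params_click(),
                          b.params_sbox() + b.params_click()):
            assert np.array_equal(pa.value, pb.value)

    def test_inference_is_deterministic(self, untrained_model, rng):
        img = rng.integers(0, 255, size=(2, 96, 96, 3)).astype(np.uint8)
        x = untrained_model.preprocess(img)
        b1, _ = untrained_model.sbox_forward(x)
        b2, _ = untrained_model.sbox_forward(x)
        assert np.array_equal(b1, b2)

    def test_default_desk_config_under_100k_parameters(self):
        for v in lr.CONTEXT_VARIANTS:
            assert TwoStageModel(ModelConfig(context=v)).param_count() < 100_000


class TestContextVariants:
    def test_variants_are_interchangeable_shapes(self, rng):
        x = rng.integers(0, 255, size=(1, 96, 96, 3)).astype(np.uint8)
        shapes = set()
        for v in lr.CONTEXT_VARIANTS:
            m = TwoStageModel(ModelConfig(context=v, seed=5))
            _, ctx = m.sbox_forward(m.preprocess(x))
            shapes.add(ctx.shape)
        assert len(shapes) == 1

    def test_psp_level_one_is_global_average(self, rng):
        pool = nn.AdaptiveAvgPool((6, 6), (1, 1))
        x = rng.standard_normal((1, 3, 6, 6))
        assert np.allclose(pool.forward(x)[0, :, 0, 0], x.mean(axis=(2, 3))[0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(context="transformer")


class TestGradients:
    """Central-difference validation of the backward passes (float64, with
    biases randomized away from the ReLU kinks)."""

    @pytest.mark.parametrize("context", lr.CONTEXT_VARIANTS)
    def test_sbox_path_gradients(self, context):
        m = TwoStageModel(tiny_config(context))
        g = np.random.default_rng(0)
        for p in m.params_sbox():
            p.value += g.standard_normal(p.value.shape) * 0.05
        x = g.standard_normal((2, 3, 32, 32))
        t = (g.uniform(size=(2, 1, 32, 32)) > 0.5).astype(float)

        def loss():
            b, _ = m.sbox_forward(x)
            return nn.bce_with_logits(b, t)[0]

        b, _ = m.sbox_forward(x)
        _, db = nn.bce_with_logits(b, t)
        for p in m.params_sbox():
            p.zero_grad()
        m.sbox_backward(db)
        for p in m.params_sbox():
            flat = p.value.ravel()
            for k in g.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-5, flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                num, ana = (lp - lm) / (2 * eps), p.grad.ravel()[k]
                assert abs(num - ana) <= 1e-6 + 1e-3 * (abs(num) + abs(ana))

    def test_click_path_gradients(self):
        m = TwoStageModel(tiny_config())
        g = np.random.default_rng(1)
        for p in m.params_sbox() + m.params_click():
            p.value += g.standard_normal(p.value.shape) * 0.05
        x = g.standard_normal((2, 3, 32, 32))
        t = (g.uniform(size=(2, 1, 32, 32)) > 0.5).astype(float)
        gd = g.uniform(size=(2, 2, 32, 32))
        w = g.uniform(size=(2, 1, 32, 32))
        b, ctx = m.sbox_forward(x)

        def loss():
            c = m.click_forward(ctx, gd)
            return nn.bce_with_logits(w * c + b, t)[0]

        c = m.click_forward(ctx, gd)
        _, df = nn.bce_with_logits(w * c + b, t)
        for p in m.params_click():
            p.zero_grad()
        m.click_backward(df * w)
        for p in m.params_click():
            flat = p.value.ravel()
            for k in g.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-5, flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                num, ana = (lp - lm) / (2 * eps), p.grad.ravel()[k]
                assert abs(num - ana) <= 1e-6 + 1e-3 * (abs(num) + abs(ana))


class TestClickHeadBehaviour:
    def test_polarity_swap_changes_trained_output(self, trained_model, guidance_cfg):
        """For a trained refinement head, positive and negative guidance are
        information-bearing: swapping the channels must change the logits."""
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(1, 96, 96, 3)).astype(np.uint8)
        _, ctx = trained_model.sbox_forward(trained_model.preprocess(img))
        cs = lr.ClickSet([lr.Click(30, 30, "positive")], [lr.Click(70, 70, "negative")])
        gm = lr.encode_clicks(cs, guidance_cfg.radius, (96, 96))
        c1 = trained_model.click_forward(ctx, gm.stacked()[None])
        c2 = trained_model.click_forward(ctx, gm.stacked()[None][:, ::-1])
        assert not np.allclose(c1, c2)

    def test_zero_guidance_is_well_defined(self, untrained_model, rng):
        img = rng.integers(0, 255, size=(1, 96, 96, 3)).astype(np.uint8)
        _, ctx = untrained_model.sbox_forward(untrained_model.preprocess(img))
        c = untrained_model.click_forward(ctx, np.zeros((1, 2, 96, 96)))
        assert np.isfinite(c).all()


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path, untrained_model, rng):
        path = tmp_path / "model.npz"
        untrained_model.save(path)
        loaded = lr.TwoStageModel.load(path)
        img = rng.integers(0, 255, size=(1, 96, 96, 3)).astype(np.uint8)
        x = untrained_model.preprocess(img)
        b1, _ = untrained_model.sbox_forward(x)
        b2, _ = loaded.sbox_forward(x)
        assert np.array_equal(b1, b2)
        assert loaded.cfg == untrained_model.cfg
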