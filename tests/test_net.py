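"""Attention network: oracle equivalence of the attention pooling, encoder
shapes, head wiring, orientation decision, augmentation ranges, gradients,
training behavior and checkpoints."""

import math

import numpy as np
import pytest

from sonodescribe.errors import ConfigurationError, ModelStateError
from sonodescribe.net import (
    AttentionState,
    AugmentRanges,
    DescriptorNet,
    NetConfig,
    apply_augment,
    attend,
    augment,
    decide_orientation,
    encode,
    heads_forward,
    load_model,
    predict,
    sample_augment_params,
    save_model,
    tiny_config,
    train,
)
from sonodescribe.phantom import load_image, render_phantom, sample_phantom_spec
from sonodescribe.roi import standardize_roi
from sonodescribe.roi_types import BoundingBox


def brute_force_attention(F, V):
    """Literal loop translation of the attention equations (softmax over
    tanh scores, context = weighted average of feature-space rows)."""
    g2, d = F.shape
    scores = [math.tanh(sum(V[k] * F[i, k] for k in range(d))) for i in range(g2)]
    exps = [math.exp(s) for s in scores]
    total = sum(exps)
    a = [e / total for e in exps]
    c = [sum(a[i] * F[i, k] for i in range(g2)) for k in range(d)]
    return np.array(a), np.array(c)


class TestAttention:
    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            g2 = int(rng.integers(2, 10))
            d = int(rng.integers(1, 9))
            F = rng.normal(size=(g2, d)) * 3
            V = rng.normal(size=d)
            state = attend(F, V)
            a_ref, c_ref = brute_force_attention(F, V)
            np.testing.assert_allclose(state.a, a_ref, atol=1e-6)
            np.testing.assert_allclose(state.c, c_ref, atol=1e-6)
            assert state.a.min() >= 0
            assert abs(state.a.sum() - 1.0) < 1e-6

    def test_zero_scorer_gives_uniform_weights_and_mean_context(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(16, 8))
        state = attend(F, np.zeros(8))
        np.testing.assert_allclose(state.a, np.full(16, 1 / 16), atol=1e-12)
        np.testing.assert_allclose(state.c, F.mean(axis=0), atol=1e-12)

    def test_toy_four_row_softmax(self):
        # One row scores tanh=+1 (saturated), the rest -1: a = softmax([1,-1,-1,-1])
        F = np.array([[50.0], [-50.0], [-50.0], [-50.0]])
        V = np.array([1.0])
        state = attend(F, V)
        expected = np.exp([1.0, -1, -1, -1])
        expected /= expected.sum()
        np.testing.assert_allclose(state.a, expected, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            attend(np.ones((4, 3)), np.ones(5))


class TestEncoder:
    def test_tiny_config_feature_space_shape(self):
        cfg = tiny_config()
        model = DescriptorNet(cfg)
        assert (cfg.grid, cfg.d) == (6, 64)
        roi = np.zeros((96, 96), dtype=np.float32)
        F = encode(roi, model)
        assert F.shape == (36, 64)
        assert np.isfinite(F).all()  # batch-norm epsilon guards zero input

    def test_downsampling_arithmetic_for_custom_config(self):
        # a 128-pixel input with downsampling 16 and d=64 yields a 64x64 matrix
        cfg = tiny_config(input_size=128)
        F = encode(np.zeros((128, 128), dtype=np.float32), DescriptorNet(cfg))
        assert F.shape == (64, 64)

    def test_default_config_reproduces_196x512(self):
        model = DescriptorNet(NetConfig())
        F = encode(np.zeros((450, 450), dtype=np.float32), model)
        assert F.shape == (196, 512)

    def test_wrong_input_size_rejected(self):
        model = DescriptorNet(tiny_config())
        with pytest.raises(ConfigurationError):
            encode(np.zeros((100, 100), dtype=np.float32), model)


class TestHeads:
    def test_probability_outputs_normalized(self):
        model = DescriptorNet(tiny_config())
        state = attend(np.random.default_rng(0).normal(size=(36, 64)),
                       model.att.params["V"])
        out = heads_forward(state, model)
        for name in ("shape", "margin", "echogenicity", "posterior", "halo"):
            assert abs(sum(out.descriptors[name].values()) - 1.0) < 1e-6
        assert all(0 <= v <= 1 for v in out.descriptors["orientation"].values())
        assert abs(sum(out.suggestivity.values()) - 1.0) < 1e-6
        assert abs(sum(out.malignancy.values()) - 1.0) < 1e-6

    def test_suggestivity_input_width(self):
        model = DescriptorNet(tiny_config())
        # d + sum of the six head cardinalities (3+4+2+5+3+2 = 19)
        assert model.sugg_head.params["W"].shape[1] == 64 + 19
        assert model.mal_head.params["W"].shape[1] == 64 + 19 + 4

    def test_descriptor_outputs_and_context_both_feed_suggestivity(self):
        """Zeroing either input block of the suggestivity head changes its
        logits: the dependency wiring exists for both."""
        model = DescriptorNet(tiny_config())
        rng = np.random.default_rng(3)
        c = rng.normal(size=(1, 64)).astype(np.float32)
        probs = rng.uniform(0.1, 0.9, size=(1, 19)).astype(np.float32)
        full = model.sugg_head.forward(
            np.concatenate([probs, c], axis=1), train=False)
        no_desc = model.sugg_head.forward(
            np.concatenate([np.zeros_like(probs), c], axis=1), train=False)
        no_ctx = model.sugg_head.forward(
            np.concatenate([probs, np.zeros_like(c)], axis=1), train=False)
        assert not np.allclose(full, no_desc)
        assert not np.allclose(full, no_ctx)


class TestOrientationDecision:
    @pytest.mark.parametrize("values,expected", [
        ((0.2, 0.25), "none"),        # both below the 0.3 threshold
        ((0.9, 0.1), "parallel"),
        ((0.1, 0.9), "anti_parallel"),
        ((0.6, 0.5), "parallel"),     # argmax above threshold
        ((0.5, 0.5), "parallel"),     # tie broken toward parallel
        ((0.29, 0.31), "anti_parallel"),
        ((0.0, 0.0), "none"),
    ])
    def test_threshold_and_argmax_semantics(self, values, expected):
        assert decide_orientation(values, tau=0.3) == expected


class TestAugment:
    def test_identity_ranges_reproduce_standardize(self):
        spec = sample_phantom_spec(5)
        img, box = render_phantom(spec)
        rng = np.random.default_rng(0)
        roi = augment(img, box, rng, AugmentRanges.identity(), target=96)
        ref = standardize_roi(img, box, target=96)
        np.testing.assert_allclose(roi.pixels, ref.pixels, atol=1e-4)

    def test_sampled_parameters_stay_in_stated_intervals(self):
        rng = np.random.default_rng(7)
        ranges = AugmentRanges()
        for _ in range(1000):
            p = sample_augment_params(rng, ranges)
            assert -0.1 <= p.dv <= 0.25
            assert -0.1 <= p.dh <= 0.15
            assert -0.3 <= p.zoom <= 0.3
            assert 0.8 <= p.contrast <= 1.2
            assert -25 <= p.brightness <= 25
            assert abs(p.rotation) <= 0.05 * 2 * math.pi

    def test_fixed_seed_reproduces_pixels(self):
        spec = sample_phantom_spec(6)
        img, box = render_phantom(spec)
        roi1 = augment(img, box, np.random.default_rng(42), target=96)
        roi2 = augment(img, box, np.random.default_rng(42), target=96)
        np.testing.assert_array_equal(roi1.pixels, roi2.pixels)


class TestGradients:
    def test_numerical_gradient_check(self):
        """Central-difference check of the full loss gradient on a micro
        topology (float64) for a sample of parameters in every layer kind."""
        cfg = NetConfig(name="micro", input_size=16, stem_channels=3,
                        stages=((4, 1), (6, 1)), dtype="float64", seed=0)
        model = DescriptorNet(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 1, 16, 16))
        labels = {
            "shape": np.array([0, 1, 2]), "margin": np.array([1, 0, 3]),
            "echogenicity": np.array([0, 2, 4]), "posterior": np.array([1, 0, 2]),
            "halo": np.array([0, 1, 0]), "suggestivity": np.array([3, 0, 2]),
            "malignancy": np.array([0, 1, 0]),
            "orientation_targets": np.array([[1., 0.], [0., 1.], [0., 0.]]),
            "orientation_mask": np.array([1., 1., 1.]),
        }

        def loss_of():
            # forward-only loss (no BN-statistics update side effects matter:
            # train-mode forward recomputes batch stats deterministically)
            return model.loss_and_backward(x, labels)["total"]

        model.loss_and_backward(x, labels)
        grads = {(i, k): layer.grads[k].copy()
                 for i, layer in enumerate(model.layers())
                 for k in layer.params}
        h = 1e-6
        checked = 0
        for i, layer in enumerate(model.layers()):
            for k, p in layer.params.items():
                flat = p.reshape(-1)
                for j in np.linspace(0, flat.size - 1, 3).astype(int):
                    orig = flat[j]
                    flat[j] = orig + h
                    lp = loss_of()
                    flat[j] = orig - h
                    lm = loss_of()
                    flat[j] = orig
                    num = (lp - lm) / (2 * h)
                    ana = grads[(i, k)].reshape(-1)[j]
                    assert num == pytest.approx(ana, rel=2e-3, abs=1e-7), \
                        f"layer {i} param {k}[{j}]"
                    checked += 1
        assert checked >= 30


class TestTraining:
    def test_overfit_one_batch(self, overfit_model):
        _, _, history = overfit_model
        assert history[-1]["total"] < 0.2 * history[0]["total"]

    def test_training_is_deterministic(self, tmp_path):
        from sonodescribe.phantom import make_dataset
        manifest = make_dataset(6, seed=2, out_dir=tmp_path,
                                extra_info_fraction=0.0)
        cfg = tiny_config(epochs=3, batch_size=6, seed=5)
        _, h1 = train(manifest, cfg)
        _, h2 = train(manifest, cfg)
        assert h1 == h2

    def test_attention_weights_normalized_after_training(self, overfit_model):
        manifest, model, _ = overfit_model
        rec = manifest["records"][0]
        roi = standardize_roi(load_image(manifest, rec),
                              BoundingBox(*rec["box"]),
                              target=model.config.input_size)
        out = model.forward(roi.pixels[None, None] / 255.0 - 0.5, train=False)
        assert out["a"].min() >= 0
        assert out["a"].sum(axis=1) == pytest.approx(1.0, abs=1e-6)

    def test_predict_requires_trained_model(self):
        model = DescriptorNet(tiny_config())
        roi = standardize_roi(np.ones((150, 150), dtype=np.uint8),
                              BoundingBox(0, 0, 96, 96), target=96)
        with pytest.raises(ModelStateError):
            predict(model, roi)

    def test_predict_outputs_valid_descriptors(self, overfit_model):
        manifest, model, _ = overfit_model
        from sonodescribe.vocab import DEFAULT_VOCABULARIES as V
        for rec in manifest["records"][:4]:
            roi = standardize_roi(load_image(manifest, rec),
                                  BoundingBox(*rec["box"]),
                                  target=model.config.input_size)
            dset, p_mal, amap = predict(model, roi)
            for name, value in dset.as_dict().items():
                assert value in V.descriptor_values(name)
            assert 0.0 <= p_mal <= 1.0
            assert amap.shape == roi.pixels.shape

    def test_checkpoint_roundtrip(self, overfit_model, tmp_path):
        manifest, model, _ = overfit_model
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        rec = manifest["records"][0]
        roi = standardize_roi(load_image(manifest, rec),
                              BoundingBox(*rec["box"]),
                              target=model.config.input_size)
        d1, p1, _ = predict(model, roi)
        d2, p2, _ = predict(loaded, roi)
        assert d1.as_dict() == d2.as_dict()
        assert p1 == pytest.approx(p2)
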