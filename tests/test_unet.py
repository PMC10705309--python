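import numpy as np
import pytest

from rfseg.unet import (TrainedModel, UNet, UNetConfig, build_unet,
                        predict_volume, sigmoid, softmax)


def _tiny(head="sigmoid", out_channels=3, dims=2, in_channels=4):
    return UNetConfig(dims=dims, in_channels=in_channels, out_channels=out_channels,
                      depth=2, base_channels=4, head=head)


class TestConfig:
    def test_paper_scale_widths(self):
        """Default 2D config: encoder 64/128/256/512, bottleneck 1024."""
        cfg = UNetConfig()
        assert cfg.encoder_widths == (64, 128, 256, 512)
        assert cfg.bottleneck_channels == 1024

    def test_for_approach_head_coupling(self):
        assert UNetConfig.for_approach("multi_class").head == "softmax"
        assert UNetConfig.for_approach("multi_class").out_channels == 4
        assert UNetConfig.for_approach("multi_label").head == "sigmoid"
        assert UNetConfig.for_approach("multi_label").out_channels == 3
        assert UNetConfig.for_approach("binary").out_channels == 1

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            UNetConfig(dims=4)
        with pytest.raises(ValueError):
            UNetConfig(head="relu")


class TestForward:
    def test_output_grid_matches_input(self, rng):
        net = build_unet(_tiny(), seed=0)
        x = rng.normal(size=(2, 4, 16, 24)).astype(np.float32)
        assert net.forward(x).shape == (2, 3, 16, 24)

    def test_softmax_head_sums_to_one(self, rng):
        net = build_unet(_tiny(head="softmax", out_channels=4), seed=0)
        x = rng.normal(size=(1, 4, 16, 16)).astype(np.float32)
        p = net.forward(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_sigmoid_head_in_open_interval(self, rng):
        net = build_unet(_tiny(), seed=0)
        x = rng.normal(size=(1, 4, 16, 16)).astype(np.float32)
        p = net.forward(x)
        assert np.all(p > 0) and np.all(p < 1)

    def test_indivisible_spatial_dims_rejected(self, rng):
        net = build_unet(_tiny(), seed=0)
        with pytest.raises(ValueError, match="2\\^depth"):
            net.forward(rng.normal(size=(1, 4, 15, 16)).astype(np.float32))

    def test_3d_variant_shape_contract(self, rng):
        net = build_unet(_tiny(dims=3), seed=0)
        x = rng.normal(size=(1, 4, 8, 12, 8)).astype(np.float32)
        assert net.forward(x).shape == (1, 3, 8, 12, 8)

    def test_inference_is_deterministic(self, rng):
        net = build_unet(_tiny(), seed=0)
        x = rng.normal(size=(2, 4, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))


class TestGradients:
    # per-layer backward passes are FD-checked rigorously in test_nn_layers;
    # the composed ReLU/max-pool network is non-smooth, so here the whole net
    # is checked functionally: finite gradients everywhere and steady descent.
    @pytest.mark.parametrize("dims,shape", [(2, (4, 2, 8, 8)), (3, (2, 2, 4, 4, 4))])
    def test_gradient_steps_reduce_loss(self, dims, shape, rng):
        from rfseg.nn import Adam

        cfg = UNetConfig(dims=dims, in_channels=2, out_channels=2, depth=2,
                         base_channels=4, head="sigmoid")
        net = UNet(cfg, seed=1)
        x = rng.normal(size=shape).astype(np.float32)
        # a learnable pixelwise target: both channels flag where input ch0 > 0
        y = np.repeat((x[:, :1] > 0).astype(np.float32), 2, axis=1)
        opt = Adam(net.parameters(), lr=1e-2)

        def bce(p):
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            return float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))

        losses = []
        for _ in range(150):
            p = sigmoid(net.forward_logits(x, train=True))
            losses.append(bce(p))
            opt.zero_grad()
            net.backward(((p - y) / p.size).astype(np.float32))
            for par in net.parameters():
                assert np.all(np.isfinite(par.grad))
            opt.step()
        assert losses[-1] < 0.25 * losses[0]


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = _tiny()
        net = build_unet(cfg, seed=2)
        model = TrainedModel(config=cfg, approach="multi_label",
                             normalization_id="zscore", network=net,
                             training_log=[{"epoch": 0, "train_loss": 0.5}],
                             norm_fit_ids=("p1", "p2"), seed=2)
        model.save(tmp_path / "run")
        back = TrainedModel.load(tmp_path / "run")
        x = rng.normal(size=(1, 4, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.network.forward(x))
        assert back.norm_fit_ids == ("p1", "p2")
        assert back.training_log[0]["train_loss"] == 0.5


class TestPredictVolume:
    @pytest.fixture
    def normalized(self, tiny_patient):
        from rfseg.training import fit_normalizer

        return fit_normalizer("zscore", []).apply(tiny_patient.volume)

    def test_probability_volume_shape_and_range(self, normalized):
        cfg = _tiny()
        model = TrainedModel(config=cfg, approach="multi_label",
                             normalization_id="zscore",
                             network=build_unet(cfg, seed=0))
        probs = predict_volume(model, normalized)
        assert probs.shape == (3,) + normalized.shape
        assert np.all((probs > 0) & (probs < 1))

    def test_multiclass_probabilities_sum_to_one(self, normalized):
        cfg = _tiny(head="softmax", out_channels=4)
        model = TrainedModel(config=cfg, approach="multi_class",
                             normalization_id="zscore",
                             network=build_unet(cfg, seed=0))
        probs = predict_volume(model, normalized)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_normalization_mismatch_rejected(self, tiny_patient):
        cfg = _tiny()
        model = TrainedModel(config=cfg, approach="multi_label",
                             normalization_id="nyul",
                             network=build_unet(cfg, seed=0))
        with pytest.raises(ValueError, match="normalized with"):
            predict_volume(model, tiny_patient.volume, normalization_id="zscore")

    def test_3d_inference_pads_and_crops(self, tiny_patient):
        cfg = UNetConfig(dims=3, in_channels=4, out_channels=1, depth=2,
                         base_channels=2, head="sigmoid")
        model = TrainedModel(config=cfg, approach="binary", normalization_id="zscore",
                             network=build_unet(cfg, seed=0), region="tc")
        probs = predict_volume(model, tiny_patient.volume)
        assert probs.shape == (1,) + tiny_patient.volume.shape
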