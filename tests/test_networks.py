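"""Network construction, loss wiring, training loop and checkpoints.

Training tests use a tiny 3-stage net on an (8, 16, 8) grid so the whole
module runs in seconds.
"""

import numpy as np
import pytest

import spinegraph as sg
from spinegraph.networks import (Checkpoint, CoarseNetConfig, RefineNetConfig,
                                 TrainConfig, build_coarse_net, build_refine_net,
                                 segmentation_loss, train_model)

TINY = dict(encoder_stages=3, base_channels=2, classes=6)


def tiny_graph():
    return sg.full_graph(["L2", "L3", "L4"])  # 5 structures + background = 6


def tiny_sample(seed=0):
    rng = np.random.default_rng(seed)
    vol = rng.standard_normal((8, 16, 8)).astype(np.float32)
    lab = np.zeros((8, 16, 8), dtype=np.int16)
    for k in range(1, 6):
        lab[:, 3 * k - 3:3 * k, :] = k
    return vol, lab


class TestBuild:
    def test_default_first_stage_has_32_channels(self):
        net = build_coarse_net(CoarseNetConfig(), seed=0)
        assert net.backbone.chans[0] == 32
        assert net.backbone.stem.conv.w.data.shape[0] == 32
        assert net.config.encoder_stages == 4

    def test_softmax_contract_on_dummy_volume(self):
        net = build_coarse_net(CoarseNetConfig(base_channels=4), seed=0)
        probs = net.predict_proba(np.random.default_rng(0)
                                  .standard_normal((16, 64, 32)))
        assert probs.shape == (20, 16, 64, 32)
        assert np.abs(probs.sum(axis=0) - 1.0).max() < 1e-6

    def test_ablation_differs_only_by_semantic_parameters(self):
        cfg = dict(TINY)
        gcsn = build_coarse_net(CoarseNetConfig(**cfg), graph=tiny_graph(), seed=0)
        res = build_coarse_net(CoarseNetConfig(use_semantic_block=False, **cfg),
                               graph=tiny_graph(), seed=0)
        names_g = {n for n, _ in gcsn.params()}
        names_r = {n for n, _ in res.params()}
        extra = names_g - names_r
        assert names_r < names_g
        assert all(("gcn" in n) or ("proj" in n) or ("assign" in n)
                   for n in extra)
        n_extra = sum(t.data.size for n, t in gcsn.params() if n in extra)
        total_g = sum(t.data.size for _, t in gcsn.params())
        total_r = sum(t.data.size for _, t in res.params())
        assert total_g - total_r == n_extra

    def test_indivisible_input_error_names_padding(self):
        net = build_coarse_net(CoarseNetConfig(base_channels=2), seed=0)
        with pytest.raises(ValueError, match="pad to"):
            net.predict_proba(np.zeros((10, 16, 8)))

    def test_graph_class_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="nodes"):
            build_coarse_net(CoarseNetConfig(classes=7), graph=tiny_graph())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CoarseNetConfig(encoder_stages=1)
        with pytest.raises(ValueError):
            TrainConfig(dice_weight=0.0, ce_weight=0.0)


class TestRefineNet:
    def test_output_shape_and_normalization(self):
        cfg = RefineNetConfig(encoder_stages=4, base_channels=2,
                              in_channels=7, classes=6)
        net = build_refine_net(cfg, seed=0)
        fused = np.zeros((7, 32, 16), dtype=np.float32)
        fused[1] = 1.0  # one-hot probability channel on a zero image
        probs = net.predict_proba(fused)
        assert probs.shape == (6, 32, 16)
        assert np.isfinite(probs).all()
        assert np.abs(probs.sum(axis=0) - 1.0).max() < 1e-6

    def test_channel_mismatch_rejected(self):
        cfg = RefineNetConfig(encoder_stages=3, base_channels=2,
                              in_channels=7, classes=6)
        net = build_refine_net(cfg, seed=0)
        with pytest.raises(ValueError, match="channels"):
            net.predict_proba(np.zeros((5, 16, 16), dtype=np.float32))

    def test_doubling_base_channels_quadruples_conv_parameters(self):
        def conv_params(base):
            cfg = RefineNetConfig(encoder_stages=3, base_channels=base,
                                  in_channels=3, classes=4)
            net = build_refine_net(cfg, seed=0)
            return sum(t.data.size for n, t in net.params()
                       if n.endswith(".w") and "head" not in n and "stem" not in n)
        ratio = conv_params(8) / conv_params(4)
        assert 3.5 < ratio < 4.1


class TestLossWiring:
    def test_aux_weights_enter_linearly(self):
        rng = np.random.default_rng(0)
        target = rng.integers(0, 3, (4, 4))
        main = np.full((3, 4, 4), 1 / 3)
        aux = np.full((3, 2, 2), 1 / 3)
        base = segmentation_loss(main, [], target)
        with_aux = segmentation_loss(main, [aux], target, aux_weights=(0.5,))
        aux_only = segmentation_loss(aux, [], target[::2, ::2])
        assert np.isclose(with_aux, base + 0.5 * aux_only, atol=1e-12)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(4), size=(5, 5)).transpose(2, 0, 1)
        target = rng.integers(0, 4, (5, 5))
        assert segmentation_loss(probs, [], target) >= 0.0


class TestTraining:
    def test_overfit_single_sample_descends(self):
        net = build_coarse_net(CoarseNetConfig(**TINY), graph=tiny_graph(), seed=0)
        cfg = TrainConfig(iterations=50, seed=0)
        ckpt = train_model(net, [tiny_sample()], cfg)
        assert len(ckpt.history) == 50
        assert ckpt.history[-1] < ckpt.history[0]

    def test_loss_halves_after_200_iterations(self):
        net = build_coarse_net(CoarseNetConfig(**TINY), graph=tiny_graph(), seed=1)
        cfg = TrainConfig(iterations=200, seed=1)
        ckpt = train_model(net, [tiny_sample()], cfg)
        assert ckpt.history[-1] < 0.5 * ckpt.history[0]

    def test_same_seed_reproduces_history(self):
        h = []
        for _ in range(2):
            net = build_coarse_net(CoarseNetConfig(**TINY), graph=tiny_graph(),
                                   seed=2)
            ckpt = train_model(net, [tiny_sample()],
                               TrainConfig(iterations=10, seed=3))
            h.append(ckpt.history)
        assert h[0] == h[1]

    def test_zero_learning_rate_keeps_loss_constant(self):
        net = build_coarse_net(CoarseNetConfig(**TINY), graph=tiny_graph(), seed=0)
        ckpt = train_model(net, [tiny_sample()],
                           TrainConfig(iterations=5, learning_rate=0.0, seed=0))
        assert np.allclose(ckpt.history, ckpt.history[0])

    def test_checkpoint_round_trip_reproduces_predictions(self, tmp_path):
        net = build_coarse_net(CoarseNetConfig(**TINY), graph=tiny_graph(), seed=0)
        ckpt = train_model(net, [tiny_sample()], TrainConfig(iterations=5, seed=0))
        ckpt.save(tmp_path / "model.ckpt")
        back = Checkpoint.load(tmp_path / "model.ckpt")
        net2 = back.build_net(graph=tiny_graph())
        vol, _ = tiny_sample()
        assert np.array_equal(net.predict_proba(vol), net2.predict_proba(vol))
        assert back.history == ckpt.history


def test_ground_truth_assignment_training_descends():
    net = build_coarse_net(CoarseNetConfig(**TINY), graph=tiny_graph(), seed=0)
    cfg = TrainConfig(iterations=12, seed=0, use_gt_assignment=True)
    ckpt = train_model(net, [tiny_sample()], cfg)
    assert ckpt.history[-1] < ckpt.history[0]
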