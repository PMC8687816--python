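import numpy as np
import pytest

from eegid import nn
from eegid.model import ICAConvNet, ModelConfig, build_model

TINY = ModelConfig(
    n_channels=3, n_points=8, n_classes=4, n_sources=4, conv_width=2,
    fc_width=5, dropout_p=0.0,
)


class TestConfig:
    def test_points_must_divide_by_8(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            ModelConfig(n_channels=4, n_points=70, n_classes=2)

    def test_dropout_range(self):
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(n_channels=4, n_points=8, n_classes=2, dropout_p=1.0)

    @pytest.mark.parametrize("p,width", [(80, 10240), (8, 1024)])
    def test_flatten_width_formula(self, p, width):
        cfg = ModelConfig(n_channels=2, n_points=p, n_classes=2)
        assert cfg.flatten_width == 32 * (p // 8) * 32 == width


class TestArchitectureContract:
    @pytest.mark.parametrize("c", [14, 32, 64])
    def test_shape_walk_matches_published_table(self, c):
        """P=80, O=109: the stage-by-stage shapes, for every montage size."""
        net = build_model(ModelConfig(n_channels=c, n_points=80, n_classes=109), seed=0)
        shapes = net.intermediate_shapes(batch_size=2)
        assert shapes == [
            (2, 1, 80, c),
            (2, 1, 80, 64),     # channel mixing always emits 64 sources
            (2, 32, 40, 64),
            (2, 32, 40, 64),
            (2, 32, 20, 64),
            (2, 32, 20, 64),
            (2, 32, 20, 64),
            (2, 32, 20, 32),
            (2, 32, 20, 32),
            (2, 32, 20, 32),
            (2, 32, 10, 32),
            (2, 10240),
            (2, 512),
            (2, 512),
            (2, 109),
        ]

    @pytest.mark.parametrize("p", [8, 16, 80, 160, 320])
    @pytest.mark.parametrize("c", [1, 14, 64])
    def test_forward_succeeds_for_any_valid_p_and_c(self, p, c):
        cfg = ModelConfig(n_channels=c, n_points=p, n_classes=3)
        net = build_model(cfg, seed=0)
        out = net.forward(np.zeros((2, 1, p, c), dtype=np.float32))
        assert out.shape == (2, 3)
        assert cfg.flatten_width == 32 * (p // 8) * 32

    @pytest.mark.parametrize("c,o", [(14, 109), (64, 109)])
    def test_parameter_count_formula(self, c, o):
        net = build_model(ModelConfig(n_channels=c, n_points=80, n_classes=o), seed=0)
        expected = (
            c * 64                      # separation matrix, no bias
            + (1 * 32 * 15 + 32)        # conv1: 5x3 kernel on one plane
            + (32 * 32 * 9 + 32) * 2    # conv2, conv3: 3x3
            + (10240 * 512 + 512)       # fc1
            + (512 * o + o)             # fc2
        )
        assert net.parameter_count() == expected

    def test_same_seed_same_weights(self):
        a = build_model(TINY, seed=9)
        b = build_model(TINY, seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_shape_mismatch_names_expected_and_got(self):
        net = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match=r"expected batch.*got"):
            net.forward(np.zeros((1, 1, 8, 5), dtype=np.float32))


class TestForward:
    def test_rows_exponentiate_to_one(self):
        net = build_model(TINY, seed=1)
        x = np.random.default_rng(0).normal(size=(6, 1, 8, 3)).astype(np.float32)
        logp = net.forward(x)
        np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, atol=1e-6)

    def test_evaluation_mode_is_deterministic(self):
        cfg = ModelConfig(n_channels=3, n_points=8, n_classes=4, n_sources=4,
                          conv_width=2, fc_width=5, dropout_p=0.5)
        net = build_model(cfg, seed=1)
        x = np.random.default_rng(0).normal(size=(4, 1, 8, 3)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_single_class_scores_are_zero(self):
        cfg = ModelConfig(n_channels=2, n_points=8, n_classes=1, n_sources=2,
                          conv_width=2, fc_width=3, dropout_p=0.0)
        net = build_model(cfg, seed=0)
        logp = net.forward(np.ones((3, 1, 8, 2), dtype=np.float32))
        np.testing.assert_array_equal(logp, 0.0)


class TestLoss:
    def test_uniform_prediction_costs_log_o(self):
        o = 7
        logp = np.full((5, o), -np.log(o))
        assert nn.nll_loss(logp, np.arange(5)) == pytest.approx(np.log(o), abs=1e-7)

    def test_perfect_prediction_costs_zero(self):
        logp = np.full((3, 4), -1e9)
        labels = np.array([0, 2, 3])
        logp[np.arange(3), labels] = 0.0
        assert nn.nll_loss(logp, labels) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(3, 4))
        logp = nn.log_softmax(scores)
        labels = rng.integers(0, 4, size=3)
        oracle = -np.mean([logp[i, labels[i]] for i in range(3)])
        assert nn.nll_loss(logp, labels) == pytest.approx(oracle, abs=1e-7)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            nn.nll_loss(np.zeros((2, 3)), np.array([0, 3]))


class TestGradients:
    def test_backprop_matches_central_differences(self):
        """Spot-check every parameter tensor against a numerical gradient."""
        net = build_model(TINY, seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 1, 8, 3))
        y = rng.integers(0, 4, size=4)
        logp = net.forward(x, train=True)
        net.zero_grad()
        net.backward(logp, y)
        for p in net.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = nn.nll_loss(net.forward(x), y)
                flat[i] = old - eps
                lm = nn.nll_loss(net.forward(x), y)
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(numeric, rel=1e-5, abs=1e-8), p.name

    def test_one_step_moves_the_separation_matrix(self):
        net = build_model(TINY, seed=4)
        w_before = net.stack.layers[0].W.value.copy()
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 1, 8, 3)).astype(np.float32)
        y = rng.integers(0, 4, size=6)
        opt = nn.Adam(net.params(), lr=3e-3)
        logp = net.forward(x, train=True)
        net.zero_grad()
        net.backward(logp, y)
        opt.step()
        assert np.abs(net.stack.layers[0].W.value - w_before).max() > 0

    def test_permuting_output_layer_permutes_columns(self):
        net = build_model(TINY, seed=6)
        x = np.random.default_rng(7).normal(size=(3, 1, 8, 3)).astype(np.float32)
        before = net.forward(x)
        perm = np.array([2, 0, 3, 1])
        fc2 = net.stack.layers[-1]
        fc2.W.value[...] = fc2.W.value[perm]
        fc2.b.value[...] = fc2.b.value[perm]
        after = net.forward(x)
        np.testing.assert_allclose(after, before[:, perm], atol=1e-6)


class TestCheckpoint:
    def test_round_trip_restores_bit_identical_outputs(self, tmp_path):
        net = build_model(TINY, seed=8)
        x = np.random.default_rng(9).normal(size=(5, 1, 8, 3)).astype(np.float32)
        ref = net.forward(x)
        path = net.save(tmp_path / "model.npz", label_map={"S001": 0},
                        stats={"S001": {"mu": 0.0, "sigma": 1.0}})
        back, label_map, stats = ICAConvNet.load(path)
        np.testing.assert_array_equal(back.forward(x), ref)
        assert label_map == {"S001": 0}
        assert stats["S001"]["sigma"] == 1.0
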