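from collections import Counter

import numpy as np
import pytest

from fallfusion import nn
from fallfusion.fusion import FusedStack, FusedImage
from fallfusion.model_4s3dcnn import (
    ConfigurationError,
    FourStreamNet,
    ModelConfig,
    branch_spatial_trace,
    build_model,
    count_parameters,
    forward,
    params_millions,
    propagate_shapes,
    summary_table,
)

DEFAULT = ModelConfig()


class TestArchitectureGoldens:
    def test_layer_count_is_67(self):
        assert build_model(DEFAULT).n_layers == 67

    def test_layer_kind_census(self):
        kinds = Counter(l.kind for l in build_model(DEFAULT).layers)
        assert kinds == {
            "input": 1,
            "split": 4,
            "conv": 12,
            "batchnorm": 14,  # 12 in branches + 2 in the FC head
            "relu": 14,
            "maxpool": 12,
            "gap": 4,
            "concat": 1,
            "fc": 3,
            "softmax": 1,
            "classification": 1,
        }

    def test_branch_spatial_trace(self):
        assert branch_spatial_trace(DEFAULT) == [128, 63, 31, 15, 7, 5, 4]

    @pytest.mark.parametrize(
        "name,shape",
        [
            ("input", (128, 128, 4, 3)),
            ("split_b3", (128, 128, 1, 3)),
            ("conv1_b1", (63, 63, 1, 64)),
            ("pool1_b1", (31, 31, 1, 64)),
            ("conv2_b2", (15, 15, 1, 128)),
            ("pool2_b4", (7, 7, 1, 128)),
            ("conv3_b1", (5, 5, 1, 256)),
            ("pool3_b1", (4, 4, 1, 256)),
            ("gap_b2", (1, 1, 1, 256)),
            ("concat", (1, 1, 1, 1024)),
            ("fc1", (1, 1, 1, 64)),
            ("fc2", (1, 1, 1, 32)),
            ("fc3", (1, 1, 1, 4)),
            ("softmax", (1, 1, 1, 4)),
        ],
    )
    def test_feature_map_shapes(self, name, shape):
        graph = propagate_shapes(build_model(DEFAULT))
        record = next(l for l in graph.layers if l.name == name)
        assert record.output_shape == shape

    def test_parameter_totals(self):
        graph = build_model(DEFAULT)
        by_name = {l.name: l.learnable_param_count for l in graph.layers}
        assert by_name["conv1_b1"] == 4 * 4 * 3 * 64 + 64  # 3,136
        assert by_name["fc1"] == 1024 * 64 + 64  # 65,600
        assert count_parameters(graph) == 1_560_228
        assert params_millions(graph) == 1.5  # truncated, not rounded

    def test_concat_width_and_summary(self):
        graph = build_model(DEFAULT)
        assert graph.concat_width() == 1024
        table = summary_table(graph)
        assert "Layers: 67" in table and "1.5 M" in table

    def test_runnable_net_matches_graph_param_count(self, fast_model_cfg):
        for cfg in (fast_model_cfg,):
            assert FourStreamNet(cfg).n_params() == build_model(cfg).total_params


class TestConfigValidation:
    def test_degenerate_single_branch_single_block(self):
        cfg = ModelConfig(
            input_shape=(128, 128, 1, 3),
            branch_conv_filters=(64,),
            conv_kernels=((4, 4, 3),),
            conv_strides=((2, 2, 3),),
            pool_windows=((3, 3),),
            pool_strides=((2, 2),),
            n_branches=1,
        )
        graph = build_model(cfg)
        kinds = Counter(l.kind for l in graph.layers)
        assert kinds["split"] == 1 and kinds["conv"] == 1
        assert kinds["maxpool"] == 1 and kinds["gap"] == 1
        assert graph.concat_width() == 64

    @pytest.mark.parametrize(
        "bad",
        [
            dict(branch_conv_filters=(64, 120, 256)),  # not doubling
            dict(fc_widths=(64, 30, 4)),  # not halving
            dict(n_branches=3),  # depth mismatch with input
            dict(conv_kernels=((200, 200, 3), (3, 3, 64), (3, 3, 128))),  # collapses
            dict(pool_windows=((5, 5), (3, 3), (2, 2))),  # illegal window
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(**bad))


def _numeric_grad(f, arr, idx, eps=1e-6):
    old = arr[idx]
    arr[idx] = old + eps
    fp = f()
    arr[idx] = old - eps
    fm = f()
    arr[idx] = old
    return (fp - fm) / (2 * eps)


class TestGradients:
    """Finite-difference checks of the NumPy engine (float64)."""

    @pytest.mark.parametrize(
        "factory,shape",
        [
            (lambda rng: nn.Conv2d(3, 4, (3, 3), (2, 2), rng, dtype=np.float64), (2, 9, 9, 3)),
            (lambda rng: nn.BatchNorm(3, dtype=np.float64), (2, 5, 5, 3)),
            (lambda rng: nn.MaxPool2d((3, 3), (2, 2)), (2, 9, 9, 3)),
            (lambda rng: nn.GlobalAvgPool(), (2, 4, 4, 3)),
            (lambda rng: nn.Linear(5, 3, rng, dtype=np.float64), (4, 5)),
            (lambda rng: nn.BatchNorm(5, dtype=np.float64), (4, 5)),
        ],
        ids=["conv", "bn2d", "maxpool", "gap", "linear", "bn1d"],
    )
    def test_layer_backward_matches_finite_differences(self, factory, shape):
        rng = np.random.default_rng(0)
        layer = factory(rng)
        x = rng.standard_normal(shape)

        def loss():
            return float((layer.forward(x, train=True) ** 2).sum()) / 2

        out = layer.forward(x, train=True)
        for p in layer.params():
            p.grad[...] = 0
        dx = layer.backward(out.copy())
        flat_idx = [np.unravel_index(i, shape) for i in rng.choice(x.size, 8, replace=False)]
        for idx in flat_idx:
            assert dx[idx] == pytest.approx(_numeric_grad(loss, x, idx), abs=1e-6)
        for p in layer.params():
            for i in rng.choice(p.size, min(6, p.size), replace=False):
                idx = np.unravel_index(i, p.value.shape)
                assert p.grad[idx] == pytest.approx(_numeric_grad(loss, p.value, idx), abs=1e-6)

    def test_full_network_gradients_and_flow(self):
        cfg = ModelConfig(
            input_shape=(20, 20, 2, 3),
            branch_conv_filters=(4, 8),
            conv_kernels=((3, 3, 3), (3, 3, 4)),
            conv_strides=((2, 2, 3), (1, 1, 4)),
            pool_windows=((3, 3), (2, 2)),
            pool_strides=((2, 2), (1, 1)),
            fc_widths=(8, 4),
            n_branches=2,
        )
        rng = np.random.default_rng(1)
        net = FourStreamNet(cfg, seed=3, dtype=np.float64)
        X = rng.random((3, 2, 20, 20, 3))
        y = np.array([0, 1, 3])

        def loss():
            logits = net.forward(X, train=True)
            l, _ = nn.softmax_cross_entropy(logits, y)
            return float(l)

        logits = net.forward(X, train=True)
        _, dl = nn.softmax_cross_entropy(logits, y)
        for p in net.params():
            p.grad[...] = 0
        net.backward(dl)
        for p in net.params():
            assert np.abs(p.grad).max() > 0, f"no gradient reaches {p.name}"
            for i in rng.choice(p.size, min(3, p.size), replace=False):
                idx = np.unravel_index(i, p.value.shape)
                assert p.grad[idx] == pytest.approx(_numeric_grad(loss, p.value, idx), abs=1e-6)


class TestForward:
    def test_probabilities_normalized_and_finite(self, fast_model_cfg):
        net = FourStreamNet(fast_model_cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((3, 4, 128, 128, 3), dtype=np.float32)
        p = net.predict_proba(x)
        assert p.shape == (3, 4)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        p0 = net.predict_proba(np.zeros((1, 4, 128, 128, 3), dtype=np.float32))
        assert np.isfinite(p0).all()

    def test_forward_accepts_fused_stack(self, fast_model_cfg):
        net = FourStreamNet(fast_model_cfg, seed=0)
        imgs = tuple(
            FusedImage(pixels=np.full((128, 128, 3), 0.1 * (k + 1)), level=2) for k in range(4)
        )
        probs = forward(net, FusedStack(images=imgs))
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_wrong_sample_shape_rejected(self, fast_model_cfg):
        net = FourStreamNet(fast_model_cfg, seed=0)
        with pytest.raises(ValueError, match="shape"):
            net.predict_proba(np.zeros((2, 3, 128, 128, 3), dtype=np.float32))

    def test_branches_are_not_weight_shared(self, fast_model_cfg):
        net = FourStreamNet(fast_model_cfg, seed=0)
        rng = np.random.default_rng(2)
        x = rng.random((1, 4, 128, 128, 3), dtype=np.float32)
        swapped = x[:, [1, 0, 2, 3]]
        assert not np.allclose(net.predict_proba(x), net.predict_proba(swapped), atol=1e-6)

    def test_branch_isolation(self, fast_model_cfg):
        net = FourStreamNet(fast_model_cfg, seed=0)
        rng = np.random.default_rng(3)
        x = rng.random((2, 4, 128, 128, 3), dtype=np.float32)
        base = net.forward_descriptors(x)
        bumped = x.copy()
        bumped[:, 1] = np.clip(2 * bumped[:, 1], 0, 1)  # touch branch 2 only
        new = net.forward_descriptors(bumped)
        for b in (0, 2, 3):
            np.testing.assert_array_equal(new[b], base[b])
        assert not np.array_equal(new[1], base[1])

    def test_same_seed_same_network(self, fast_model_cfg):
        a = FourStreamNet(fast_model_cfg, seed=9)
        b = FourStreamNet(fast_model_cfg, seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestCheckpoint:
    def test_save_load_roundtrip(self, fast_model_cfg, tmp_path):
        net = FourStreamNet(fast_model_cfg, seed=4)
        rng = np.random.default_rng(4)
        x = rng.random((2, 4, 128, 128, 3), dtype=np.float32)
        # a training step so running stats are nontrivial
        logits = net.forward(x, train=True)
        _, dl = nn.softmax_cross_entropy(logits, np.array([0, 2]))
        net.backward(dl)
        nn.Adam(net.params(), lr=1e-3).step()
        path = tmp_path / "model.npz"
        net.save(path)
        back = FourStreamNet.load(path)
        assert back.config == fast_model_cfg
        np.testing.assert_array_equal(back.predict_proba(x), net.predict_proba(x))
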