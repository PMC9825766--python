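"""Architecture contracts: introspection, shapes, determinism, persistence."""

import dataclasses

import numpy as np
import pytest

from loopnet.nn.model import InteractionNet, ModelConfig, MultiTaskNet, build_ablation, build_model
from loopnet.training import TrainConfig, bce_with_logits, fit

from conftest import random_bundles


def test_default_dense_block_layout():
    net = build_model(ModelConfig())
    desc = net.describe()
    for mod in ("S", "R"):
        block = desc["blocks"][mod]
        assert block["n_layers"] == 4
        assert [l["filters"] for l in block["layers"]] == [64, 32, 16, 16]
        assert [l["dilation"] for l in block["layers"]] == [1, 2, 3, 4]
        assert all(l["operations"] == ("convolution", "batch_normalization", "prelu", "dropout")
                   for l in block["layers"])
    assert desc["classifier_hidden"] == 256
    s_layers = desc["blocks"]["S"]["layers"]
    assert s_layers[0]["kernel"] == (20, 4) and s_layers[0]["stride"] == (10, 4)
    r_layers = desc["blocks"]["R"]["layers"]
    assert r_layers[0]["kernel"] == (3, 1) and r_layers[0]["stride"] == (1, 1)
    assert all(l["stride"] == (1, 1) for l in s_layers[1:] + r_layers[1:])
    assert desc["fusion"]["kernel"] == (4, 4) and desc["fusion"]["stride"] == (4, 4)


def test_channel_bookkeeping():
    net = build_model(ModelConfig())
    for block in net.describe()["blocks"].values():
        filters = [l["filters"] for l in block["layers"]]
        for k, layer in enumerate(block["layers"][1:], start=1):
            assert layer["in_channels"] == sum(filters[:k])
        assert block["out_channels"] == sum(filters)


def test_shape_table():
    """Spatial shapes implied by the printed kernels/strides.

    Sequence path: 2000x4 --(20x4 kernel, 10x4 stride, valid)--> 199x1, then
    stride-1 same-padded layers keep 199x1. Read path: 21xM --(3x1, valid)-->
    19xM kept by later layers. Fused grid stacks 199*1 + 19*4 = 275 rows of
    sum(filters)=128 channels; the 4x4/4x4 fusion maps it to 68x32.
    """
    net = build_model(ModelConfig())
    desc = net.describe()
    assert desc["blocks"]["S"]["out_shape"] == (199, 1)
    assert desc["blocks"]["R"]["out_shape"] == (19, 4)
    assert desc["grid_shape"] == (199 * 1 + 19 * 4, 128)
    assert desc["fusion_out_shape"] == (68, 32)
    assert desc["fused_dim"] == 64
    assert desc["classifier_input"] == 64 + 1  # fused features + distance


def test_predictions_strictly_inside_unit_interval(tiny_model_cfg):
    net = build_model(tiny_model_cfg)
    bundles = random_bundles(16, tiny_model_cfg, seed=1)
    p = net.predict(bundles)
    assert np.all(p > 0) and np.all(p < 1)


def test_same_seed_identical_initial_predictions(tiny_model_cfg):
    bundles = random_bundles(8, tiny_model_cfg, seed=2)
    p1 = build_model(tiny_model_cfg).predict(bundles)
    p2 = build_model(tiny_model_cfg).predict(bundles)
    assert np.array_equal(p1, p2)
    other = build_model(dataclasses.replace(tiny_model_cfg, seed=99)).predict(bundles)
    assert not np.array_equal(p1, other)


def test_save_load_roundtrip(tmp_path, tiny_model_cfg):
    net = build_model(tiny_model_cfg)
    bundles = random_bundles(100, tiny_model_cfg, seed=3)
    before = net.predict(bundles)
    net.save(tmp_path / "model")
    back = InteractionNet.load(tmp_path / "model")
    after = back.predict(bundles)
    assert np.allclose(before, after, atol=1e-6)
    assert back.cfg == net.cfg


@pytest.mark.parametrize("active,expected_blocks", [
    (("S",), {"S"}),
    (("S", "D"), {"S"}),
    (("R", "D"), {"R"}),
    (("D",), set()),
    (("S", "R", "D", "aux"), {"S", "R", "aux"}),
])
def test_ablations_consume_exactly_active_features(tiny_model_cfg, active, expected_blocks):
    cfg = dataclasses.replace(tiny_model_cfg, features=active, n_aux_tracks=2)
    net = build_ablation(cfg, active)
    assert set(net.extractor.blocks) == expected_blocks
    bundles = random_bundles(6, cfg, seed=4)
    p = net.predict(bundles)
    assert p.shape == (6,) and np.all((p > 0) & (p < 1))
    if not expected_blocks:
        assert net.head.in_dim == 1  # distance-only: classifier on the scalar


def test_empty_feature_subset_rejected(tiny_model_cfg):
    with pytest.raises(ValueError):
        dataclasses.replace(tiny_model_cfg, features=())


def test_extract_contract(tiny_model_cfg):
    net = build_model(tiny_model_cfg)
    bundles = random_bundles(5, tiny_model_cfg, seed=5)
    f1 = net.extract(bundles)
    f2 = net.extract(bundles)
    assert np.array_equal(f1, f2)
    assert f1.shape == (5, net.describe()["fused_dim"])
    two = bundles.subset(np.array([1, 1]))
    fs = net.extract(two)
    assert np.array_equal(fs[0], fs[1])


def test_frozen_extractor_unchanged_by_head_training(tiny_model_cfg):
    net = build_model(tiny_model_cfg)
    train = random_bundles(64, tiny_model_cfg, seed=6, signal=True)
    val = random_bundles(32, tiny_model_cfg, seed=7, signal=True)
    probe = random_bundles(8, tiny_model_cfg, seed=8)
    net.freeze_extractor()
    before = net.extract(probe)
    before_w = {k: v.copy() for k, v in net.extractor.state_dict().items()}
    fit(net, train, val, TrainConfig(learning_rate=1e-2, max_epochs=2, patience=2, seed=0))
    after = net.extract(probe)
    assert np.allclose(before, after, atol=1e-7)
    for k, v in net.extractor.state_dict().items():
        assert np.array_equal(before_w[k], v), k


def test_multitask_classifier_width(tiny_model_cfg):
    shared = build_model(tiny_model_cfg)
    net = MultiTaskNet(tiny_model_cfg, shared)
    fused = shared.extractor.out_dim
    assert net.head.in_dim == 2 * fused + 1
    bundles = random_bundles(4, tiny_model_cfg, seed=9)
    p = net.predict(bundles)
    assert np.all((p > 0) & (p < 1))


def test_multitask_rejects_mismatched_architecture(tiny_model_cfg):
    shared = build_model(tiny_model_cfg)
    other = dataclasses.replace(tiny_model_cfg, filters=(4, 4, 4, 4))
    with pytest.raises(ValueError, match="incompatible"):
        MultiTaskNet(other, shared)


def test_gradients_match_finite_differences():
    """Backprop through the full network agrees with central differences."""
    cfg = ModelConfig(features=("S", "R", "D"), anchor_len=60, n_windows=11,
                      n_read_tracks=2, filters=(5, 4, 3, 3), seq_kernel=(10, 4),
                      seq_stride=(5, 4), fusion_filters=4, hidden_units=6,
                      dropout=0.0, seed=1)
    net = InteractionNet(cfg)
    for p in net.all_params():
        p.data = p.data.astype(np.float64)
        p.grad = np.zeros_like(p.data)
    for block in net.extractor.blocks.values():
        for layer in block.layers:
            layer.bn.running_mean = layer.bn.running_mean.astype(np.float64)
            layer.bn.running_var = layer.bn.running_var.astype(np.float64)
    net.extractor.fusion.bn.running_mean = net.extractor.fusion.bn.running_mean.astype(np.float64)
    net.extractor.fusion.bn.running_var = net.extractor.fusion.bn.running_var.astype(np.float64)
    rng = np.random.default_rng(0)
    batch = {"S": rng.random((4, 2, 60, 4)), "R": rng.random((4, 2, 11, 2)),
             "D": rng.random(4)}
    y = rng.integers(0, 2, 4).astype(np.float64)

    def loss():
        return bce_with_logits(net.forward_logits(batch, train=True), y)

    for p in net.all_params():
        p.zero_grad()
    _, dz = loss()
    net.backward_logits(dz)
    eps = 1e-6
    for p in net.all_params():
        flat, gflat = p.data.reshape(-1), p.grad.reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = loss()
            flat[i] = orig - eps
            lm, _ = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[i]) <= 1e-4 * max(abs(num), abs(gflat[i]), 1e-3), p.name
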