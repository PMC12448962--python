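"""Backbone contract: descriptor constants, reference net, sliding window."""

import numpy as np
import pytest

from psnseg.backbone import (
    ReferenceNet,
    build_reference_net,
    build_swin_descriptor,
    sliding_window_predict,
    softmax_scores,
)
from psnseg.training import composite_loss_with_grad
from psnseg.volume import Volume


class TestDescriptor:
    def test_clinical_configuration_constants(self):
        d = build_swin_descriptor()
        assert d.patch_size == (2, 2, 2)
        assert d.embed_dim == 48
        assert d.stage_channels == (48, 96, 192, 384)
        assert d.heads == (3, 6, 12, 24)
        assert d.depths == (2, 2, 2, 2)
        assert d.window == (7, 7, 7)
        assert d.bottleneck_channels == 768
        assert d.drop_path_rate == 0.10

    def test_invalid_channel_progression_rejected(self):
        from psnseg.backbone import ArchitectureDescriptor

        with pytest.raises(ValueError):
            ArchitectureDescriptor(stage_channels=(48, 96, 192, 400))

    def test_yaml_export_round_trips(self):
        import yaml

        doc = yaml.safe_load(build_swin_descriptor().to_yaml())
        assert doc["embed_dim"] == 48
        assert doc["stage_channels"] == [48, 96, 192, 384]


class TestReferenceNet:
    def test_forward_shape_contract(self):
        net = build_reference_net(width=4, depth=2, seed=0)
        x = np.random.default_rng(0).random((1, 32, 16, 16)).astype(np.float32)
        scores = net.forward(x)
        assert scores.shape == (2, 32, 16, 16)

    def test_softmax_normalized_per_voxel(self):
        net = build_reference_net(width=4, depth=1, seed=0)
        x = np.random.default_rng(1).random((1, 8, 8, 8)).astype(np.float32)
        p = softmax_scores(net.forward(x))
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-6)

    def test_same_seed_identical_parameters(self):
        a = build_reference_net(8, 2, seed=5).parameters()
        b = build_reference_net(8, 2, seed=5).parameters()
        assert set(a) == set(b)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        c = build_reference_net(8, 2, seed=6).parameters()
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_too_small_patch_rejected(self):
        net = build_reference_net(width=4, depth=3, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 4, 4, 4), np.float32))

    def test_save_load_reproduces_scores_bitwise(self, tmp_path):
        from psnseg.io import CheckpointRef, load_checkpoint, save_checkpoint

        net = build_reference_net(6, 2, seed=3)
        x = np.random.default_rng(2).random((1, 16, 16, 16)).astype(np.float32)
        before = net.forward(x)
        ref = CheckpointRef(tmp_path / "ck.npz", "pretrain")
        save_checkpoint(net.parameters(), ref)
        other = build_reference_net(6, 2, seed=99)
        params, _ = load_checkpoint(ref.path)
        other.load_parameters(params)
        np.testing.assert_array_equal(other.forward(x), before)

    def test_gradients_match_finite_differences(self):
        """Analytic backprop vs central differences on a tiny net."""
        net = build_reference_net(width=2, depth=2, seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((1, 8, 8, 8)).astype(np.float32)
        t = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8)
        keys = sorted(net.parameters())

        def loss_at(flat):
            p = net.parameters()
            i = 0
            for k in keys:
                n = p[k].size
                p[k][...] = flat[i : i + n].reshape(p[k].shape)
                i += n
            return composite_loss_with_grad(net.forward(x), t)[0]

        p0 = np.concatenate([net.parameters()[k].ravel().astype(np.float64) for k in keys])
        for layer in net._layers():
            for g in layer.grads.values():
                g[...] = 0.0
        _, grad, _, _ = composite_loss_with_grad(net.forward(x), t)
        net.backward(grad)
        gdict = {}
        for name, layer in zip(net._layer_names(), net._layers()):
            for k in layer.grads:
                gdict[f"{name}.{k}"] = layer.grads[k].copy()
        ga = np.concatenate([gdict[k].ravel() for k in keys])
        eps = 3e-3
        idx = rng.choice(p0.size, 30, replace=False)
        for i in idx:
            up, dn = p0.copy(), p0.copy()
            up[i] += eps
            dn[i] -= eps
            gn = (loss_at(up) - loss_at(dn)) / (2 * eps)
            # float32 forward + ReLU kinks limit attainable agreement
            assert abs(gn - ga[i]) <= 5e-3 * max(1.0, abs(gn) + abs(ga[i]))

    def test_memorizes_single_patch(self):
        """200 optimizer steps on one fixed (patch, mask) pair drive the
        composite loss below 10% of its initial value."""
        net = build_reference_net(width=8, depth=2, seed=1)
        rng = np.random.default_rng(1)
        x = rng.random((1, 16, 16, 16)).astype(np.float32) * 0.2
        t = np.zeros((16, 16, 16), np.uint8)
        t[5:12, 4:11, 6:13] = 1
        x[0][t > 0] += 0.6
        opt = net.optimizer(1e-3, 1e-5)
        first = None
        for _ in range(200):
            opt.zero_grad()
            loss, grad, _, _ = composite_loss_with_grad(net.forward(x), t)
            if first is None:
                first = loss
            net.backward(grad)
            opt.step()
        assert loss < 0.1 * first


class TestSlidingWindow:
    class _ConstantModel:
        def __init__(self, ctv_score=5.0):
            self.ctv_score = ctv_score

        def forward(self, x):
            scores = np.zeros((2, *x.shape[1:]), np.float32)
            scores[1] = self.ctv_score
            return scores

        def eval(self):
            pass

    def test_constant_ctv_model_fills_grid(self):
        vol = Volume(np.zeros((12, 12, 12), np.float32), (1, 1, 1))
        out = sliding_window_predict(self._ConstantModel(), vol, (8, 8, 8), overlap=0.5)
        assert out.shape == (12, 12, 12)
        assert np.all(out == 1)

    def test_overlap_neutral_for_constant_model(self):
        vol = Volume(np.zeros((16, 16, 16), np.float32), (1, 1, 1))
        a = sliding_window_predict(self._ConstantModel(), vol, (8, 8, 8), overlap=0.0)
        b = sliding_window_predict(self._ConstantModel(), vol, (8, 8, 8), overlap=0.5)
        np.testing.assert_array_equal(a, b)

    def test_output_binary(self):
        net = build_reference_net(4, 2, seed=0)
        vol = Volume(np.random.default_rng(3).random((16, 16, 16)).astype(np.float32), (1, 1, 1))
        out = sliding_window_predict(net, vol, (8, 8, 8), overlap=0.25)
        assert set(np.unique(out)) <= {0, 1}

    def test_translation_consistency_under_padding(self):
        """Padding the grid with background and cropping back reproduces the
        interior prediction away from the new window seams (checked with a
        briefly trained net whose decisions are crisp — an untrained net sits
        on its decision boundary everywhere, where window alignment matters)."""
        from psnseg.training import composite_loss_with_grad

        net = build_reference_net(4, 2, seed=4)
        rng = np.random.default_rng(4)
        base = rng.random((16, 16, 16)).astype(np.float32) * 0.2
        target = np.zeros((16, 16, 16), np.uint8)
        target[5:11, 5:11, 5:11] = 1
        base[target > 0] += 0.6
        opt = net.optimizer(1e-3, 1e-5)
        for _ in range(60):
            opt.zero_grad()
            _, grad, _, _ = composite_loss_with_grad(net.forward(base[None]), target)
            net.backward(grad)
            opt.step()
        vol = Volume(base, (1, 1, 1))
        padded = np.zeros((24, 24, 24), np.float32)
        padded[4:20, 4:20, 4:20] = base
        out_a = sliding_window_predict(net, vol, (8, 8, 8), overlap=0.5)
        out_b = sliding_window_predict(net, Volume(padded, (1, 1, 1)), (8, 8, 8), overlap=0.5)
        inner = out_b[4:20, 4:20, 4:20]
        agreement = (out_a == inner).mean()
        assert agreement > 0.95

    def test_patch_larger_than_grid_rejected(self):
        vol = Volume(np.zeros((8, 8, 8), np.float32), (1, 1, 1))
        with pytest.raises(ValueError):
            sliding_window_predict(self._ConstantModel(), vol, (16, 16, 16))
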