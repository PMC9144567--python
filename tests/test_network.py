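"""Network blocks against dense oracles, analytic limits, and invariants."""

import time

import numpy as np
import pytest

from oracles import (attention_oracle, gcn_dynamic_oracle, gcn_static_oracle,
                     mstcn_oracle)
from somnograph.autodiff import Tensor
from somnograph.graph import SleepGraph, normalize_adjacency
from somnograph.network import (InterTemporalAttention, MultiScaleTCN,
                                NetworkConfig, SleepStageNetwork,
                                contexts_to_input, gcn_dynamic, gcn_fuse,
                                gcn_static, load_checkpoint, save_checkpoint)


class TestGcnStatic:
    def test_identity_composition(self, rng):
        x = np.abs(rng.normal(size=(2, 3, 4, 5)))   # non-negative input
        out = gcn_static(x, np.eye(5), np.zeros((5, 5)), np.eye(3))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_zero_input_no_bias(self, rng):
        out = gcn_static(np.zeros((1, 3, 2, 4)), np.eye(4),
                         rng.normal(size=(4, 4)), rng.normal(size=(3, 6)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_dense_oracle(self, rng, tiny_network_inputs):
        x = tiny_network_inputs
        a = rng.normal(size=(5, 5))
        mu = rng.normal(size=(4, 6))
        out = gcn_static(x, a, np.zeros((5, 5)), mu)
        np.testing.assert_allclose(out, gcn_static_oracle(x, a, mu),
                                   atol=1e-6)

    def test_gradients(self, gradcheck, rng):
        x = rng.normal(size=(1, 2, 2, 3))
        a = rng.normal(size=(3, 3))
        mu = rng.normal(size=(2, 2))
        gradcheck(lambda xs, gs, ms:
                  gcn_static(xs, np.eye(3) * 0.5, gs, ms).sum(), x, a, mu)


class TestGcnDynamic:
    def test_uniform_graph_averages_nodes(self, rng):
        x = rng.normal(size=(1, 3, 2, 4))
        gd = np.full((4, 4), 0.25)
        out = gcn_dynamic(x, gd, np.eye(3))
        expected = np.broadcast_to(x.mean(axis=3, keepdims=True), x.shape)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_identity_everything(self, rng):
        x = rng.normal(size=(1, 3, 2, 4))
        np.testing.assert_allclose(gcn_dynamic(x, np.eye(4), np.eye(3)), x,
                                   atol=1e-12)

    def test_matches_dense_oracle_per_frame_graph(self, rng,
                                                  tiny_network_inputs):
        x = tiny_network_inputs
        gd = rng.random((2, 3, 5, 5))
        gd /= gd.sum(axis=-1, keepdims=True)
        mu = rng.normal(size=(4, 6))
        out = gcn_dynamic(x, gd, mu)
        np.testing.assert_allclose(out, gcn_dynamic_oracle(x, gd, mu),
                                   atol=1e-6)

    def test_gradients(self, gradcheck, rng):
        x = rng.normal(size=(1, 2, 2, 3))
        gd = rng.random((3, 3))
        mu = rng.normal(size=(2, 2))
        gradcheck(lambda xs, gs, ms: gcn_dynamic(xs, gs, ms).sum(), x, gd, mu)


class TestGcnFuse:
    def test_phi_zero_drops_static_branch(self, rng):
        stat, dyn = rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 3, 4))
        np.testing.assert_array_equal(gcn_fuse(stat, dyn, 0.0), dyn)

    def test_phi_one_plain_sum(self, rng):
        stat, dyn = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        np.testing.assert_allclose(gcn_fuse(stat, dyn, 1.0), stat + dyn)

    def test_half_and_half(self):
        ones = np.ones((2, 2))
        np.testing.assert_allclose(gcn_fuse(ones, ones, 0.5), 1.5 * ones)

    def test_phi_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            gcn_fuse(np.ones(2), np.ones(2), 1.5)


class TestMultiScaleTCN:
    def test_channel_partition_covers_output(self, rng):
        layer = MultiScaleTCN(5, 16, np.random.default_rng(0))
        # 4 dilated + frame + pool branches at 16//7 = 2 channels each,
        # residual branch takes the remaining 4: seven branches total
        assert layer.branch_channels == 2 and layer.res_channels == 4
        assert 6 * 2 + 4 == 16
        n_branches = len(layer.dilated) + 3  # + frame, pool, residual
        assert n_branches == 7

    @pytest.mark.parametrize("t_len", [1, 5, 25])
    def test_temporal_length_preserved(self, rng, t_len):
        layer = MultiScaleTCN(4, 14, np.random.default_rng(1))
        x = Tensor(rng.normal(size=(2, 4, t_len, 3)))
        assert layer.forward(x, training=True).shape == (2, 14, t_len, 3)

    @pytest.mark.parametrize("constant", [False, True])
    def test_matches_dense_oracle(self, rng, constant):
        layer = MultiScaleTCN(4, 14, np.random.default_rng(2))
        if constant:
            x = np.broadcast_to(rng.normal(size=(2, 4, 1, 3)),
                                (2, 4, 5, 3)).copy()
        else:
            x = rng.normal(size=(2, 4, 5, 3))
        out = layer.forward(Tensor(x), training=True).data
        np.testing.assert_allclose(out, mstcn_oracle(layer, x), atol=1e-6)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="7"):
            MultiScaleTCN(4, 6, np.random.default_rng(0))

    def test_gradients_through_all_branches(self, rng):
        layer = MultiScaleTCN(3, 7, np.random.default_rng(3))
        x = rng.normal(size=(2, 3, 4, 2))
        _layer_gradcheck(lambda t: layer.forward(t, training=True), layer, x)


class TestAttention:
    def test_shape_preserved_and_bounded(self, rng):
        layer = InterTemporalAttention(8, 4, np.random.default_rng(0))
        x = rng.normal(size=(3, 8, 5, 6))
        out = layer.forward(Tensor(x), training=True).data
        assert out.shape == x.shape
        assert (np.abs(out) <= np.abs(x) + 1e-12).all()

    def test_constant_input_gets_per_channel_scalar(self):
        layer = InterTemporalAttention(8, 4, np.random.default_rng(1))
        x = np.broadcast_to(
            np.random.default_rng(2).normal(size=(2, 8, 1, 1)),
            (2, 8, 5, 6)).copy()
        out = layer.forward(Tensor(x), training=True).data
        ratio = out / x
        # the attention map is constant within each (sample, channel)
        np.testing.assert_allclose(
            ratio, np.broadcast_to(ratio[:, :, :1, :1], ratio.shape),
            atol=1e-9)

    def test_matches_dense_oracle(self, rng):
        layer = InterTemporalAttention(8, 4, np.random.default_rng(3))
        x = rng.normal(size=(2, 8, 4, 5))
        out = layer.forward(Tensor(x), training=True).data
        np.testing.assert_allclose(out, attention_oracle(layer, x),
                                   atol=1e-6)

    def test_reduction_exceeding_channels_rejected(self):
        with pytest.raises(ValueError, match="reduction"):
            InterTemporalAttention(3, 4, np.random.default_rng(0))

    def test_gradients(self, rng):
        layer = InterTemporalAttention(4, 2, np.random.default_rng(4))
        x = rng.normal(size=(2, 4, 3, 3))
        _layer_gradcheck(lambda t: layer.forward(t, training=True), layer, x)


def _layer_gradcheck(fn, layer, x, tol=1e-4, eps=1e-6):
    """Finite-difference check of input + parameter gradients."""
    from conftest import relative_error

    xt = Tensor(x, requires_grad=True)
    out = fn(xt)
    proj = np.random.default_rng(99).normal(size=out.shape)
    (out * Tensor(proj)).sum().backward()

    def loss_at(x_arr):
        return float((fn(Tensor(x_arr)).data * proj).sum())

    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[ix] += eps
        xm[ix] -= eps
        num[ix] = (loss_at(xp) - loss_at(xm)) / (2 * eps)
    assert relative_error(xt.grad, num) < tol

    for p in layer.parameters():
        flat = p.data.ravel()
        idx = np.random.default_rng(7).choice(flat.size,
                                              size=min(4, flat.size),
                                              replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_at(x)
            flat[i] = orig - eps
            lm = loss_at(x)
            flat[i] = orig
            num_g = (lp - lm) / (2 * eps)
            ana_g = p.grad.ravel()[i]
            assert relative_error(ana_g, num_g) < tol


@pytest.fixture(scope="module")
def small_model(isruc_graph):
    cfg = NetworkConfig(n_electrodes=6, channel_plan=(8, 14),
                        reduction=2, dropout=0.0)
    return SleepStageNetwork(cfg, isruc_graph, seed=0)


class TestFullNetwork:
    def test_classifier_probabilities(self, small_model, rng):
        x = rng.normal(size=(3, 5, 5, 6))
        probs = small_model.classify(x)
        assert probs.shape == (3, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        logits = small_model.forward(x).data
        np.testing.assert_array_equal(np.argmax(probs, axis=1),
                                      np.argmax(logits, axis=1))

    def test_zero_head_gives_uniform_probabilities(self, isruc_graph, rng):
        cfg = NetworkConfig(n_electrodes=6, channel_plan=(8,), reduction=2)
        model = SleepStageNetwork(cfg, isruc_graph, seed=0)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        probs = model.classify(rng.normal(size=(2, 5, 5, 6)))
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_eval_forward_deterministic(self, small_model, rng):
        x = rng.normal(size=(2, 5, 5, 6))
        a = small_model.forward(x).data
        b = small_model.forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_attention_ablation_switch(self, isruc_graph, rng):
        x = rng.normal(size=(2, 5, 5, 6))
        cfg_on = NetworkConfig(n_electrodes=6, channel_plan=(8,), reduction=2)
        cfg_off = NetworkConfig(n_electrodes=6, channel_plan=(8,),
                                reduction=2, attention=False)
        m_on = SleepStageNetwork(cfg_on, isruc_graph, seed=0)
        m_off = SleepStageNetwork(cfg_off, isruc_graph, seed=0)
        assert m_on.modules[0].att is not None
        assert m_off.modules[0].att is None
        assert len(m_off.parameters()) < len(m_on.parameters())

    def test_nine_module_shape_propagation(self, isruc_graph, rng):
        cfg = NetworkConfig(n_electrodes=6)  # default 66..264 plan
        model = SleepStageNetwork(cfg, isruc_graph, seed=0)
        x = Tensor(rng.normal(size=(1, 5, 5, 6)))
        out = x
        for module in model.modules:
            out = module.forward(out, training=False, rng=None)
        assert out.shape == (1, 264, 5, 6)   # channels grow 5 -> 264
        assert model.forward(x.data).shape == (1, 5)

    def test_forward_backward_under_one_second(self, isruc_graph, rng):
        cfg = NetworkConfig(n_electrodes=6)
        model = SleepStageNetwork(cfg, isruc_graph, seed=0)
        x = rng.normal(size=(1, 5, 5, 6))
        model.forward(x)  # warm-up outside the timed region
        t0 = time.perf_counter()
        logits = model.forward(x, training=True,
                               rng=np.random.default_rng(0))
        (-logits.log_softmax(axis=-1)[np.arange(1), [2]]).mean().backward()
        assert time.perf_counter() - t0 < 1.0

    def test_electrode_permutation_equivariance(self, isruc_graph, rng):
        perm = np.array([3, 0, 5, 1, 4, 2])
        cfg = NetworkConfig(n_electrodes=6, channel_plan=(8, 14),
                            reduction=2, dropout=0.0)
        m1 = SleepStageNetwork(cfg, isruc_graph, seed=0)
        gp_perm = isruc_graph.gp[np.ix_(perm, perm)]
        graph_perm = SleepGraph(
            montage=[isruc_graph.montage[i] for i in perm], gp=gp_perm,
            gp_norm=normalize_adjacency(gp_perm),
            gm_init=np.zeros_like(gp_perm))
        m2 = SleepStageNetwork(cfg, graph_perm, seed=0)  # same weights
        x = rng.normal(size=(2, 5, 5, 6))
        np.testing.assert_allclose(m2.classify(x[:, :, :, perm]),
                                   m1.classify(x), atol=1e-8)

    def test_checkpoint_round_trip(self, small_model, tmp_path, rng):
        x = rng.normal(size=(2, 5, 5, 6))
        before = small_model.classify(x)
        save_checkpoint(tmp_path / "m.npz", small_model)
        loaded = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.classify(x), before, atol=1e-12)

    def test_model_gradient_subset_matches_finite_differences(
            self, isruc_graph, rng):
        from conftest import relative_error

        cfg = NetworkConfig(n_electrodes=6, channel_plan=(8,), reduction=2,
                            dropout=0.0)
        model = SleepStageNetwork(cfg, isruc_graph, seed=1)
        x = rng.normal(size=(4, 5, 3, 6))
        y = np.array([0, 2, 1, 4])

        def loss_value():
            logits = model.forward(x, training=True)
            return float(-(logits.log_softmax(axis=-1).data[
                np.arange(4), y]).mean())

        logits = model.forward(x, training=True)
        loss = -(logits.log_softmax(axis=-1)[np.arange(4), y]).mean()
        for p in model.parameters():
            p.grad = None
        loss.backward()
        eps = 1e-6
        prng = np.random.default_rng(5)
        for p in prng.choice(len(model.parameters()), size=6, replace=False):
            param = model.parameters()[p]
            flat = param.data.ravel()
            i = int(prng.integers(flat.size))
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_value()
            flat[i] = orig - eps
            lm = loss_value()
            flat[i] = orig
            ana = param.grad.ravel()[i]
            assert relative_error(ana, (lp - lm) / (2 * eps)) < 1e-4


def test_contexts_to_input_layout(rng):
    vals = rng.normal(size=(3, 6, 5, 4))     # (B, N, F, Tn)
    x = contexts_to_input(vals)
    assert x.shape == (3, 5, 4, 6)           # (B, F, Tn, N)
    np.testing.assert_array_equal(x[1, 2, 3, 4], vals[1, 4, 2, 3])
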