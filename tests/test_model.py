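"""Architecture components: attention oracles, shape contracts, token
geometry, resolution preservation and residual structure."""

import numpy as np
import pytest

import neuroseg3d as ns

from neuroseg3d.autograd import Tensor
from neuroseg3d.model import (AttentionParams, SegmentationNetwork, conv3d,
                              layer_norm, mhsa, scaled_dot_attention, upsample2)


def attention_loop_oracle(q, k, v):
    """Explicit-loop reference: per-row exp/Σexp weights applied to V."""
    n_q, d_k = q.shape
    n_k, d_v = v.shape
    out = np.zeros((n_q, d_v))
    for i in range(n_q):
        scores = np.array([q[i] @ k[j] / np.sqrt(d_k) for j in range(n_k)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n_k):
            out[i] += w[j] * v[j]
    return out


class TestScaledDotAttention:
    def test_zero_queries_average_values(self, rng):
        """Q = 0 → uniform softmax → every output row is the mean of V."""
        k = rng.normal(size=(5, 3))
        v = rng.normal(size=(5, 2))
        out = scaled_dot_attention(np.zeros((4, 3)), k, v)
        np.testing.assert_allclose(out, np.tile(v.mean(0), (4, 1)), atol=1e-12)

    def test_single_key_returns_value_row(self, rng):
        q = rng.normal(size=(6, 3))
        k = rng.normal(size=(1, 3))
        v = rng.normal(size=(1, 4))
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out, np.tile(v[0], (6, 1)), atol=1e-12)

    def test_matches_explicit_loop_oracle(self, rng):
        q, k = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        v = rng.normal(size=(3, 2))
        np.testing.assert_allclose(scaled_dot_attention(q, k, v),
                                   attention_loop_oracle(q, k, v), atol=1e-6)

    def test_rows_are_convex_combinations(self, rng):
        """Attention weights are row-stochastic: outputs lie inside the
        convex hull of V (checked per coordinate)."""
        q, k = rng.normal(size=(8, 5)), rng.normal(size=(6, 5))
        v = rng.normal(size=(6, 3))
        out = scaled_dot_attention(q, k, v)
        assert (out <= v.max(0) + 1e-9).all() and (out >= v.min(0) - 1e-9).all()

    def test_zero_dk_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 0)), np.zeros((2, 0)), np.zeros((2, 2)))


def mhsa_loop_oracle(x, params):
    """Head-by-head explicit recomputation of multi-head self-attention."""
    h = params.w_q.data.shape[0]
    heads = []
    for i in range(h):
        q = x @ params.w_q.data[i]
        k = x @ params.w_k.data[i]
        v = x @ params.w_v.data[i]
        heads.append(attention_loop_oracle(q, k, v))
    return np.concatenate(heads, axis=-1) @ params.w_o.data


def random_attention_params(rng, h, d_model):
    d_k = d_model // h
    return AttentionParams(
        w_q=Tensor(rng.normal(size=(h, d_model, d_k))),
        w_k=Tensor(rng.normal(size=(h, d_model, d_k))),
        w_v=Tensor(rng.normal(size=(h, d_model, d_k))),
        w_o=Tensor(rng.normal(size=(d_model, d_model))))


class TestMHSA:
    def test_single_head_identity_projections_reduce_to_attention(self, rng):
        d = 4
        eye = Tensor(np.eye(d))
        params = AttentionParams(w_q=Tensor(np.eye(d)[None]),
                                 w_k=Tensor(np.eye(d)[None]),
                                 w_v=Tensor(np.eye(d)[None]), w_o=eye)
        x = rng.normal(size=(5, d))
        np.testing.assert_allclose(mhsa(x, params),
                                   scaled_dot_attention(x, x, x), atol=1e-12)

    @pytest.mark.parametrize("h,d_model,n", [(2, 6, 5), (4, 8, 7), (1, 3, 4)])
    def test_matches_head_by_head_oracle(self, rng, h, d_model, n):
        x = rng.normal(size=(n, d_model))
        params = random_attention_params(rng, h, d_model)
        np.testing.assert_allclose(mhsa(x, params), mhsa_loop_oracle(x, params),
                                   atol=1e-6)

    def test_permutation_equivariance(self, rng):
        """Permuting token order permutes the output rows identically."""
        x = rng.normal(size=(6, 8))
        params = random_attention_params(rng, 2, 8)
        perm = rng.permutation(6)
        np.testing.assert_allclose(mhsa(x[perm], params), mhsa(x, params)[perm],
                                   atol=1e-10)

    def test_output_shape_and_default_head_dim(self, rng):
        """h=4, d_model=64 → per-head width 16; output shape = input shape."""
        cfg = ns.ModelConfig(input_shape=(16, 16, 16, 1), n_classes=2,
                             patch_resolution=8)
        assert cfg.head_dim == 16
        x = rng.normal(size=(2, 8, cfg.hidden_size))  # batched
        params = random_attention_params(rng, cfg.n_heads, cfg.hidden_size)
        assert mhsa(x, params).shape == x.shape


class TestConv3d:
    def conv_loop_oracle(self, x, w, b):
        k = w.shape[0]
        p = k // 2
        xp = np.pad(x, ((p, p), (p, p), (p, p), (0, 0)))
        H, W, D, _ = x.shape
        out = np.zeros(x.shape[:3] + (w.shape[-1],))
        for i in range(H):
            for j in range(W):
                for l in range(D):
                    patch = xp[i:i + k, j:j + k, l:l + k, :]
                    out[i, j, l] = np.tensordot(patch, w, axes=4) + b
        return out

    def test_matches_explicit_loop(self, rng):
        x = rng.normal(size=(4, 5, 3, 2))
        w = rng.normal(size=(3, 3, 3, 2, 4))
        b = rng.normal(size=4)
        got = conv3d(Tensor(x[None]), Tensor(w), Tensor(b)).data[0]
        np.testing.assert_allclose(got, self.conv_loop_oracle(x, w, b), atol=1e-10)

    def test_one_cubed_kernel_is_per_voxel_matmul(self, rng):
        """A 1×1×1 kernel acts as an explicit channel-mixing matrix."""
        x = rng.normal(size=(4, 4, 4, 3))
        m = rng.normal(size=(3, 2))
        got = conv3d(Tensor(x[None]), Tensor(m.reshape(1, 1, 1, 3, 2))).data[0]
        np.testing.assert_allclose(got, x @ m, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.normal(size=(1, 3, 3, 3, 2))
        w = rng.normal(size=(3, 3, 3, 2, 2))
        tx, tw = Tensor(x, requires_grad=True), Tensor(w, requires_grad=True)
        conv3d(tx, tw).sum().backward()
        eps = 1e-6
        for t, arr in ((tx, x), (tw, w)):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            arr[idx] += eps
            fp = conv3d(Tensor(x), Tensor(w)).data.sum()
            arr[idx] -= 2 * eps
            fm = conv3d(Tensor(x), Tensor(w)).data.sum()
            arr[idx] += eps
            assert t.grad[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)


class TestNetworkStages:
    def test_encoder_preserves_resolution(self, tiny_model_cfg, rng):
        """No pooling, no striding: spatial shape is unchanged at every depth."""
        net = SegmentationNetwork(tiny_model_cfg)
        x = Tensor(rng.normal(size=(2, 8, 8, 8, 1)).astype(np.float32))
        feats = net.conv_encoder(x)
        assert feats.shape[:4] == (2, 8, 8, 8)
        assert feats.shape[4] == tiny_model_cfg.encoder_channels[-1]

    def test_zero_input_zero_bias_encoder_gives_zero(self, tiny_model_cfg):
        net = SegmentationNetwork(tiny_model_cfg)
        x = Tensor(np.zeros((1, 8, 8, 8, 1), dtype=np.float32))
        assert not net.conv_encoder(x).data.any()

    @pytest.mark.parametrize("p,expected_n", [(8, 512), (16, 64)])
    def test_token_count_follows_geometric_partition(self, p, expected_n):
        """64³ features: P=8 → 512 tokens, P=16 → 64 tokens (coarser grid)."""
        cfg = ns.ModelConfig(input_shape=(64, 64, 64, 1), n_classes=2,
                             patch_resolution=p)
        assert cfg.n_tokens == expected_n

    def test_patch_embed_zero_features_zero_epos_gives_zero_tokens(self, tiny_model_cfg):
        net = SegmentationNetwork(tiny_model_cfg)
        net.params["e_pos"].data[:] = 0
        feats = Tensor(np.zeros((1, 8, 8, 8, 3), dtype=np.float32))
        seq = net.patch_embed(feats)
        assert seq.tokens.shape == (1, 8, tiny_model_cfg.hidden_size)
        assert not seq.tokens.data.any()

    def test_transformer_layer_zero_weights_is_identity(self, tiny_model_cfg, rng):
        """With all block weights zero the residual passes input through."""
        net = SegmentationNetwork(tiny_model_cfg)
        for name, p in net.params.items():
            if name.startswith("tf.0") and not name.endswith((".g",)):
                p.data[:] = 0
        x = rng.normal(size=(1, 8, tiny_model_cfg.hidden_size)).astype(np.float32)
        seq = ns.TokenSequence(tokens=Tensor(x), grid_shape=(2, 2, 2))
        out = net.transformer_layer(seq, 0)
        np.testing.assert_allclose(out.tokens.data, x, atol=1e-7)

    def test_stacked_layers_equal_iterated_application(self, rng):
        cfg = ns.ModelConfig(input_shape=(8, 8, 8, 1), n_classes=3,
                             n_transformer_layers=4, n_heads=2, hidden_size=8,
                             mlp_size=12, dropout_rate=0.0, patch_resolution=4,
                             encoder_channels=(3,), seed=1)
        net = SegmentationNetwork(cfg)
        x = rng.normal(size=(1, 8, cfg.hidden_size)).astype(np.float32)
        seq = ns.TokenSequence(tokens=Tensor(x), grid_shape=(2, 2, 2))
        manual = seq
        for i in range(4):
            manual = net.transformer_layer(manual, i)
        auto = ns.TokenSequence(tokens=Tensor(x), grid_shape=(2, 2, 2))
        for i in range(cfg.n_transformer_layers):
            auto = net.transformer_layer(auto, i)
        np.testing.assert_array_equal(manual.tokens.data, auto.tokens.data)

    def test_res_path_zero_weights_zero_output(self, tiny_model_cfg, rng):
        net = SegmentationNetwork(tiny_model_cfg)
        for name, p in net.params.items():
            if name.startswith("res."):
                p.data[:] = 0
        feats = Tensor(rng.normal(size=(1, 8, 8, 8, 3)).astype(np.float32))
        assert not net.res_path(feats).data.any()

    def test_res_path_hand_computed_sum_of_branches(self, rng):
        """n_blocks=1 with hand-set 1×1×1-equivalent kernels on a 2³ toy."""
        cfg = ns.ModelConfig(input_shape=(8, 8, 8, 1), n_classes=2,
                             n_transformer_layers=1, n_heads=1, hidden_size=8,
                             mlp_size=8, dropout_rate=0.0, patch_resolution=2,
                             encoder_channels=(2,), seed=0)
        net = SegmentationNetwork(cfg)
        w3 = np.zeros((3, 3, 3, 2, 2))
        w3[1, 1, 1] = [[2.0, 0.0], [0.0, 0.5]]  # center tap only
        m1 = np.array([[0.0, 1.0], [1.0, 0.0]])
        net.params["res.0.conv3.w"].data = w3.astype(np.float32)
        net.params["res.0.conv1.w"].data = m1.reshape(1, 1, 1, 2, 2).astype(np.float32)
        net.params["res.0.conv3.b"].data[:] = 0
        net.params["res.0.conv1.b"].data[:] = 0
        x = rng.normal(size=(2, 2, 2, 2))
        out = net.res_path(Tensor(x[None].astype(np.float32))).data[0]
        expected = np.maximum(x @ np.array([[2.0, 0], [0, 0.5]]) + x @ m1, 0)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_upsample_constant_grid_stays_constant(self):
        """Nearest-neighbour upsampling of a constant grid is constant."""
        x = np.full((1, 2, 2, 2, 3), 1.7, dtype=np.float32)
        out = upsample2(x)
        assert out.shape == (1, 4, 4, 4, 3)
        np.testing.assert_allclose(out, 1.7)

    def test_decoder_stage_count_and_channels(self):
        cfg = ns.ModelConfig(input_shape=(64, 64, 64, 1), n_classes=5,
                             patch_resolution=8)
        assert cfg.n_upsample_stages == 3  # ×2³ recovers 64³ from the 8³ grid
        net = SegmentationNetwork(cfg)
        assert net.params["head.w"].shape[-1] == 5

    def test_layer_norm_gradcheck(self, rng):
        x = Tensor(rng.normal(size=(3, 5)), requires_grad=True)
        g = Tensor(rng.normal(size=5), requires_grad=True)
        b = Tensor(rng.normal(size=5), requires_grad=True)
        (layer_norm(x, g, b, 1e-4) ** 2.0).sum().backward()
        xv = x.data
        eps = 1e-6
        idx = (1, 2)
        xv[idx] += eps
        fp = float((layer_norm(Tensor(xv), Tensor(g.data), Tensor(b.data), 1e-4)
                    .data ** 2).sum())
        xv[idx] -= 2 * eps
        fm = float((layer_norm(Tensor(xv), Tensor(g.data), Tensor(b.data), 1e-4)
                    .data ** 2).sum())
        xv[idx] += eps
        assert x.grad[idx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4)


class TestForward:
    def test_end_to_end_shape_and_probability_contract(self, tiny_model_cfg, rng):
        """(8,8,8) in → (8,8,8,S+1) out; per-voxel probabilities sum to 1."""
        net = SegmentationNetwork(tiny_model_cfg)
        probs = net.forward(rng.random((8, 8, 8), dtype=np.float32)).data
        assert probs.shape == (1, 8, 8, 8, 3)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_forward_deterministic_for_fixed_seed(self, tiny_model_cfg, rng):
        x = rng.random((8, 8, 8), dtype=np.float32)
        a = SegmentationNetwork(tiny_model_cfg).forward(x).data
        b = SegmentationNetwork(tiny_model_cfg).forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_biased_head_dominates_argmax(self, tiny_model_cfg, rng):
        """A large final-layer bias on one class wins argmax everywhere."""
        net = SegmentationNetwork(tiny_model_cfg)
        net.params["head.b"].data[:] = 0
        net.params["head.b"].data[1] = 50.0
        pred = net.predict_labels(rng.random((8, 8, 8), dtype=np.float32))
        assert (pred == 1).all()

    def test_checkpoint_round_trip(self, tiny_model_cfg, tmp_path, rng):
        net = SegmentationNetwork(tiny_model_cfg)
        x = rng.random((8, 8, 8), dtype=np.float32)
        before = net.forward(x).data
        net.save(tmp_path / "ckpt.npz")
        loaded = SegmentationNetwork.load(tmp_path / "ckpt.npz")
        assert loaded.cfg == tiny_model_cfg
        np.testing.assert_array_equal(loaded.forward(x).data, before)

    @pytest.mark.parametrize("bad", [
        dict(patch_resolution=5),                      # not a power of two
        dict(patch_resolution=16, input_shape=(8, 8, 8, 1)),  # P doesn't divide
        dict(hidden_size=10, n_heads=4),               # heads don't divide
        dict(dropout_rate=1.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        kwargs = dict(input_shape=(16, 16, 16, 1), n_classes=2)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ns.ModelConfig(**kwargs)
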