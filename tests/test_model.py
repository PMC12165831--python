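"""End-to-end network: attention, encoder blocks, pooling, heads, loss."""

import numpy as np
import pytest

from kansformer_epi import autodiff as ad
from kansformer_epi.autodiff import Tensor
from kansformer_epi.model import (ForwardState, KansformerEPI, ModelConfig,
                                  aggregate, combined_loss, load_checkpoint,
                                  save_checkpoint)
from kansformer_epi.nn import MultiheadAttention


def tiny_cfg(**kw):
    base = dict(in_channels=4, bins=100, cnn_channels=8, kernel=5, pool=10,
                hidden=8, encoder_layers=1, heads=2, ff_hidden=8,
                attn_pool_s=4, attn_pool_r=2, head_dims=(8, 4))
    base.update(kw)
    return ModelConfig(**base)


class TestMultiheadAttention:
    def test_rows_sum_to_one(self, rng):
        mha = MultiheadAttention(8, 2, rng)
        _, attn = mha(Tensor(rng.normal(size=(3, 5, 8))), return_weights=True)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_single_token(self, rng):
        mha = MultiheadAttention(4, 1, rng)
        z = rng.normal(size=(1, 1, 4))
        out, attn = mha(Tensor(z), return_weights=True)
        assert np.allclose(attn.data, 1.0)
        v = z[0] @ mha.w_v.weight.data
        want = v @ mha.w_out.weight.data + mha.w_out.bias.data
        assert np.abs(out.data[0] - want).max() < 1e-12

    def test_hand_computed_three_token_example(self, rng):
        """l=3, h=2, one head: softmax(QK^T/sqrt(2))V matches by hand."""
        mha = MultiheadAttention(2, 1, rng)
        z = rng.normal(size=(1, 3, 2))
        q = z[0] @ mha.w_q.weight.data
        k = z[0] @ mha.w_k.weight.data
        v = z[0] @ mha.w_v.weight.data
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        want = (attn @ v) @ mha.w_out.weight.data + mha.w_out.bias.data
        got = mha(Tensor(z)).data[0]
        assert np.abs(got - want).max() < 1e-8

    def test_literal_mv_variant_differs(self, rng):
        z = rng.normal(size=(1, 3, 4))
        a = MultiheadAttention(4, 1, np.random.default_rng(0))
        b = MultiheadAttention(4, 1, np.random.default_rng(0), literal_mv=True)
        assert not np.allclose(a(Tensor(z)).data, b(Tensor(z)).data)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MultiheadAttention(7, 2, rng)


class TestBackbone:
    def test_pooled_length(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        z = model.backbone(Tensor(rng.normal(size=(2, 100, 4))))
        assert z.shape == (2, 10, 8)

    def test_full_scale_pool_arithmetic(self):
        cfg = ModelConfig()        # 5000 bins, pool 10
        assert cfg.pooled_length == 500

    def test_indivisible_length_errors(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.backbone(Tensor(rng.normal(size=(1, 105, 4))))

    def test_cnn_pool_locality(self, rng):
        """Pre-LSTM features at pooled position t ignore far-away input."""
        model = KansformerEPI(tiny_cfg(), seed=0)
        x1 = rng.normal(size=(1, 100, 4))
        x2 = x1.copy()
        x2[0, 50:] += 5.0       # outside the receptive field of position 0
        def cnn_pool(x):
            with ad.no_grad():
                return model.pool(ad.relu(model.conv(
                    Tensor(x).transpose(0, 2, 1)))).data
        # pooled position 0 covers bins 0..9 + kernel halo 2 -> bins <= 11
        assert np.allclose(cnn_pool(x1)[0, :, 0], cnn_pool(x2)[0, :, 0])


class TestKansformerBlock:
    def test_identity_when_residual_branches_zeroed(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        block = model.blocks[0]
        block.mha.w_out.weight.data[:] = 0
        block.mha.w_out.bias.data[:] = 0
        for layer in block.kan.layers:
            layer.coeff.data[:] = 0
            layer.w_base.data[:] = 0
        z = rng.normal(size=(2, 10, 8))
        assert np.allclose(block(Tensor(z)).data, z)

    def test_output_shape(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        out = model.blocks[0](Tensor(rng.normal(size=(3, 10, 8))))
        assert out.shape == (3, 10, 8)

    def test_kan_sublayer_is_positionwise(self, rng):
        """Permuting sequence positions permutes the KAN sub-layer output."""
        model = KansformerEPI(tiny_cfg(), seed=0)
        kan = model.blocks[0].kan
        z = rng.normal(size=(1, 10, 8))
        perm = rng.permutation(10)
        out = kan(Tensor(z)).data
        out_perm = kan(Tensor(z[:, perm])).data
        assert np.allclose(out[:, perm], out_perm)


class TestAttentionPoolAndAggregate:
    def test_rows_sum_to_one_and_convexity(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        h0 = rng.normal(size=(2, 10, 8))
        a_s, h1 = model.attn_pool(Tensor(h0))
        assert np.allclose(a_s.data.sum(axis=-1), 1.0, atol=1e-5)
        # convex-combination bounds per column
        assert (h1.data <= h0.max(axis=1, keepdims=True) + 1e-9).all()
        assert (h1.data >= h0.min(axis=1, keepdims=True) - 1e-9).all()

    def test_identical_rows_fixed_point(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        v = rng.normal(size=8)
        h0 = np.tile(v, (1, 10, 1))
        _, h1 = model.attn_pool(Tensor(h0))
        assert np.allclose(h1.data, v)

    def test_weighted_sum_matches_loop(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        h0 = rng.normal(size=(1, 10, 8))
        a_s, h1 = model.attn_pool(Tensor(h0))
        want = np.zeros((2, 8))
        for r in range(2):
            for l in range(10):
                want[r] += a_s.data[0, r, l] * h0[0, l]
        assert np.abs(h1.data[0] - want).max() < 1e-10

    def test_aggregate_single_row(self, rng):
        h1 = rng.normal(size=(1, 1, 8))
        h_e = Tensor(rng.normal(size=(1, 8)))
        h_p = Tensor(rng.normal(size=(1, 8)))
        out = aggregate(Tensor(h1), h_e, h_p).data
        assert np.allclose(out[0, :8], h1[0, 0])      # avg == the row
        assert np.allclose(out[0, 8:16], h1[0, 0])    # max == the row

    def test_aggregate_two_row_closed_form(self):
        v = np.abs(np.random.default_rng(0).normal(size=8))
        h1 = np.stack([np.zeros(8), v])[None]
        out = aggregate(Tensor(h1), Tensor(np.zeros((1, 8))),
                        Tensor(np.zeros((1, 8)))).data
        assert np.allclose(out[0, :8], v / 2)
        assert np.allclose(out[0, 8:16], v)           # nonnegative v

    def test_aggregate_width_contract(self, rng):
        cfg = tiny_cfg(hidden=64, heads=4, cnn_channels=16)
        model = KansformerEPI(cfg, seed=0)
        p, d_p, state = model.forward(
            rng.normal(size=(2, 100, 4)), np.array([5, 50]),
            np.array([80, 20]), return_state=True)
        assert state.H.shape == (2, 256)

    def test_anchor_out_of_range_errors(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0)
        with pytest.raises(IndexError, match="anchor"):
            model.forward(rng.normal(size=(1, 100, 4)),
                          np.array([100]), np.array([0]))


class TestHeads:
    def test_zero_parameter_heads(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0).eval()
        for head in (model.head_class, model.head_dist):
            for layer in head.layers:
                layer.coeff.data[:] = 0
                layer.w_base.data[:] = 0
        p, d_p = model.forward(rng.normal(size=(2, 100, 4)),
                               np.array([5, 6]), np.array([80, 70]))
        assert np.allclose(p.data, 0.5)       # sigmoid(0)
        assert np.allclose(d_p.data, 0.0)

    def test_probability_range(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=1).eval()
        p, _ = model.forward(rng.normal(size=(8, 100, 4)),
                             rng.integers(0, 100, 8), rng.integers(0, 100, 8))
        assert ((p.data > 0) & (p.data < 1)).all()

    def test_heads_match_kan_forward_composition(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=0).eval()
        h = rng.normal(size=(3, 32))
        p, d_p = model.heads_forward(Tensor(h))
        want_p = 1 / (1 + np.exp(-model.head_class(Tensor(h)).data[:, 0]))
        want_d = model.head_dist(Tensor(h)).data[:, 0]
        assert np.allclose(p.data, want_p)
        assert np.allclose(d_p.data, want_d)


class TestCombinedLoss:
    def test_perfect_predictions_near_zero(self):
        p = Tensor(np.array([1.0, 0.0, 1.0]))
        d = Tensor(np.array([0.3, 0.5, 0.2]))
        lc, ld, total = combined_loss(p, [1, 0, 1], d, [0.3, 0.5, 0.2])
        assert total.item() < 1e-5

    def test_single_sample_ln2(self):
        lc, ld, total = combined_loss(Tensor(np.array([0.5])), [1],
                                      Tensor(np.array([0.4])), [0.4])
        assert lc.item() == pytest.approx(np.log(2), abs=1e-12)
        assert ld.item() == 0
        assert total.item() == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_per_sample_loop(self, rng):
        n = 16
        p = np.clip(rng.random(n), 1e-3, 1 - 1e-3)
        y = rng.integers(0, 2, n)
        dp, dt = rng.random(n), rng.random(n)
        lc, ld, total = combined_loss(Tensor(p), y, Tensor(dp), dt)
        want_lc = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                            for yi, pi in zip(y, p)])
        want_ld = np.mean([(a - b) ** 2 for a, b in zip(dp, dt)])
        assert lc.item() == pytest.approx(want_lc, rel=1e-12)
        assert ld.item() == pytest.approx(want_ld, rel=1e-12)
        assert total.item() == pytest.approx(want_lc + want_ld, rel=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            combined_loss(Tensor(np.array([0.5])), [1, 0],
                          Tensor(np.array([0.1])), [0.1])


class TestModelInvariants:
    def test_eval_forward_deterministic(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=2).eval()
        x = rng.normal(size=(4, 100, 4))
        e, p = rng.integers(0, 100, 4), rng.integers(0, 100, 4)
        with ad.no_grad():
            a, _ = model.forward(x, e, p)
            b, _ = model.forward(x, e, p)
        assert np.array_equal(a.data, b.data)

    def test_gradient_reaches_every_parameter(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=3)
        x = rng.normal(size=(4, 100, 4))
        p, d_p = model.forward(x, rng.integers(0, 100, 4),
                               rng.integers(0, 100, 4))
        _, _, loss = combined_loss(p, rng.integers(0, 2, 4), d_p,
                                   rng.random(4))
        model.zero_grad()
        loss.backward()
        for name, param in model.named_parameters():
            assert param.grad is not None, name
            assert np.abs(param.grad).sum() > 0, name

    def test_forward_state_invariants_across_seeds(self, rng):
        model = KansformerEPI(tiny_cfg(), seed=4).eval()
        for trial in range(20):
            r = np.random.default_rng(trial)
            x = r.normal(size=(2, 100, 4))
            p, d_p, state = model.forward(x, r.integers(0, 100, 2),
                                          r.integers(0, 100, 2),
                                          return_state=True)
            assert np.allclose(state.A_s.sum(axis=-1), 1.0, atol=1e-5)
            assert ((state.p >= 0) & (state.p <= 1)).all()
            assert state.H.shape == (2, 4 * 8)
            assert state.H1.shape == (2, 2, 8)

    def test_overfits_small_batch(self):
        """The full architecture drives L_class below 0.05 on 32 fixed pairs."""
        from kansformer_epi.optim import AdamW
        r = np.random.default_rng(0)
        model = KansformerEPI(tiny_cfg(encoder_dropout=0.0, dropout=0.0),
                              seed=5)
        x = r.normal(size=(32, 100, 4))
        e, pb = r.integers(0, 100, 32), r.integers(0, 100, 32)
        y = r.integers(0, 2, 32)
        dt = r.random(32)
        opt = AdamW(model.parameters(), lr=3e-3, weight_decay=0.0)
        lc = np.inf
        for _ in range(500):
            p, d_p = model.forward(x, e, pb)
            l_class, _, loss = combined_loss(p, y, d_p, dt)
            opt.zero_grad()
            loss.backward()
            opt.step()
            lc = l_class.item()
            if lc < 0.05:
                break
        assert lc < 0.05

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = KansformerEPI(tiny_cfg(), seed=6).eval()
        x = rng.normal(size=(2, 100, 4))
        e, p_idx = np.array([5, 20]), np.array([60, 90])
        p0, _ = model.forward(x, e, p_idx)
        save_checkpoint(tmp_path / "m.npz", model,
                        normalizer_dict={"mean": [0], "std": [1]},
                        channels=["a", "b", "c", "d"])
        back, meta = load_checkpoint(tmp_path / "m.npz")
        back.eval()
        p1, _ = back.forward(x, e, p_idx)
        assert np.array_equal(p0.data, p1.data)
        assert meta["channels"] == ["a", "b", "c", "d"]


class TestModelConfig:
    @pytest.mark.parametrize("kw", [
        {"hidden": 63},                  # odd: cannot split directions
        {"hidden": 64, "heads": 6},      # not divisible by heads
        {"bins": 101},                   # not divisible by pool
        {"encoder_layers": 0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)

    def test_roundtrip_dict(self):
        cfg = ModelConfig.small()
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg
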