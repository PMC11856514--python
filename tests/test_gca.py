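"""Character/phrase RNNs, multi-head attention, and the gating units."""

import numpy as np
import pytest

from gcaner.autodiff import Tensor
from gcaner.gca import (AttentionParams, CharRNNParams, GateParams, GCAConfig,
                        PhraseRNNParams, SegmentationError, attention_weights,
                        char_rnn, emissions, gate_fuse_1, gate_fuse_2,
                        gca_forward, init_gca, multi_head_attention,
                        phrase_rnn, segment)


def t(x):
    return Tensor(np.asarray(x, dtype=float))


def char_params(w_hh, w_xh, b):
    return CharRNNParams(t(w_hh), t(w_xh), t(b))


def phrase_params(w_hh, w_yh, b):
    return PhraseRNNParams(t(w_hh), t(w_yh), t(b))


class TestCharRNN:
    def test_zero_weights_give_zero_states(self):
        p = char_params(np.zeros((2, 2)), np.zeros((3, 2)), np.zeros(2))
        out = char_rnn(np.ones((4, 3)), p)
        assert np.allclose(out.data, 0.0)

    def test_matches_scalar_hand_recurrence(self):
        """n=2, hidden dim 1: two steps of h = tanh(w*h + u*x + b) by hand."""
        w, u, b = 0.5, 2.0, 0.1
        x = np.array([[1.0], [-0.5]])
        h1 = np.tanh(u * 1.0 + b)
        h2 = np.tanh(w * h1 + u * (-0.5) + b)
        out = char_rnn(x, char_params([[w]], [[u]], [b]))
        assert np.allclose(out.data, [[h1], [h2]], atol=1e-12)

    def test_converges_to_fixed_point_on_constant_input(self):
        """With spectral norm < 1, a long constant input drives the state to
        the fixed point h* = tanh(W h* + U x + b) found by iteration."""
        rng = np.random.default_rng(3)
        w = rng.standard_normal((3, 3)) * 0.2
        u = rng.standard_normal((3, 3)) * 0.3
        b = rng.standard_normal(3) * 0.1
        x = rng.standard_normal(3)
        h_star = np.zeros(3)
        for _ in range(10000):
            h_star = np.tanh(h_star @ w + x @ u + b)
        out = char_rnn(np.tile(x, (200, 1)), char_params(w, u, b))
        assert np.allclose(out.data[-1], h_star, atol=1e-8)

    def test_non_finite_input_rejected(self):
        p = char_params(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="non-finite"):
            char_rnn(np.array([[np.nan, 0.0]]), p)


class TestSegment:
    @pytest.mark.parametrize("n,k,expected", [
        (10, 2, [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10)]),
        (5, 2, [(0, 2), (2, 4), (4, 5)]),
        (3, 5, [(0, 3)]),
    ])
    def test_fixed_ngram_tiling(self, n, k, expected):
        assert segment(n, "fixed-ngram", k) == expected

    def test_k1_gives_singletons(self):
        assert segment(4, k=1) == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_external_validated(self):
        assert segment(5, "external",
                       intervals=[(0, 3), (3, 5)]) == [(0, 3), (3, 5)]

    @pytest.mark.parametrize("intervals", [
        [(0, 2), (3, 5)],        # gap
        [(0, 3), (2, 5)],        # overlap
        [(0, 3)],                # short
        [(0, 6)],                # beyond n
    ])
    def test_external_rejects_non_tilings(self, intervals):
        with pytest.raises(SegmentationError):
            segment(5, "external", intervals=intervals)


class TestPhraseRNN:
    def test_k1_segmentation_degenerates_to_char_recurrence(self):
        """Singleton segments feed y_t = h_t; with tied weights the phrase
        RNN is literally a recurrence over the character states."""
        rng = np.random.default_rng(0)
        h = rng.standard_normal((5, 2))
        w_hh, w_yh, b = (rng.standard_normal((2, 2)) * 0.3,
                         rng.standard_normal((2, 2)) * 0.3, rng.standard_normal(2))
        out = phrase_rnn(h, segment(5, k=1), phrase_params(w_hh, w_yh, b))
        expect = char_rnn(h, char_params(w_hh, w_yh, b))
        assert np.allclose(out.data, expect.data, atol=1e-12)

    def test_single_global_segment_pools_everything(self):
        rng = np.random.default_rng(1)
        h = rng.standard_normal((6, 3))
        p = phrase_params(np.zeros((3, 3)), np.eye(3), np.zeros(3))
        out = phrase_rnn(h, [(0, 6)], p)
        expect = np.tanh(h.mean(axis=0))
        assert np.allclose(out.data, np.tile(expect, (6, 1)), atol=1e-12)

    def test_matches_scalar_hand_computation(self):
        """n=4, k=2, scalar dims: pool, two recurrence steps, broadcast."""
        h = np.array([[1.0], [3.0], [-2.0], [0.0]])
        w, u, b = 0.5, 1.0, 0.2
        y1, y2 = 2.0, -1.0                     # segment means
        s1 = np.tanh(u * y1 + b)
        s2 = np.tanh(w * s1 + u * y2 + b)
        out = phrase_rnn(h, segment(4, k=2), phrase_params([[w]], [[u]], [b]))
        assert np.allclose(out.data, [[s1], [s1], [s2], [s2]], atol=1e-12)

    def test_segmentation_length_mismatch_rejected(self):
        p = phrase_params(np.zeros((2, 2)), np.eye(2), np.zeros(2))
        with pytest.raises(SegmentationError):
            phrase_rnn(np.ones((5, 2)), [(0, 2), (2, 4)], p)


def make_attention(rng, m, d, d_k=None):
    d_k = d_k if d_k else d // m
    s = 0.5
    return AttentionParams(
        w_q=t(rng.standard_normal((m, d, d_k)) * s),
        w_k=t(rng.standard_normal((m, d, d_k)) * s),
        w_v=t(rng.standard_normal((m, d, d_k)) * s),
        w_o=t(rng.standard_normal((m * d_k, d)) * s),
    )


class TestAttention:
    def test_single_position_weight_is_one(self):
        rng = np.random.default_rng(2)
        params = make_attention(rng, m=2, d=4)
        x = rng.standard_normal((1, 4))
        out = multi_head_attention(x, params)
        manual = np.concatenate([x @ params.w_v.data[i] for i in range(2)],
                                axis=-1) @ params.w_o.data
        assert np.allclose(out.data, manual, atol=1e-12)

    def test_identical_keys_average_the_values(self):
        """When every key row is equal the softmax is uniform and the
        attended value is the mean of the projected values."""
        rng = np.random.default_rng(4)
        params = make_attention(rng, m=1, d=3, d_k=3)
        params.w_k = t(np.zeros((1, 3, 3)))   # all keys identical (zero)
        x = rng.standard_normal((5, 3))
        out = multi_head_attention(x, params)
        mean_v = (x @ params.w_v.data[0]).mean(axis=0)
        expect = np.tile(mean_v, (5, 1)) @ params.w_o.data
        assert np.allclose(out.data, expect, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        """n=2, one head, d_k=2: softmax and products done by hand."""
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        wq = np.array([[1.0, 0.5], [0.0, 1.0]])
        wk = np.array([[0.5, 0.0], [1.0, 1.0]])
        wv = np.array([[1.0, 2.0], [0.0, 1.0]])
        wo = np.eye(2)
        q, k, v = x @ wq, x @ wk, x @ wv
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        expect = a @ v
        params = AttentionParams(t(wq[None]), t(wk[None]), t(wv[None]), t(wo))
        out = multi_head_attention(x, params)
        assert np.allclose(out.data, expect, atol=1e-12)

    def test_rows_sum_to_one_every_head_and_position(self):
        rng = np.random.default_rng(7)
        params = make_attention(rng, m=4, d=8)
        x = rng.standard_normal((9, 8))
        w = attention_weights(x, params)
        assert w.shape == (4, 9, 9)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        params = make_attention(rng, m=2, d=4)
        with pytest.raises(ValueError):
            multi_head_attention(rng.standard_normal((3, 6)), params)

    def test_padding_mask_excludes_padded_keys(self):
        rng = np.random.default_rng(9)
        params = make_attention(rng, m=2, d=4)
        x = rng.standard_normal((6, 4))
        full = multi_head_attention(x[:4], params).data
        padded = multi_head_attention(
            x[None], params, mask=np.array([[1.0] * 4 + [0.0] * 2])).data
        assert np.allclose(full, padded[0, :4], atol=1e-9)


class TestGates:
    def gate(self, d, w=None, b=None):
        w = np.zeros((2 * d, d)) if w is None else w
        b = np.zeros(d) if b is None else b
        return GateParams(t(w), t(b))

    def test_zero_parameters_give_midpoint(self):
        rng = np.random.default_rng(0)
        h, hp = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        g, fused = gate_fuse_1(h, hp, self.gate(3))
        assert np.allclose(g.data, 0.5)
        assert np.allclose(fused.data, (h + hp) / 2, atol=1e-12)
        g2, fused2 = gate_fuse_2(h, hp, self.gate(3))
        assert np.allclose(fused2.data, (h + hp) / 2, atol=1e-12)

    def test_saturated_gates_pass_one_input_through(self):
        rng = np.random.default_rng(1)
        h, hp = rng.standard_normal((5, 2)), rng.standard_normal((5, 2))
        _, fused = gate_fuse_1(h, hp, self.gate(2, b=np.full(2, 20.0)))
        assert np.allclose(fused.data, hp, atol=1e-6)
        _, fused = gate_fuse_2(h, hp, self.gate(2, b=np.full(2, -20.0)))
        assert np.allclose(fused.data, h, atol=1e-6)

    def test_convex_combination_componentwise(self):
        """1000 random draws: every fused component lies in the closed
        interval between its two inputs, and gates lie in (0, 1)."""
        rng = np.random.default_rng(2)
        for fuse in (gate_fuse_1, gate_fuse_2):
            for _ in range(500):
                d = int(rng.integers(1, 5))
                a = rng.standard_normal((3, d))
                b = rng.standard_normal((3, d))
                params = GateParams(t(rng.standard_normal((2 * d, d))),
                                    t(rng.standard_normal(d)))
                g, fused = fuse(a, b, params)
                assert np.all(g.data > 0) and np.all(g.data < 1)
                lo, hi = np.minimum(a, b), np.maximum(a, b)
                assert np.all(fused.data >= lo - 1e-12)
                assert np.all(fused.data <= hi + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gate_fuse_1(np.ones((3, 2)), np.ones((3, 3)), self.gate(2))


class TestEmissionsAndForward:
    def test_zero_projection_gives_zero_emissions(self):
        out = emissions(np.ones((4, 3)), t(np.zeros((3, 5))), t(np.zeros(5)))
        assert np.allclose(out.data, 0.0)
        single = emissions(np.ones((4, 3)), t(np.zeros((3, 1))), t(np.zeros(1)))
        assert single.shape == (4, 1)

    def test_no_gca_equals_plain_encoder_head(self):
        """The no_gca ablation reproduces a direct projection of the encoder
        states — a plain encoder-to-CRF model's emissions."""
        rng = np.random.default_rng(11)
        cfg = GCAConfig(model_dim=6, heads=2, ablation="no_gca")
        params = init_gca(4, 3, cfg, np.random.default_rng(0))
        states = rng.standard_normal((7, 4))
        out = gca_forward(states, params, cfg)
        proj = states @ params.proj_in_w.data + params.proj_in_b.data
        expect = proj @ params.emit_w.data + params.emit_b.data
        assert np.allclose(out.data, expect, atol=1e-12)

    def test_no_attention_changes_only_the_fused_state(self):
        rng = np.random.default_rng(12)
        states = rng.standard_normal((6, 4))
        full_cfg = GCAConfig(model_dim=6, heads=2, ablation="none")
        params = init_gca(4, 3, full_cfg, np.random.default_rng(1))
        _, full = gca_forward(states, params, full_cfg, return_states=True)
        abl_cfg = GCAConfig(model_dim=6, heads=2, ablation="no_attention")
        _, abl = gca_forward(states, params, abl_cfg, return_states=True)
        # shared lower layers are identical; only the fused output differs
        assert np.allclose(full.h.data, abl.h.data, atol=1e-12)
        assert np.allclose(full.fused1.data, abl.fused1.data, atol=1e-12)
        assert np.allclose(abl.fused2.data, abl.fused1.data, atol=1e-12)

    def test_forward_deterministic(self):
        rng = np.random.default_rng(13)
        cfg = GCAConfig(model_dim=8, heads=4)
        params = init_gca(4, 5, cfg, np.random.default_rng(2))
        states = rng.standard_normal((10, 4))
        a = gca_forward(states, params, cfg).data
        b = gca_forward(states, params, cfg).data
        assert np.array_equal(a, b)

    def test_batched_equals_per_sentence(self):
        """The masked batched path agrees with per-sentence forwards."""
        rng = np.random.default_rng(14)
        cfg = GCAConfig(model_dim=6, heads=2, segment_k=2)
        params = init_gca(4, 3, cfg, np.random.default_rng(3))
        lens = [5, 3, 8]
        n = max(lens)
        states = np.zeros((3, n, 4))
        mask = np.zeros((3, n))
        singles = []
        for b, ln in enumerate(lens):
            s = rng.standard_normal((ln, 4))
            states[b, :ln] = s
            mask[b, :ln] = 1.0
            singles.append(gca_forward(s, params, cfg).data)
        batched = gca_forward(states, params, cfg, mask=mask).data
        for b, ln in enumerate(lens):
            assert np.allclose(batched[b, :ln], singles[b], atol=1e-9)

    def test_head_count_must_divide_model_dim(self):
        with pytest.raises(ValueError):
            GCAConfig(model_dim=6, heads=4)
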