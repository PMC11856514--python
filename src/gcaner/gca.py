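"""Gated context-aware (GCA) feature stack.

The stack refines encoder states through three levels and fuses them with
two sigmoid gates:

1. a character-level vanilla RNN ``h_t = tanh(W_hh h_{t-1} + W_xh x_t + b)``
   over the (projected) encoder states;
2. a phrase-level RNN over pooled multi-character segments, whose states are
   broadcast back to the token positions they cover;
3. sentence-level multi-head scaled dot-product self-attention.

Gate 1 mixes character and phrase states elementwise,
``g = sigmoid(W_g [h ; h'] + b_g)``, ``h~' = g * h' + (1-g) * h``; gate 2
mixes the attention output into that fusion the same way.  Both gates are
componentwise convex combinations of their inputs by construction.  A final
linear projection turns the fused states into per-label emission scores for
the CRF.

All functions accept either a single sentence ``(n, d)`` or a batch
``(B, n, d)``; the batched path with a validity mask is what training uses,
and it agrees exactly with the per-sentence path at valid positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, astensor, concat, softmax

__all__ = [
    "CharRNNParams", "PhraseRNNParams", "AttentionParams", "GateParams",
    "GCAConfig", "GCAParams", "FusedStates", "SegmentationError",
    "segment", "char_rnn", "phrase_rnn", "multi_head_attention",
    "gate_fuse_1", "gate_fuse_2", "emissions", "init_gca", "gca_forward",
]

ABLATIONS = ("none", "no_attention", "no_gca")


class SegmentationError(ValueError):
    """Segments do not tile the sentence."""


@dataclass
class CharRNNParams:
    w_hh: Tensor   # (d, d)
    w_xh: Tensor   # (d_in, d)
    bias: Tensor   # (d,)


@dataclass
class PhraseRNNParams:
    w_hh: Tensor   # (d, d)
    w_yh: Tensor   # (d, d)
    bias: Tensor   # (d,)


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections stacked as (m, d, d_k), plus W_O (d, d)."""

    w_q: Tensor
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor

    @property
    def heads(self) -> int:
        return self.w_q.shape[0]


@dataclass
class GateParams:
    weight: Tensor  # (2d, d)
    bias: Tensor    # (d,)


@dataclass
class GCAConfig:
    model_dim: int = 256
    heads: int = 4
    segment_k: int = 2
    ablation: str = "none"

    def __post_init__(self):
        if self.model_dim <= 0:
            raise ValueError("model_dim must be positive")
        if self.heads < 1 or self.model_dim % self.heads != 0:
            raise ValueError("head count must divide model_dim")
        if self.segment_k < 1:
            raise ValueError("segment size k must be >= 1")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")


@dataclass
class GCAParams:
    """All learnable weights of the GCA stack."""

    proj_in_w: Tensor     # encoder dim -> model dim
    proj_in_b: Tensor
    char: CharRNNParams
    phrase: PhraseRNNParams
    attention: AttentionParams
    gate1: GateParams
    gate2: GateParams
    emit_w: Tensor        # model dim -> label count
    emit_b: Tensor


@dataclass
class FusedStates:
    """Intermediate states of one forward pass (diagnostics / tests)."""

    h: Tensor          # character-level RNN states
    h_phrase: Tensor   # phrase states broadcast to token positions
    g1: Tensor         # first gate activations, componentwise in (0, 1)
    fused1: Tensor     # h~' = g1*h' + (1-g1)*h
    attended: Tensor   # multi-head attention output H
    g2: Tensor
    fused2: Tensor     # H~ = g2*H + (1-g2)*h~'


# ----------------------------------------------------------------- segments

def segment(n: int, kind: str = "fixed-ngram", k: int = 2,
            intervals: Sequence[tuple[int, int]] | None = None
            ) -> list[tuple[int, int]]:
    """Tile ``[0, n)`` into phrase segments.

    ``fixed-ngram`` produces ceil(n/k) consecutive chunks of size k (the
    last possibly shorter).  ``external`` validates and adopts user-provided
    half-open intervals, e.g. from a phrase segmenter.
    """
    if n < 1:
        raise SegmentationError("sentence must contain at least one token")
    if kind == "fixed-ngram":
        if k < 1:
            raise SegmentationError("segment size k must be >= 1")
        return [(s, min(s + k, n)) for s in range(0, n, k)]
    if kind == "external":
        if intervals is None:
            raise SegmentationError("external segmentation requires intervals")
        pos = 0
        for lo, hi in intervals:
            if lo != pos or hi <= lo:
                raise SegmentationError(
                    f"segments must tile [0, {n}) exactly; got ({lo}, {hi}) "
                    f"where {pos} was expected")
            pos = hi
        if pos != n:
            raise SegmentationError(
                f"segments cover [0, {pos}) but the sentence has {n} tokens")
        return [tuple(iv) for iv in intervals]
    raise SegmentationError(f"unknown segmentation kind {kind!r}")


# --------------------------------------------------------------------- RNNs

def _check_finite(x: Tensor, name: str) -> None:
    if not np.all(np.isfinite(x.data)):
        raise ValueError(f"{name} contains non-finite values")


def _scan_rnn(x: Tensor, w_hh: Tensor, w_in: Tensor, bias: Tensor,
              mask: np.ndarray | None) -> Tensor:
    """tanh recurrence over axis -2; zero initial state; masked update."""
    from .autodiff import stack
    single = x.ndim == 2
    if single:
        x = x.reshape(1, *x.shape)
    batch, n, _ = x.shape
    d = w_hh.shape[0]
    h = Tensor(np.zeros((batch, d)))
    outputs = []
    for t in range(n):
        h_new = (h @ w_hh + x[:, t, :] @ w_in + bias).tanh()
        if mask is not None and not np.all(mask[:, t] == 1.0):
            mt = Tensor(mask[:, t:t + 1])
            h = mt * h_new + (1.0 - mt) * h
        else:
            h = h_new
        outputs.append(h)
    out = stack(outputs, axis=1)
    return out.reshape(*out.shape[1:]) if single else out


def char_rnn(inputs, params: CharRNNParams,
             mask: np.ndarray | None = None) -> Tensor:
    """Left-to-right character-level recurrence with h_0 = 0."""
    x = astensor(inputs)
    _check_finite(x, "char RNN input")
    return _scan_rnn(x, params.w_hh, params.w_xh, params.bias, mask)


def phrase_rnn(char_states, seg: Sequence[tuple[int, int]],
               params: PhraseRNNParams,
               mask: np.ndarray | None = None) -> Tensor:
    """Phrase-level recurrence over pooled segments, broadcast to positions.

    The phrase input ``y_j`` is the mean of the character states inside
    segment j (mask-weighted under padding, so partially padded segments
    pool only their valid characters).  The recurrence runs over the segment
    sequence and each segment's output state is copied back to all its token
    positions, so the elementwise gate fusion sees a phrase state at every t.
    """
    h = astensor(char_states)
    single = h.ndim == 2
    if single:
        h = h.reshape(1, *h.shape)
    batch, n, d = h.shape
    if seg[-1][1] != n or seg[0][0] != 0:
        raise SegmentationError(
            f"segmentation covers [{seg[0][0]}, {seg[-1][1]}) but the "
            f"sentence has {n} positions")
    # Pool characters into per-segment means.
    pooled = []
    seg_mask = None if mask is None else np.zeros((batch, len(seg)))
    for j, (lo, hi) in enumerate(seg):
        if mask is None:
            pooled.append(h[:, lo:hi, :].mean(axis=1))
        else:
            counts = mask[:, lo:hi].sum(axis=1)                 # (B,)
            seg_mask[:, j] = (counts > 0).astype(float)
            weights = mask[:, lo:hi] / np.maximum(counts, 1.0)[:, None]
            pooled.append((h[:, lo:hi, :] * Tensor(weights[:, :, None])).sum(axis=1))
    from .autodiff import stack
    y = stack(pooled, axis=1)                                   # (B, S, d)
    states = _scan_rnn(y, params.w_hh, params.w_yh, params.bias, seg_mask)
    # Broadcast segment states back to token positions.
    pos_to_seg = np.empty(n, dtype=np.int64)
    for j, (lo, hi) in enumerate(seg):
        pos_to_seg[lo:hi] = j
    out = states[:, pos_to_seg, :]
    return out.reshape(*out.shape[1:]) if single else out


# ---------------------------------------------------------------- attention

def multi_head_attention(states, params: AttentionParams,
                         mask: np.ndarray | None = None) -> Tensor:
    """Scaled dot-product self-attention with m heads, no positional encoding.

    Per head i: ``softmax(Q W_i^Q (K W_i^K)^T / sqrt(d_k)) V W_i^V``; head
    outputs are concatenated and projected by W^O.  Order information comes
    from the recurrent layers underneath, so no positional encoding is added.
    Padded key positions (mask 0) are excluded from every softmax.
    """
    x = astensor(states)
    single = x.ndim == 2
    if single:
        x = x.reshape(1, *x.shape)
    batch, n, d = x.shape
    m = params.heads
    d_k = params.w_q.shape[-1]
    if params.w_q.shape[1] != d:
        raise ValueError(
            f"attention projections expect dim {params.w_q.shape[1]}, got {d}")
    heads = []
    bias = None
    if mask is not None:
        bias = np.where(mask[:, None, :] > 0, 0.0, -1e9)        # (B, 1, n)
    for i in range(m):
        q = x @ params.w_q[i]
        k = x @ params.w_k[i]
        v = x @ params.w_v[i]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
        if bias is not None:
            scores = scores + Tensor(bias)
        heads.append(softmax(scores, axis=-1) @ v)
    out = concat(heads, axis=-1) @ params.w_o
    return out.reshape(*out.shape[1:]) if single else out


def attention_weights(states: np.ndarray, params: AttentionParams,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Per-head attention matrices (m, n, n) for one sentence (diagnostics)."""
    x = np.asarray(states, dtype=np.float64)
    d_k = params.w_q.shape[-1]
    rows = []
    for i in range(params.heads):
        q = x @ params.w_q.data[i]
        k = x @ params.w_k.data[i]
        scores = q @ k.T / np.sqrt(d_k)
        if mask is not None:
            scores = scores + np.where(mask[None, :] > 0, 0.0, -1e9)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        rows.append(e / e.sum(axis=-1, keepdims=True))
    return np.stack(rows)


# -------------------------------------------------------------------- gates

def _gate(a: Tensor, b: Tensor, params: GateParams) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"gate inputs must share a shape; got {a.shape} "
                         f"and {b.shape}")
    return (concat([a, b], axis=-1) @ params.weight + params.bias).sigmoid()


def gate_fuse_1(h, h_phrase, params: GateParams) -> tuple[Tensor, Tensor]:
    """g = sigmoid(W_g [h ; h'] + b_g);  h~' = g * h' + (1-g) * h."""
    h, h_phrase = astensor(h), astensor(h_phrase)
    g = _gate(h, h_phrase, params)
    return g, g * h_phrase + (1.0 - g) * h


def gate_fuse_2(fused1, attended, params: GateParams) -> tuple[Tensor, Tensor]:
    """g' = sigmoid(W'_g [h~' ; H] + b'_g);  H~ = g' * H + (1-g') * h~'."""
    fused1, attended = astensor(fused1), astensor(attended)
    g = _gate(fused1, attended, params)
    return g, g * attended + (1.0 - g) * fused1


# ---------------------------------------------------------------- emissions

def emissions(fused, weight: Tensor, bias: Tensor) -> Tensor:
    """Linear projection of the fused states to per-label scores."""
    return astensor(fused) @ weight + bias


# ------------------------------------------------------------ full forward

def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def init_gca(encoder_dim: int, n_labels: int, config: GCAConfig,
             rng: np.random.Generator) -> GCAParams:
    d = config.model_dim
    d_k = d // config.heads
    m = config.heads
    return GCAParams(
        proj_in_w=_uniform(rng, (encoder_dim, d), encoder_dim),
        proj_in_b=Tensor(np.zeros(d), requires_grad=True),
        char=CharRNNParams(_uniform(rng, (d, d), d), _uniform(rng, (d, d), d),
                           Tensor(np.zeros(d), requires_grad=True)),
        phrase=PhraseRNNParams(_uniform(rng, (d, d), d), _uniform(rng, (d, d), d),
                               Tensor(np.zeros(d), requires_grad=True)),
        attention=AttentionParams(
            w_q=_uniform(rng, (m, d, d_k), d),
            w_k=_uniform(rng, (m, d, d_k), d),
            w_v=_uniform(rng, (m, d, d_k), d),
            w_o=_uniform(rng, (d, d), d),
        ),
        gate1=GateParams(_uniform(rng, (2 * d, d), 2 * d),
                         Tensor(np.zeros(d), requires_grad=True)),
        gate2=GateParams(_uniform(rng, (2 * d, d), 2 * d),
                         Tensor(np.zeros(d), requires_grad=True)),
        emit_w=_uniform(rng, (d, n_labels), d),
        emit_b=Tensor(np.zeros(n_labels), requires_grad=True),
    )


def gca_forward(encoder_states, params: GCAParams, config: GCAConfig,
                mask: np.ndarray | None = None,
                return_states: bool = False):
    """Run the full stack: encoder states -> emission scores.

    Ablations: ``no_attention`` bypasses attention and the second gate
    (H~ := h~'); ``no_gca`` bypasses the whole stack and projects encoder
    states straight to emissions — exactly the plain encoder->CRF model.
    The ablation changes only which fused state feeds the emission layer;
    every other contract (shapes, masking, CRF) is unchanged.
    """
    x = astensor(encoder_states)
    single = x.ndim == 2
    if single:
        x = x.reshape(1, *x.shape)
        if mask is not None and mask.ndim == 1:
            mask = mask[None, :]
    proj = x @ params.proj_in_w + params.proj_in_b
    if config.ablation == "no_gca":
        scores = emissions(proj, params.emit_w, params.emit_b)
        return scores.reshape(*scores.shape[1:]) if single else scores
    n = x.shape[1]
    seg = segment(n, kind="fixed-ngram", k=config.segment_k)
    h = char_rnn(proj, params.char, mask=mask)
    hp = phrase_rnn(h, seg, params.phrase, mask=mask)
    g1, fused1 = gate_fuse_1(h, hp, params.gate1)
    if config.ablation == "no_attention":
        attended, g2, fused2 = fused1, g1, fused1
    else:
        attended = multi_head_attention(fused1, params.attention, mask=mask)
        g2, fused2 = gate_fuse_2(fused1, attended, params.gate2)
    scores = emissions(fused2, params.emit_w, params.emit_b)
    if single:
        scores = scores.reshape(*scores.shape[1:])
    if return_states:
        return scores, FusedStates(h, hp, g1, fused1, attended, g2, fused2)
    return scores
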