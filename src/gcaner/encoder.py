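"""Character encoder: trainable embeddings + a bidirectional LSTM.

Each character is mapped to a trainable embedding and run through forward
and backward LSTM recurrences; the contextual state at position t is the
concatenation ``h_t = [h_t_fwd ; h_t_bwd]``, so every position sees both
directions of its sentence.  A pretrained contextual encoder can be plugged
in instead: anything that maps a token list to an ``(n, dim)`` array of
per-position vectors satisfies the same downstream contract (see
:class:`ExternalEncoder`).

Sentences longer than the configured maximum length are never silently
truncated — :func:`split_sentence` chunks them upstream at the nearest
non-entity position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .autodiff import Tensor, concat, stack
from .tagging import TaggedSentence

__all__ = [
    "PAD", "UNK", "Vocabulary", "EncoderConfig", "EncoderStates",
    "LSTMParams", "BiLSTMParams", "ExternalEncoder",
    "build_vocabulary", "init_bilstm", "bilstm_forward", "encode_sequence",
    "split_sentence",
]

PAD = "<pad>"
UNK = "<unk>"


@dataclass
class Vocabulary:
    """Symbol inventory with reserved padding (0) and unknown (1) indices."""

    itos: list[str]
    stoi: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if self.itos[:2] != [PAD, UNK]:
            raise ValueError("indices 0 and 1 are reserved for padding/unknown")
        self.stoi = {s: i for i, s in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def unk_index(self) -> int:
        return 1

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        unk = self.unk_index
        return np.array([self.stoi.get(t, unk) for t in tokens], dtype=np.int64)


def build_vocabulary(corpus: Iterable[TaggedSentence], min_count: int = 1) -> Vocabulary:
    """Count characters and keep those with frequency >= ``min_count``.

    Ordering is deterministic: descending frequency, ties broken by
    codepoint, after the two reserved symbols.
    """
    counts: dict[str, int] = {}
    seen_any = False
    for sent in corpus:
        seen_any = True
        for tok in sent.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    if not seen_any:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    kept = sorted((c for c, k in counts.items() if k >= min_count),
                  key=lambda c: (-counts[c], c))
    return Vocabulary([PAD, UNK] + kept)


@dataclass
class EncoderConfig:
    embedding_dim: int = 128
    hidden_dim: int = 512          # per direction; output dim is twice this
    max_len: int = 512
    kind: str = "embedding+bilstm"  # or "external"

    def __post_init__(self):
        if self.embedding_dim <= 0 or self.hidden_dim <= 0:
            raise ValueError("encoder dimensions must be positive")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.kind not in ("embedding+bilstm", "external"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")


@dataclass
class EncoderStates:
    """Per-position contextual vectors plus the validity mask."""

    states: np.ndarray      # (n, 2*hidden) or (batch, n, 2*hidden)
    lengths: np.ndarray     # per-sentence true lengths
    mask: np.ndarray        # 1.0 at valid positions, 0.0 at padding


@runtime_checkable
class ExternalEncoder(Protocol):
    """Contract for a substituted pretrained encoder."""

    dim: int

    def __call__(self, tokens: list[str]) -> np.ndarray:
        """Return an (len(tokens), dim) array of contextual vectors."""


# --------------------------------------------------------------------- LSTM

@dataclass
class LSTMParams:
    """One direction.  Gate layout along the 4H axis: input, forget, cell, output."""

    w_ih: Tensor   # (input_dim, 4H)
    w_hh: Tensor   # (H, 4H)
    bias: Tensor   # (4H,)


@dataclass
class BiLSTMParams:
    embedding: Tensor        # (vocab, embedding_dim)
    fwd: LSTMParams
    bwd: LSTMParams


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def init_bilstm(vocab_size: int, config: EncoderConfig,
                rng: np.random.Generator) -> BiLSTMParams:
    """Uniform init scaled by 1/sqrt(fan-in); forget-gate bias set to +1."""
    e, h = config.embedding_dim, config.hidden_dim

    def direction() -> LSTMParams:
        bias = np.zeros(4 * h)
        bias[h:2 * h] = 1.0
        return LSTMParams(
            w_ih=_uniform(rng, (e, 4 * h), e),
            w_hh=_uniform(rng, (h, 4 * h), h),
            bias=Tensor(bias, requires_grad=True),
        )

    emb = Tensor(rng.uniform(-1.0 / np.sqrt(e), 1.0 / np.sqrt(e), size=(vocab_size, e)),
                 requires_grad=True)
    emb.data[0] = 0.0  # padding row
    return BiLSTMParams(embedding=emb, fwd=direction(), bwd=direction())


def _lstm_step(x_t: Tensor, h: Tensor, c: Tensor, p: LSTMParams,
               hidden: int) -> tuple[Tensor, Tensor]:
    z = x_t @ p.w_ih + h @ p.w_hh + p.bias
    i = z[:, :hidden].sigmoid()
    f = z[:, hidden:2 * hidden].sigmoid()
    g = z[:, 2 * hidden:3 * hidden].tanh()
    o = z[:, 3 * hidden:].sigmoid()
    c_new = f * c + i * g
    return o * c_new.tanh(), c_new


def _lstm_scan(emb: Tensor, mask: np.ndarray, p: LSTMParams, hidden: int,
               reverse: bool) -> Tensor:
    """Masked recurrence over the time axis of a (B, n, E) batch.

    The state only advances where the mask is 1, so padded positions carry
    the zero initial state and cannot influence (or be influenced by) valid
    positions — padding neutrality is exact, not approximate.
    """
    batch, n, _ = emb.shape
    h = Tensor(np.zeros((batch, hidden)))
    c = Tensor(np.zeros((batch, hidden)))
    order = range(n - 1, -1, -1) if reverse else range(n)
    outputs: list[Tensor | None] = [None] * n
    for t in order:
        h_new, c_new = _lstm_step(emb[:, t, :], h, c, p, hidden)
        m = mask[:, t:t + 1]
        if np.all(m == 1.0):
            h, c = h_new, c_new
        else:
            mt = Tensor(m)
            h = mt * h_new + (1.0 - mt) * h
            c = mt * c_new + (1.0 - mt) * c
        outputs[t] = h
    return stack(outputs, axis=1)


def bilstm_forward(token_ids: np.ndarray, mask: np.ndarray,
                   params: BiLSTMParams, config: EncoderConfig) -> Tensor:
    """Batched encoder pass: (B, n) int ids -> (B, n, 2*hidden) states."""
    emb = params.embedding[token_ids]
    fwd = _lstm_scan(emb, mask, params.fwd, config.hidden_dim, reverse=False)
    bwd = _lstm_scan(emb, mask, params.bwd, config.hidden_dim, reverse=True)
    return concat([fwd, bwd], axis=-1)


def encode_sequence(tokens: list[str], vocab: Vocabulary,
                    params: BiLSTMParams, config: EncoderConfig) -> EncoderStates:
    """Encode one sentence to its (n, 2*hidden) contextual states."""
    n = len(tokens)
    if n == 0:
        raise ValueError("cannot encode an empty token sequence")
    if n > config.max_len:
        raise ValueError(
            f"sequence length {n} exceeds max_len {config.max_len}; split it "
            "upstream (see split_sentence) rather than truncating")
    ids = vocab.encode(tokens)[None, :]
    mask = np.ones((1, n))
    states = bilstm_forward(ids, mask, params, config)
    return EncoderStates(states=states.data[0], lengths=np.array([n]),
                         mask=mask[0])


def split_sentence(sentence: TaggedSentence, max_len: int) -> list[TaggedSentence]:
    """Split an over-length sentence at the nearest O-tagged position.

    The cut point is the O position closest to ``max_len`` from below (so no
    entity is ever severed); if a chunk contains no O at all it is cut hard
    at ``max_len`` as a last resort.
    """
    if len(sentence) <= max_len:
        return [sentence]
    pieces: list[TaggedSentence] = []
    tokens, tags = sentence.tokens, sentence.tags
    start = 0
    while len(tokens) - start > max_len:
        window_end = start + max_len
        cut = None
        for t in range(window_end - 1, start - 1, -1):
            if tags[t] == "O":
                cut = t + 1  # keep the O with the left chunk
                break
        if cut is None or cut == start:
            cut = window_end
        pieces.append(TaggedSentence(tokens[start:cut], tags[start:cut]))
        start = cut
    pieces.append(TaggedSentence(tokens[start:], tags[start:]))
    return pieces
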