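"""Linear-chain CRF with exact inference, plus the composite training loss.

A label path y for emissions e scores
``start[y_1] + sum_t e[t, y_t] + sum_t T[y_{t-1}, y_t] + stop[y_n]``;
the CRF log-likelihood is that score minus the log-partition over all L^n
paths, computed exactly by the forward recursion in log space.  Decoding is
max-sum Viterbi with backpointers; posterior per-position marginals come
from forward–backward.  Training mixes sequence-level CRF negative
log-likelihood with per-position cross-entropy:

    L = alpha * L_CE + (1 - alpha) * L_CRF,    alpha in [0, 1].

Illegal tag transitions (from the BIEO mask) are scored with a large
negative constant rather than a true -inf so arithmetic stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, logsumexp

__all__ = [
    "NEG_INF", "CRFParams", "LossConfig", "LabelDistributions",
    "init_crf", "crf_log_likelihood", "crf_loss_batch", "viterbi",
    "posterior_marginals", "cross_entropy", "composite_loss",
]

NEG_INF = -1e4   # finite stand-in for forbidden transitions


@dataclass
class CRFParams:
    """Transition matrix T[i, j] = score of label j following label i,
    plus explicit learnable start/stop boundary scores."""

    transitions: Tensor          # (L, L)
    start: Tensor                # (L,)
    stop: Tensor                 # (L,)
    mask: np.ndarray | None = None          # allowed label-pair matrix
    start_mask: np.ndarray | None = None
    stop_mask: np.ndarray | None = None

    @property
    def n_labels(self) -> int:
        return self.transitions.shape[0]

    def effective(self) -> tuple[Tensor, Tensor, Tensor]:
        """Scores with masked entries pinned to NEG_INF."""
        t, s, e = self.transitions, self.start, self.stop
        if self.mask is not None:
            t = t * Tensor(self.mask.astype(float)) + Tensor(
                np.where(self.mask, 0.0, NEG_INF))
        if self.start_mask is not None:
            s = s * Tensor(self.start_mask.astype(float)) + Tensor(
                np.where(self.start_mask, 0.0, NEG_INF))
        if self.stop_mask is not None:
            e = e * Tensor(self.stop_mask.astype(float)) + Tensor(
                np.where(self.stop_mask, 0.0, NEG_INF))
        return t, s, e


def init_crf(n_labels: int, rng: np.random.Generator,
             mask: np.ndarray | None = None,
             start_mask: np.ndarray | None = None,
             stop_mask: np.ndarray | None = None) -> CRFParams:
    scale = 0.1
    return CRFParams(
        transitions=Tensor(rng.uniform(-scale, scale, (n_labels, n_labels)),
                           requires_grad=True),
        start=Tensor(rng.uniform(-scale, scale, n_labels), requires_grad=True),
        stop=Tensor(rng.uniform(-scale, scale, n_labels), requires_grad=True),
        mask=mask, start_mask=start_mask, stop_mask=stop_mask,
    )


def _validate_emissions(e: np.ndarray) -> None:
    if e.ndim != 2:
        raise ValueError(f"emissions must be (n, L); got shape {e.shape}")
    if e.shape[0] < 1:
        raise ValueError("emissions must cover at least one position")
    if not np.all(np.isfinite(e)):
        raise ValueError("emissions contain non-finite values")


def crf_log_likelihood(emissions, tags, params: CRFParams) -> Tensor:
    """log P(y | x) for one sentence: gold path score minus log-partition."""
    em = astensor(emissions)
    _validate_emissions(em.data)
    tags = np.asarray(tags, dtype=np.int64)
    n, n_labels = em.shape
    if tags.shape != (n,) or tags.min() < 0 or tags.max() >= n_labels:
        raise ValueError("tag indices do not match the emission matrix")
    trans, start, stop = params.effective()

    gold = start[tags[0]] + em[np.arange(n), tags].sum() + stop[tags[-1]]
    if n > 1:
        gold = gold + trans[tags[:-1], tags[1:]].sum()

    alpha = start + em[0, :]                       # (L,)
    for t in range(1, n):
        # alpha_j = logsumexp_i(alpha_i + T_ij) + e_tj
        alpha = logsumexp(alpha.reshape(-1, 1) + trans, axis=0) + em[t, :]
    log_z = logsumexp(alpha + stop, axis=0)
    return gold - log_z


def crf_loss_batch(emissions: Tensor, tags: np.ndarray, mask: np.ndarray,
                   params: CRFParams) -> Tensor:
    """Summed CRF negative log-likelihood over a padded batch.

    ``emissions`` is (B, n, L); ``mask`` is 1.0 at valid positions and the
    padding is strictly trailing (left-aligned sentences).
    """
    batch, n, n_labels = emissions.shape
    trans, start, stop = params.effective()
    lengths = mask.sum(axis=1).astype(np.int64)
    rows = np.arange(batch)

    gold = (emissions[rows[:, None], np.arange(n)[None, :], tags]
            * Tensor(mask)).sum()
    gold = gold + start[tags[:, 0]].sum() + stop[tags[rows, lengths - 1]].sum()
    if n > 1:
        trans_scores = trans[tags[:, :-1], tags[:, 1:]]        # (B, n-1)
        gold = gold + (trans_scores * Tensor(mask[:, 1:])).sum()

    alpha = start.reshape(1, -1) + emissions[:, 0, :]          # (B, L)
    for t in range(1, n):
        m = mask[:, t]
        if not m.any():
            break
        nxt = logsumexp(alpha.reshape(batch, n_labels, 1) + trans.reshape(1, n_labels, n_labels),
                        axis=1) + emissions[:, t, :]
        if np.all(m == 1.0):
            alpha = nxt
        else:
            mt = Tensor(m[:, None])
            alpha = mt * nxt + (1.0 - mt) * alpha
    log_z = logsumexp(alpha + stop.reshape(1, -1), axis=1)     # (B,)
    return log_z.sum() - gold


def viterbi(emissions, params: CRFParams) -> tuple[list[int], float]:
    """Highest-scoring label path by max-sum dynamic programming.

    Ties break toward the lower label index (argmax returns the first
    maximum).  With a transition mask enabled, forbidden transitions carry
    the NEG_INF score and never appear in the output path.
    """
    em = np.asarray(emissions.data if isinstance(emissions, Tensor) else emissions,
                    dtype=np.float64)
    _validate_emissions(em)
    n, n_labels = em.shape
    trans, start, stop = (p.data for p in params.effective())

    score = start + em[0]
    back = np.zeros((n, n_labels), dtype=np.int64)
    for t in range(1, n):
        cand = score[:, None] + trans            # (from, to)
        back[t] = cand.argmax(axis=0)
        score = cand[back[t], np.arange(n_labels)] + em[t]
    score = score + stop
    last = int(score.argmax())
    path = [last]
    for t in range(n - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    path.reverse()
    return path, float(score.max())


def posterior_marginals(emissions, params: CRFParams) -> np.ndarray:
    """Per-position label posteriors P(y_t = j | x) via forward–backward."""
    em = np.asarray(emissions.data if isinstance(emissions, Tensor) else emissions,
                    dtype=np.float64)
    _validate_emissions(em)
    n, n_labels = em.shape
    trans, start, stop = (p.data for p in params.effective())

    def lse(a, axis):
        m = a.max(axis=axis, keepdims=True)
        return (np.log(np.exp(a - m).sum(axis=axis, keepdims=True)) + m).squeeze(axis)

    fwd = np.zeros((n, n_labels))
    fwd[0] = start + em[0]
    for t in range(1, n):
        fwd[t] = lse(fwd[t - 1][:, None] + trans, axis=0) + em[t]
    bwd = np.zeros((n, n_labels))
    bwd[-1] = stop
    for t in range(n - 2, -1, -1):
        bwd[t] = lse(trans + (em[t + 1] + bwd[t + 1])[None, :], axis=1)
    log_marg = fwd + bwd
    log_marg -= lse(log_marg, axis=1)[:, None]
    return np.exp(log_marg)


# -------------------------------------------------------------------- losses

@dataclass
class LabelDistributions:
    """One-hot truths and predicted row distributions for the CE loss."""

    truth: np.ndarray        # (n, C) one-hot
    predicted: np.ndarray    # (n, C) rows summing to 1
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=np.float64)
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        if self.truth.shape != self.predicted.shape:
            raise ValueError("truth and prediction shapes differ")
        rows = self.predicted.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("predicted rows must each sum to 1 (within 1e-6)")


def cross_entropy(dists: LabelDistributions, reduction: str = "sum") -> float:
    """Per-position cross-entropy, summed over valid positions.

    ``reduction='mean'`` gives the per-token variant used for logging.
    Predicted probabilities are clamped at 1e-12 before the log.
    """
    p = np.clip(dists.predicted, 1e-12, None)
    per_pos = -(dists.truth * np.log(p)).sum(axis=-1)
    if dists.mask is not None:
        per_pos = per_pos * dists.mask
        n_valid = dists.mask.sum()
    else:
        n_valid = per_pos.size
    total = float(per_pos.sum())
    if reduction == "mean":
        return total / max(n_valid, 1)
    if reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return total


def cross_entropy_batch(emissions: Tensor, tags: np.ndarray,
                        mask: np.ndarray) -> Tensor:
    """Differentiable CE from emission scores (softmax rows), summed."""
    logp = emissions - logsumexp(emissions, axis=-1, keepdims=True)
    batch, n, _ = emissions.shape
    gold = logp[np.arange(batch)[:, None], np.arange(n)[None, :], tags]
    return -(gold * Tensor(mask)).sum()


@dataclass
class LossConfig:
    """alpha mixes the two objectives; alpha=0 is a pure CRF model."""

    alpha: float = 0.5
    ce_from_marginals: bool = False   # use CRF posteriors as y-hat instead of softmax

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1]; got {self.alpha}")


def composite_loss(ce, crf, config: LossConfig):
    """L = alpha * L_CE + (1 - alpha) * L_CRF (works on floats or Tensors)."""
    a = config.alpha
    return a * ce + (1.0 - a) * crf
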