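"""Training loop, k-fold cross-validation, and checkpoint/resume.

Optimisation is mini-batch adaptive moment estimation with decoupled weight
decay on the weight matrices (biases and the embedding's padding row are
exempt) and global gradient-norm clipping at 5.0.  Batches group sentences
of similar length to limit padding; batch order is reshuffled every epoch
with a seed derived from (run seed, epoch), so an interrupted run resumed
from a checkpoint replays the identical batch stream and reproduces the
uninterrupted run's metrics exactly.

Each epoch logs one line — epoch, mean train loss, validation P/R/F1 — and
the best-validation-F1 checkpoint is retained.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import RunConfig
from .evaluation import evaluate_corpus, prf
from .model import GCATagger, make_batch
from .tagging import TaggedSentence

__all__ = ["FoldPlan", "make_folds", "AdamW", "TrainResult", "train",
           "cross_validate", "predict_corpus"]


# -------------------------------------------------------------------- folds

@dataclass
class FoldPlan:
    """k-fold split: each sentence validates in exactly one fold."""

    k: int
    seed: int
    folds: list[tuple[list[int], list[int]]]   # (train_idx, val_idx) per fold


def make_folds(corpus: list[TaggedSentence], k: int, seed: int) -> FoldPlan:
    n = len(corpus)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= corpus size; got k={k}, n={n}")
    order = np.random.default_rng(seed).permutation(n)
    parts = np.array_split(order, k)       # sizes differ by at most one
    folds = []
    for i in range(k):
        val = sorted(int(j) for j in parts[i])
        train = sorted(int(j) for p in parts[:i] + parts[i + 1:] for j in p)
        folds.append((train, val))
    return FoldPlan(k=k, seed=seed, folds=folds)


# ---------------------------------------------------------------- optimizer

class AdamW:
    """Adaptive moment estimation with decoupled weight decay."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)          # [(name, Tensor)]
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(t.data) for name, t in self.params}
        self.v = {name: np.zeros_like(t.data) for name, t in self.params}

    @staticmethod
    def _decayed(name: str, tensor) -> bool:
        return tensor.data.ndim >= 2 and not name.endswith("embedding")

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name, p in self.params:
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1 ** self.t)
            v_hat = self.v[name] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay and self._decayed(name, p):
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for k in self.m:
            self.m[k][...] = state["m"][k]
            self.v[k][...] = state["v"][k]


def clip_gradients(params, max_norm: float) -> float:
    total = 0.0
    for _, p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for _, p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


# ----------------------------------------------------------------- training

def _length_batches(indices: list[int], corpus: list[TaggedSentence],
                    batch_size: int) -> list[list[int]]:
    by_len = sorted(indices, key=lambda i: (len(corpus[i]), i))
    return [by_len[i:i + batch_size] for i in range(0, len(by_len), batch_size)]


@dataclass
class TrainResult:
    model: GCATagger
    history: list[dict] = field(default_factory=list)
    best_f1: float = 0.0
    best_epoch: int = -1


def _evaluate(model: GCATagger, sentences: list[TaggedSentence]
              ) -> tuple[float, float, float]:
    gold = [s.gold_spans if s.gold_spans is not None else s.spans
            for s in sentences]
    pred = model.predict_spans(sentences)
    return prf(evaluate_corpus(gold, pred))


def train(config: RunConfig, corpus: list[TaggedSentence],
          val: list[TaggedSentence] | None = None,
          model: GCATagger | None = None,
          checkpoint_path: str | Path | None = None,
          start_epoch: int = 0,
          optimizer_state: dict | None = None,
          log=None) -> TrainResult:
    """Train on ``corpus``; evaluate entity F1 on ``val`` after each epoch.

    When ``val`` is None a 1/``config.folds`` tail split of the (shuffled)
    corpus is held out.  Passing ``model``/``start_epoch``/``optimizer_state``
    resumes an interrupted run; the derived per-epoch shuffling seeds make
    the resumed run identical to an uninterrupted one.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    log = log if log is not None else sys.stderr
    if val is None:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(corpus))
        n_val = max(1, len(corpus) // config.folds)
        val = [corpus[i] for i in order[:n_val]]
        corpus = [corpus[i] for i in order[n_val:]]
    if model is None:
        model = GCATagger.from_corpus(corpus + val, config)
    params = model.parameters()
    optimizer = AdamW(params, lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    if optimizer_state is not None:
        optimizer.load_state_dict(optimizer_state)
    print(f"# config: {json.dumps(model.config.to_dict(), sort_keys=True)}",
          file=log)

    result = TrainResult(model=model)
    best_params = None
    batches = _length_batches(list(range(len(corpus))), corpus,
                              config.batch_size)
    for epoch in range(start_epoch, config.epochs):
        epoch_rng = np.random.default_rng((config.seed * 100003 + epoch)
                                          % (2**31 - 1))
        order = epoch_rng.permutation(len(batches))
        total_loss = 0.0
        n_sent = 0
        for bi in order:
            idx = batches[bi]
            batch = make_batch([corpus[i] for i in idx], model.vocab,
                               model.label_index)
            loss = model.loss_batch(batch) * (1.0 / len(idx))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} batch {bi}; parameter "
                    f"norm {sum(float((p.data**2).sum()) for _, p in params):.3e}")
            optimizer.zero_grad()
            loss.backward()
            clip_gradients(params, config.grad_clip)
            optimizer.step()
            total_loss += float(loss.data) * len(idx)
            n_sent += len(idx)
        p, r, f1 = _evaluate(model, val)
        entry = {"epoch": epoch, "train_loss": total_loss / max(n_sent, 1),
                 "val_precision": p, "val_recall": r, "val_f1": f1}
        result.history.append(entry)
        print(f"epoch {epoch:3d}  loss {entry['train_loss']:.4f}  "
              f"P {p:.2f}  R {r:.2f}  F1 {f1:.2f}", file=log)
        if f1 >= result.best_f1:
            result.best_f1, result.best_epoch = f1, epoch
            best_params = {name: t.data.copy() for name, t in params}
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, model, optimizer, epoch, result)
    if best_params is not None:
        for name, t in params:
            t.data[...] = best_params[name]
    return result


def save_checkpoint(path, model: GCATagger, optimizer: AdamW, epoch: int,
                    result: TrainResult) -> None:
    state = optimizer.state_dict()
    arrays = {f"param/{n}": t.data for n, t in model.parameters()}
    arrays.update({f"adam_m/{k}": v for k, v in state["m"].items()})
    arrays.update({f"adam_v/{k}": v for k, v in state["v"].items()})
    meta = json.dumps({
        "config": model.config.to_dict(), "vocab": model.vocab.itos,
        "labels": model.labels, "epoch": epoch, "adam_t": state["t"],
        "best_f1": result.best_f1, "best_epoch": result.best_epoch,
        "history": result.history,
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Return (model, optimizer_state, next_epoch, partial TrainResult)."""
    from .encoder import Vocabulary
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = GCATagger(Vocabulary(meta["vocab"]), meta["labels"],
                          RunConfig(**meta["config"]))
        m, v = {}, {}
        for name, t in model.parameters():
            t.data[...] = data[f"param/{name}"]
            m[name] = data[f"adam_m/{name}"].copy()
            v[name] = data[f"adam_v/{name}"].copy()
    result = TrainResult(model=model, history=meta["history"],
                         best_f1=meta["best_f1"],
                         best_epoch=meta["best_epoch"])
    state = {"t": meta["adam_t"], "m": m, "v": v}
    return model, state, meta["epoch"] + 1, result


def cross_validate(config: RunConfig, corpus: list[TaggedSentence],
                   log=None) -> dict:
    """k-fold cross-validation; reports per-fold and mean +/- sd metrics."""
    plan = make_folds(corpus, config.folds, config.seed)
    fold_metrics = []
    for i, (train_idx, val_idx) in enumerate(plan.folds):
        result = train(config, [corpus[j] for j in train_idx],
                       val=[corpus[j] for j in val_idx], log=log)
        best = max(result.history, key=lambda e: e["val_f1"])
        fold_metrics.append({"fold": i, "precision": best["val_precision"],
                             "recall": best["val_recall"],
                             "f1": best["val_f1"]})
    f1s = np.array([m["f1"] for m in fold_metrics])
    ps = np.array([m["precision"] for m in fold_metrics])
    rs = np.array([m["recall"] for m in fold_metrics])
    return {"folds": fold_metrics,
            "mean": {"precision": float(ps.mean()), "recall": float(rs.mean()),
                     "f1": float(f1s.mean())},
            "sd": {"precision": float(ps.std(ddof=1)),
                   "recall": float(rs.std(ddof=1)),
                   "f1": float(f1s.std(ddof=1))}}


def predict_corpus(model: GCATagger, sentences: list[TaggedSentence]
                   ) -> list[list[str]]:
    """Deterministic Viterbi predictions, batched by similar length."""
    if not sentences:
        return []
    out: list[list[str] | None] = [None] * len(sentences)
    for idx in _length_batches(list(range(len(sentences))), sentences,
                               batch_size=32):
        tags = model.predict([sentences[i] for i in idx])
        for i, t in zip(idx, tags):
            out[i] = t
    return out  # type: ignore[return-value]
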