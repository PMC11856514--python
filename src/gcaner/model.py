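"""Full tagger: embedding+BiLSTM encoder -> GCA stack -> linear-chain CRF.

``GCATagger`` owns every learnable tensor, maps tagged sentences to padded
batches, computes the composite training loss, and decodes with Viterbi.
Checkpoints are single ``.npz`` files with the config, vocabulary, and
label inventory embedded as JSON, so a saved model reloads with no side
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .corpus import RunConfig
from .crf import (CRFParams, LossConfig, crf_loss_batch, cross_entropy_batch,
                  init_crf, viterbi)
from .encoder import (BiLSTMParams, EncoderConfig, Vocabulary,
                      bilstm_forward, build_vocabulary, init_bilstm)
from .gca import GCAConfig, GCAParams, gca_forward, init_gca
from .tagging import (TaggedSentence, boundary_masks, decode_tags,
                      label_inventory, transition_mask)

__all__ = ["GCATagger", "Batch", "make_batch"]


@dataclass
class Batch:
    ids: np.ndarray      # (B, n) int64
    mask: np.ndarray     # (B, n) float, 1.0 at valid positions
    tags: np.ndarray     # (B, n) int64 gold label indices (0 at padding)
    sentences: list[TaggedSentence]


def make_batch(sentences: list[TaggedSentence], vocab: Vocabulary,
               label_index: dict[str, int]) -> Batch:
    n = max(len(s) for s in sentences)
    batch = len(sentences)
    ids = np.zeros((batch, n), dtype=np.int64)
    mask = np.zeros((batch, n))
    tags = np.zeros((batch, n), dtype=np.int64)
    for b, sent in enumerate(sentences):
        ln = len(sent)
        ids[b, :ln] = vocab.encode(sent.tokens)
        mask[b, :ln] = 1.0
        tags[b, :ln] = [label_index[t] for t in sent.tags]
    return Batch(ids, mask, tags, sentences)


class GCATagger:
    """The assembled model; all state lives in numpy-backed tensors."""

    def __init__(self, vocab: Vocabulary, labels: list[str],
                 config: RunConfig):
        self.vocab = vocab
        self.labels = list(labels)
        self.label_index = {t: i for i, t in enumerate(self.labels)}
        self.config = config
        self.enc_config = EncoderConfig(embedding_dim=config.embedding_dim,
                                        hidden_dim=config.hidden_dim,
                                        max_len=config.max_len)
        self.gca_config = GCAConfig(model_dim=config.model_dim,
                                    heads=config.heads,
                                    segment_k=config.segment_k,
                                    ablation=config.ablation)
        self.loss_config = LossConfig(alpha=config.alpha)
        rng = np.random.default_rng(config.seed)
        self.encoder: BiLSTMParams = init_bilstm(len(vocab), self.enc_config, rng)
        self.gca: GCAParams = init_gca(2 * config.hidden_dim, len(self.labels),
                                       self.gca_config, rng)
        if config.use_transition_mask:
            pair = transition_mask(self.labels)
            start_m, stop_m = boundary_masks(self.labels)
        else:
            pair = start_m = stop_m = None
        self.crf: CRFParams = init_crf(len(self.labels), rng, mask=pair,
                                       start_mask=start_m, stop_mask=stop_m)

    # ------------------------------------------------------------- plumbing
    @classmethod
    def from_corpus(cls, corpus: list[TaggedSentence],
                    config: RunConfig) -> "GCATagger":
        vocab = build_vocabulary(corpus, min_count=config.min_count)
        cats = sorted({t.partition("-")[2] for s in corpus for t in s.tags
                       if t != "O"})
        labels = label_inventory(tuple(cats) if cats != [""] else ("",))
        return cls(vocab, labels, config)

    def parameters(self) -> list[tuple[str, Tensor]]:
        out = []
        for side, p in (("enc.fwd", self.encoder.fwd), ("enc.bwd", self.encoder.bwd)):
            out += [(f"{side}.w_ih", p.w_ih), (f"{side}.w_hh", p.w_hh),
                    (f"{side}.bias", p.bias)]
        out.append(("enc.embedding", self.encoder.embedding))
        g = self.gca
        out += [("gca.proj_in_w", g.proj_in_w), ("gca.proj_in_b", g.proj_in_b),
                ("gca.char.w_hh", g.char.w_hh), ("gca.char.w_xh", g.char.w_xh),
                ("gca.char.bias", g.char.bias),
                ("gca.phrase.w_hh", g.phrase.w_hh),
                ("gca.phrase.w_yh", g.phrase.w_yh),
                ("gca.phrase.bias", g.phrase.bias),
                ("gca.attn.w_q", g.attention.w_q), ("gca.attn.w_k", g.attention.w_k),
                ("gca.attn.w_v", g.attention.w_v), ("gca.attn.w_o", g.attention.w_o),
                ("gca.gate1.w", g.gate1.weight), ("gca.gate1.b", g.gate1.bias),
                ("gca.gate2.w", g.gate2.weight), ("gca.gate2.b", g.gate2.bias),
                ("gca.emit_w", g.emit_w), ("gca.emit_b", g.emit_b),
                ("crf.transitions", self.crf.transitions),
                ("crf.start", self.crf.start), ("crf.stop", self.crf.stop)]
        return out

    # -------------------------------------------------------------- forward
    def emissions_batch(self, batch: Batch) -> Tensor:
        states = bilstm_forward(batch.ids, batch.mask, self.encoder,
                                self.enc_config)
        return gca_forward(states, self.gca, self.gca_config, mask=batch.mask)

    def loss_batch(self, batch: Batch) -> Tensor:
        """Composite loss summed over the batch's sentences."""
        em = self.emissions_batch(batch)
        ce = cross_entropy_batch(em, batch.tags, batch.mask)
        crf = crf_loss_batch(em, batch.tags, batch.mask, self.crf)
        a = self.loss_config.alpha
        return a * ce + (1.0 - a) * crf

    def predict(self, sentences: list[TaggedSentence]) -> list[list[str]]:
        """Viterbi tag sequences; unknown characters map to the unk index."""
        if not sentences:
            return []
        out = []
        batch = make_batch(sentences, self.vocab, self.label_index)
        em = self.emissions_batch(batch).data
        for b, sent in enumerate(sentences):
            path, _ = viterbi(em[b, :len(sent), :], self.crf)
            out.append([self.labels[i] for i in path])
        return out

    def predict_spans(self, sentences: list[TaggedSentence]):
        return [decode_tags(tags, mode="lenient")
                for tags in self.predict(sentences)]

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        arrays = {name: t.data for name, t in self.parameters()}
        meta = json.dumps({
            "config": self.config.to_dict(),
            "vocab": self.vocab.itos,
            "labels": self.labels,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GCATagger":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(Vocabulary(meta["vocab"]), meta["labels"],
                        RunConfig(**meta["config"]))
            for name, t in model.parameters():
                t.data[...] = data[name]
        return model
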