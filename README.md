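# gcaner

Gated context-aware sequence labeling for Chinese medical named entity
recognition (NER).

Clinical text mining needs to locate spans like diseases, symptoms and
drugs in character-level Chinese text. `gcaner` implements a tagger for
this task aimed at researchers who want every component inspectable and
testable on a laptop CPU: a BiLSTM character encoder (with a pluggable
slot for a pretrained contextual encoder), a gated context-aware (GCA)
feature stack, and a linear-chain CRF decoder, trained with a composite
cross-entropy + CRF objective and scored with entity-level exact-match
precision/recall/F1.

## The model

Characters are embedded and encoded bidirectionally, h_t = [h_t→ ; h_t←].
The GCA stack then extracts features at three levels and fuses them with
two sigmoid gates:

* character level: h_t = tanh(W_hh h_{t−1} + W_xh x_t + b_h)
* phrase level: the same recurrence over pooled character n-grams,
  broadcast back to token positions, giving h'_t
* sentence level: multi-head self-attention,
  Attention(Q,K,V) = softmax(QKᵀ/√d_k)V, H = Concat(head_1..head_m)W^O

with the gates

    g_t  = σ(W_g [h_t ; h'_t] + b_g),     h̃'_t = g_t ⊙ h'_t + (1−g_t) ⊙ h_t
    g'_t = σ(W'_g [h̃'_t ; H_t] + b'_g),   H̃_t  = g'_t ⊙ H_t + (1−g'_t) ⊙ h̃'_t

A linear head maps H̃_t to per-label emission scores for a linear-chain CRF
(exact forward log-partition, Viterbi decoding, optional BIEO transition
mask). The training loss is L = α·L_CE + (1−α)·L_CRF. Tags follow the
four-symbol BIEO scheme (Begin/Inside/End/Outside, optionally
category-suffixed, e.g. `B-dis`); evaluation is exact-span micro
P/R/F1 = 2PR/(P+R) on the 0–100 scale. Ablation flags reproduce the two
reduced models (`no_attention`, `no_gca`). The whole numerical stack —
including a small reverse-mode autodiff engine — is NumPy, so everything
runs offline and deterministically on one CPU.

The absolute published benchmark scores on MCSCSet and CMeEE are out of
scope here: they require those external corpora, pretrained
RoBERTa-wwm-ext encoder weights, and GPU training. See
`docs/methods.md` for what this package does and does not reproduce.

## Worked example

Tagging the canonical 10-character query 眼睛痛肿胀是什么原因 ("eye pain
and swelling — what is the cause?") with its two entities:

```python
from gcaner import EntitySpan, encode_spans, decode_tags

tokens = list("眼睛痛肿胀是什么原因")
tags = encode_spans(tokens, [EntitySpan(0, 3), EntitySpan(3, 5)])
print(tags)          # ['B', 'I', 'E', 'B', 'E', 'O', 'O', 'O', 'O', 'O']
print(decode_tags(tags))
# [EntitySpan(start=0, end=3, category=''), EntitySpan(start=3, end=5, category='')]
```

Training the full model from scratch on a seeded synthetic corpus
(500 sentences, 3 entity categories, ~2 entities/sentence) at desk scale:

```python
from gcaner import RunConfig, train
from gcaner.synthetic import SynthSpec, generate

corpus = generate(SynthSpec(n_sentences=500, categories=("dis", "sym", "dru"),
                            entity_density=2.0, seed=13))
config = RunConfig(epochs=15, batch_size=16, learning_rate=1e-3,
                   hidden_dim=32, embedding_dim=32, model_dim=64, seed=13)
result = train(config, corpus)
print(result.best_f1)
```

The run logs one line per epoch (loss, validation P/R/F1 on the held-out
fifth of the corpus) and finishes in under a minute on one CPU:

```
epoch   0  loss 47.4103  P 0.00  R 0.00  F1 0.00
epoch   5  loss 8.3498  P 68.95  R 59.55  F1 63.90
epoch  10  loss 1.6333  P 90.41  R 90.00  F1 90.21
epoch  14  loss 0.5659  P 93.69  R 94.55  F1 94.12
94.12
```

An F1 of 94 means the model recovers almost every planted entity span
exactly (start, end and category) — on this deliberately learnable
synthetic corpus that demonstrates the architecture, gradients, decoder
and metric pipeline are wired correctly, not clinical-grade performance.

The same pipeline is available as a CLI:

```
gcaner synth --out corpus.tsv --seed 13
gcaner train --config run.yaml --corpus corpus.tsv --model-out model.npz
gcaner eval  --model model.npz --corpus corpus.tsv
gcaner predict --model model.npz --input corpus.tsv --output pred.tsv
```

Corpora are CoNLL-style text files (`character<TAB>tag`, blank line
between sentences); `gcaner train --folds 5` runs five-fold
cross-validation and reports mean ± sd.

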