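# Methods

## Model

`gcaner` implements a character-level sequence tagger for Chinese medical
named entity recognition built from four blocks, in the order a forward
pass runs them.

**Encoder.** Each character x_t is embedded (trainable lookup, default
dimension 128) and passed through a bidirectional LSTM; the contextual
state is the concatenation h_t = [h_t→ ; h_t←] of the forward and backward
recurrences (per-direction hidden size 512 by default, so the encoder emits
1024-dimensional states). Input length is capped at 512 characters;
over-length sentences are split upstream at the nearest O-tagged position,
never truncated. The encoder slot is pluggable: any object mapping a token
list to per-position vectors of a declared dimension (for example, a
pretrained RoBERTa-style contextual encoder) satisfies the same downstream
contract. The bundled default is a from-scratch trainable encoder so that
every experiment in this repository runs offline on a CPU; the pretrained
weights and their domain-adaptive pre-training are out of scope.

**Gated context-aware (GCA) stack.** Encoder states are projected to a
shared model dimension d (default 256) and refined at three levels:

1. *Character level*: a vanilla RNN, h_t = tanh(W_hh h_{t−1} + W_xh x_t + b_h),
   with h_0 = 0, where x_t is the projected encoder state at position t.
2. *Phrase level*: the sentence is tiled into segments by a pluggable
   segmenter (default: fixed non-overlapping n-grams of size k = 2); the
   phrase input y_j is the mean of the character states inside segment j;
   the same tanh recurrence runs over the segment sequence and each
   segment's output state is broadcast back to all its token positions.
3. *Sentence level*: multi-head scaled dot-product self-attention
   (default m = 4 heads, d_k = d/m, no positional encoding — order
   information already comes from the recurrences) over the first fusion
   output.

Two sigmoid gates fuse the levels elementwise:

    g_t  = σ(W_g [h_t ; h'_t] + b_g)          h̃'_t = g_t ⊙ h'_t + (1−g_t) ⊙ h_t
    g'_t = σ(W'_g [h̃'_t ; H_t] + b'_g)        H̃_t  = g'_t ⊙ H_t + (1−g'_t) ⊙ h̃'_t

where h'_t is the broadcast phrase state and H_t the attention output.
Both fusions are componentwise convex combinations of their inputs by
construction (tested exhaustively). A final linear layer maps H̃_t to one
real score per label (the emission matrix).

**CRF decoder.** A linear-chain CRF with a learnable L×L transition matrix
and explicit learnable start/stop boundary scores. The log-partition is
computed exactly by the forward recursion in log space; decoding is max-sum
Viterbi with backpointers (ties toward the lower label index); per-position
posteriors come from forward–backward and are exposed as diagnostics.
Transitions that are illegal under the strict BIEO rules can be masked;
masked entries are scored −1e4 (a finite stand-in for −∞ that keeps all
arithmetic well defined). With the mask enabled, every decoded path is
scheme-legal even from an untrained model.

**Training objective.** The loss mixes per-position cross-entropy over the
softmax of the emission scores with the CRF negative log-likelihood:

    L = α·L_CE + (1−α)·L_CRF,   α ∈ [0, 1], default 0.5.

α = 0 gives a pure CRF model, α = 1 a pure softmax classifier. L_CE uses
the softmax of the emissions as ŷ (simple, differentiable, independent of
the CRF pass); a variant that uses the CRF posterior marginals instead
exists behind `LossConfig.ce_from_marginals`. Both losses are sums over
valid (unpadded) positions; a mean-per-token variant exists for logging.

## Tag scheme

Four symbols — B, I, E, O — optionally category-suffixed (`B-dis`). The
source describing this architecture labels the scheme "BIO" but defines and
uses all four symbols; this package names it BIEO and treats the strict
transition rules (I/E only after B/I of the same category; I never ends a
sentence) as the single source of truth for validation, the CRF mask, and
the synthetic generator. Length-1 entities get a lone B (there is no S
symbol in the alphabet), length-2 get B,E. The canonical worked example —
a 10-character query with entities 眼睛痛 (positions 0–3) and 肿胀 (3–5) —
encodes to [B,I,E,B,E,O,O,O,O,O]. The published version of that example
prints 11 labels for the 10 characters (one surplus trailing O); the
10-symbol correction above is used here, and the lenient decoder yields the
same two entities for either variant. Lenient decoding (the default on
model output) is total: a new entity starts at each B, extends through
matching I, and closes at a matching E or at the first tag that cannot
continue it.

## Numerical choices

* All arithmetic is float64 on top of a small reverse-mode autodiff engine
  written for this package; gradient correctness is enforced by central
  finite-difference tests (relative error < 1e−4 on the full composite
  loss).
* LSTM initialisation is uniform scaled by 1/√fan-in with forget-gate bias
  +1; all other matrices are uniform 1/√fan-in; biases start at zero.
* Batches pad to the longest sentence; the recurrent updates are gated by
  the validity mask, so padding neutrality is exact (tested bitwise), and
  attention adds −1e9 to scores at padded keys.
* Softmax/logsumexp use max-shift stabilisation; predicted probabilities
  are clamped at 1e−12 before logs.
* Viterbi ties break toward the lower label index; label order is O first,
  then B/I/E per category.

## Training protocol

Optimisation is mini-batch adaptive moment estimation with decoupled
weight decay (applied to weight matrices only) and global gradient-norm
clipping at 5.0; batches group sentences of similar length and batch order
is reshuffled each epoch with a seed derived from (run seed, epoch), which
makes checkpoint resume bit-exact. The reference protocol is 100 epochs,
batch size 16, learning rate 5e−5, weight decay 0.01 — values appropriate
for fine-tuning on top of a pretrained encoder, and kept as the `RunConfig`
defaults. Desk-scale runs that train the whole model from scratch use the
standard adaptive-moment rate of 1e−3 with model dimension 64 and 15
epochs; that is the configuration of the learning-sanity run in the test
suite and acceptance script. The "learning rate decay 0.01" of the
reference protocol is read as decoupled weight decay — an interpretation,
recorded here because the protocol names no optimiser. k-fold
cross-validation (default k = 5) shuffles once with the run seed, splits
into near-equal parts, and reports per-fold best validation metrics with
mean ± sd across folds.

## Evaluation

Entity-level exact match: a predicted span counts only if (start, end,
category) all agree with a gold span. Counts are micro-aggregated across
the corpus; P, R and F1 = 2PR/(P+R) are reported on the 0–100 scale at two
decimals, with 0/0 defined as 0. Partial-overlap credit is deliberately
rejected. Token-level accuracy exists only as a debug statistic. One
consistency note: in the reference results for the CMeEE benchmark, the
proposed model's printed P = 66.43 and R = 63.07 imply F1 = 64.71, not the
printed 64.36 (possibly a cross-fold aggregation artifact); the same holds
for two baseline rows there. The metric-reproduction checks therefore use
the internally consistent rows only.

## Synthetic corpus

The generator emulates the *structure* of the benchmark data — character
sequences of 10–50 tokens containing multi-character entities of several
categories at an expected density of 2 entities/sentence, embedded in
filler text over a 300-symbol alphabet — not Chinese morphology, spelling
errors, or realistic entity ambiguity. By default each category's lexicon
(20 entries, lengths 2–5) is drawn from its own character block disjoint
from the filler alphabet, so the task is learnable by a small model within
minutes on a CPU; `hard_mode` shares one alphabet between filler and
entities. Entity counts are Poisson(density), truncated only when a
sentence physically cannot host them; entity lengths default to 2–5 so
that the feasibility rule density × max-entity-length ≤ min-sentence-length
holds at the defaults. Placement distributes slack uniformly over gaps
(stars-and-bars). Tag noise (`corrupt_tags`) resamples each tag with the
given probability from the alphabet excluding the current tag, so the
changed-position count is exactly binomial; planted gold spans are kept
separately from the (possibly corrupted) tags.

Because entities are unambiguous strings absent from the filler, a passing
learning-sanity run demonstrates that the architecture, gradients, decoder
and evaluation pipeline are wired correctly — it says nothing about
performance on real clinical text, where entity boundaries are ambiguous
and context carries most of the signal.

## Problem sizes used in tests and the acceptance script

CRF exactness is checked against exhaustive enumeration at n ≤ 5, L ≤ 4
(100 random instances, tolerance 1e−8); gate convexity on 1000 random
draws; the learning-sanity run uses 500 synthetic sentences, 3 categories,
model dimension 64, 15 epochs on one CPU. These sizes were chosen so the
whole suite runs in a few minutes while every check remains exact or
statistically sharp.

## Known limitations

* The absolute benchmark scores on MCSCSet and CMeEE (91.90 and 64.36 F1)
  are **not** reproducible with this repository alone: they require the
  external corpora, the pretrained RoBERTa-wwm-ext encoder with
  domain-adaptive pre-training, and GPU-scale training, all out of scope.
  What is reproduced instead: exact inference, the gate/attention algebra,
  the loss identities, the worked tagging example, the metric arithmetic of
  the printed tables, and from-scratch learnability on synthetic data.
* Phrase segmentation is a fixed n-gram tiling by default; the reference
  description leaves phrase construction unspecified, and the broadcasting
  of phrase states to token positions (required for the elementwise gate)
  is this package's choice, not a claim about the original design.
* Nested and discontinuous entities are out of scope; spans are
  non-overlapping, 0-based, half-open everywhere.
* Single shared emission head feeds both losses (the alternative —
  separate heads per loss — is not implemented).
* Attention head count (default 4), embedding dimension (default 128) and
  α (default 0.5) are not specified by the reference protocol; the
  defaults are package choices, all configurable.
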