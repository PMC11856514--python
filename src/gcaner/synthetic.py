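"""Seeded synthetic corpora for desk-scale training and evaluation.

The generator emulates the structure of character-level Chinese medical NER
data: sentences of 10–50 characters containing multi-character entities
from per-category lexicons, embedded in non-entity filler text.  By default
each category draws its entity strings from its own character block,
disjoint from the filler alphabet, which makes the task learnable by a
small model in a few epochs — that is intentional, so learning-sanity runs
are fast and stable.  ``hard_mode`` shares one alphabet between filler and
entities instead.

Entity counts per sentence are Poisson with the configured density; entity
lengths are clipped so every sampled sentence can host its entities, and
placement distributes the slack uniformly over the gaps between entities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tagging import EntitySpan, TaggedSentence, encode_spans, label_inventory

__all__ = ["SynthSpec", "SpecError", "make_lexicons", "generate", "corrupt_tags"]

FILLER_BASE = 0x4E00     # CJK block used for filler symbols
ENTITY_BASE = 0x5B00     # per-category entity blocks start here
CATEGORY_STRIDE = 0x100


class SpecError(ValueError):
    """The generator spec cannot produce valid sentences."""


@dataclass
class SynthSpec:
    """Study conditions for one synthetic corpus."""

    n_sentences: int = 1000
    min_len: int = 10
    max_len: int = 50
    categories: tuple[str, ...] = ("dis", "sym", "dru")
    lexicon_size: int = 20          # entries per category
    entity_min_len: int = 2
    entity_max_len: int = 5
    entity_density: float = 2.0     # expected entities per sentence
    filler_alphabet: int = 300
    noise_rate: float = 0.0
    hard_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 0:
            raise SpecError("n_sentences must be >= 0")
        if not 1 <= self.min_len <= self.max_len:
            raise SpecError("need 1 <= min_len <= max_len")
        if not 2 <= self.entity_min_len <= self.entity_max_len:
            raise SpecError("entity lengths must satisfy 2 <= min <= max")
        if self.entity_density < 0:
            raise SpecError("entity_density must be >= 0")
        if self.entity_density * self.entity_max_len > self.min_len:
            raise SpecError(
                f"infeasible spec: density {self.entity_density} x max entity "
                f"length {self.entity_max_len} exceeds min sentence length "
                f"{self.min_len}")
        if self.filler_alphabet < 1:
            raise SpecError("filler_alphabet must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise SpecError("noise_rate must lie in [0, 1]")

    @property
    def labels(self) -> list[str]:
        return label_inventory(self.categories)


def make_lexicons(spec: SynthSpec,
                  rng: np.random.Generator) -> dict[str, list[str]]:
    """Per-category entity lexicons: unique multi-character strings.

    Default mode draws each category's characters from its own codepoint
    block, disjoint from the filler alphabet; hard mode samples entity
    characters from the filler alphabet itself.
    """
    lexicons: dict[str, list[str]] = {}
    for c_idx, cat in enumerate(spec.categories):
        if spec.hard_mode:
            alphabet = [chr(FILLER_BASE + i) for i in range(spec.filler_alphabet)]
        else:
            base = ENTITY_BASE + c_idx * CATEGORY_STRIDE
            alphabet = [chr(base + i) for i in range(64)]
        entries: set[str] = set()
        while len(entries) < spec.lexicon_size:
            length = int(rng.integers(spec.entity_min_len,
                                      spec.entity_max_len + 1))
            entries.add("".join(rng.choice(alphabet) for _ in range(length)))
        lexicons[cat] = sorted(entries)
    return lexicons


def _place_entities(length: int, entities: list[tuple[str, str]],
                    rng: np.random.Generator) -> list[tuple[int, str, str]]:
    """Place entity strings without overlap; returns (start, text, category).

    Slack positions are split uniformly over the gaps around the entities
    (stars-and-bars), so placements cover the whole sentence.
    """
    total = sum(len(text) for text, _ in entities)
    slack = length - total
    k = len(entities)
    cuts = np.sort(rng.integers(0, slack + 1, size=k)) if k else np.array([], int)
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    placed = []
    pos = 0
    order = rng.permutation(k)
    for j, gap in zip(order, gaps[:-1]):
        pos += int(gap)
        text, cat = entities[j]
        placed.append((pos, text, cat))
        pos += len(text)
    return placed


def generate(spec: SynthSpec) -> list[TaggedSentence]:
    """Generate a corpus; identical output for identical specs (seed fixed)."""
    rng = np.random.default_rng(spec.seed)
    lexicons = make_lexicons(spec, rng)
    filler = [chr(FILLER_BASE + i) for i in range(spec.filler_alphabet)]
    cats = list(spec.categories)
    sentences: list[TaggedSentence] = []
    for _ in range(spec.n_sentences):
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        n_entities = int(rng.poisson(spec.entity_density)) if cats else 0
        n_entities = min(n_entities, length // spec.entity_min_len)
        chosen: list[tuple[str, str]] = []
        budget = length
        for _ in range(n_entities):
            cat = cats[int(rng.integers(len(cats)))]
            entry = lexicons[cat][int(rng.integers(len(lexicons[cat])))]
            if len(entry) > budget - (0 if not chosen else 0):
                # fall back to the shortest entry of the category that fits
                fitting = [e for e in lexicons[cat] if len(e) <= budget]
                if not fitting:
                    continue
                entry = fitting[int(rng.integers(len(fitting)))]
            chosen.append((entry, cat))
            budget -= len(entry)
        placed = _place_entities(length, chosen, rng)
        tokens = [filler[int(i)] for i in rng.integers(0, len(filler),
                                                       size=length)]
        spans = []
        for start, text, cat in sorted(placed):
            tokens[start:start + len(text)] = list(text)
            spans.append(EntitySpan(start, start + len(text), cat))
        tags = encode_spans(tokens, spans)
        sentences.append(TaggedSentence(tokens, tags, gold_spans=spans))
    if spec.noise_rate > 0:
        sentences = corrupt_tags(sentences, spec.noise_rate,
                                 seed=spec.seed + 1, labels=spec.labels)
    return sentences


def corrupt_tags(sentences: list[TaggedSentence], noise_rate: float,
                 seed: int, labels: list[str] | None = None
                 ) -> list[TaggedSentence]:
    """Independently resample each tag with probability ``noise_rate``.

    A resampled tag is drawn uniformly from the alphabet *excluding* the
    current tag, so the number of changed positions is exactly
    Binomial(total tags, noise_rate); a one-symbol alphabet leaves
    everything unchanged.  Gold spans are carried over untouched.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = sorted({t for s in sentences for t in s.tags})
    out = []
    for sent in sentences:
        tags = list(sent.tags)
        if noise_rate > 0 and len(labels) > 1:
            flips = rng.random(len(tags)) < noise_rate
            for i in np.nonzero(flips)[0]:
                alternatives = [l for l in labels if l != tags[i]]
                tags[int(i)] = alternatives[int(rng.integers(len(alternatives)))]
        gold = sent.gold_spans if sent.gold_spans is not None else sent.spans
        out.append(TaggedSentence(list(sent.tokens), tags, gold_spans=list(gold)))
    return out
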