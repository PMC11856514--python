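"""BIEO tag scheme: entity spans <-> per-character tag sequences.

The scheme uses four symbols — B (begin), I (inside), E (end), O (outside) —
optionally suffixed with an entity category after a hyphen (``B-dis``).  A
length-1 entity is a lone ``B``, a length-2 entity is ``B,E``, and longer
entities are ``B, I..., E``.  Spans are 0-based and half-open everywhere in
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EntitySpan",
    "TaggedSentence",
    "SchemeError",
    "SpanConflictError",
    "encode_spans",
    "decode_tags",
    "label_inventory",
    "transition_mask",
    "boundary_masks",
]

SCHEME = "BIEO"


class SchemeError(ValueError):
    """A tag sequence violates the strict BIEO transition rules."""


class SpanConflictError(ValueError):
    """Entity spans overlap, nest, or fall outside the sentence."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A contiguous entity: token indices ``[start, end)`` plus a category.

    ``category`` is the empty string for single-category corpora.
    """

    start: int
    end: int
    category: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise SpanConflictError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TaggedSentence:
    """A character sequence with aligned BIEO tags.

    ``spans`` is derived lazily from the tags (lenient decoding); when the
    sentence was produced by a generator that knows the planted entities,
    ``gold_spans`` may carry them independently of the (possibly corrupted)
    tags.
    """

    tokens: list[str]
    tags: list[str]
    gold_spans: list[EntitySpan] | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    @property
    def spans(self) -> list[EntitySpan]:
        return decode_tags(self.tags, mode="lenient")


def _split(tag: str) -> tuple[str, str]:
    """Return (symbol, category) for a tag like ``B-dis`` or ``O``."""
    if tag == "O":
        return "O", ""
    sym, _, cat = tag.partition("-")
    return sym, cat


def _join(sym: str, cat: str) -> str:
    return sym if not cat or sym == "O" else f"{sym}-{cat}"


def _check_tag(tag: str, pos: int) -> tuple[str, str]:
    sym, cat = _split(tag)
    if sym not in ("B", "I", "E", "O"):
        raise SchemeError(f"position {pos}: unknown tag symbol {tag!r}")
    return sym, cat


def encode_spans(tokens: Sequence[str], spans: Iterable[EntitySpan]) -> list[str]:
    """Encode non-overlapping entity spans into a BIEO tag sequence.

    Spans must be sorted, pairwise disjoint, and lie within the sentence;
    violations raise :class:`SpanConflictError`.
    """
    n = len(tokens)
    tags = ["O"] * n
    prev_end = -1
    for span in spans:
        if span.end > n:
            raise SpanConflictError(
                f"span ({span.start}, {span.end}) exceeds sentence length {n}")
        if span.start < prev_end:
            raise SpanConflictError(
                f"span ({span.start}, {span.end}) overlaps a previous span "
                f"ending at {prev_end} (spans must be sorted and disjoint)")
        prev_end = span.end
        length = len(span)
        if length == 1:
            tags[span.start] = _join("B", span.category)
        else:
            tags[span.start] = _join("B", span.category)
            for t in range(span.start + 1, span.end - 1):
                tags[t] = _join("I", span.category)
            tags[span.end - 1] = _join("E", span.category)
    return tags


def decode_tags(tags: Sequence[str], mode: str = "lenient") -> list[EntitySpan]:
    """Decode a BIEO tag sequence into entity spans.

    ``lenient`` (default, used on model output) never raises: a new entity
    starts at each B, extends through matching I tags, and closes at a
    matching E or at the first tag that cannot continue it (a lone B is a
    complete single-token entity).  ``strict`` raises :class:`SchemeError`
    at the first illegal transition, naming the position.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown decode mode {mode!r}")
    spans: list[EntitySpan] = []
    start: int | None = None     # open entity start
    cat = ""
    prev_sym, prev_cat = "O", ""

    def close(end: int) -> None:
        nonlocal start
        if start is not None:
            spans.append(EntitySpan(start, end, cat))
            start = None

    for pos, tag in enumerate(tags):
        sym, tcat = _check_tag(tag, pos)
        if mode == "strict":
            if sym in ("I", "E") and (prev_sym not in ("B", "I") or prev_cat != tcat):
                raise SchemeError(
                    f"position {pos}: {tag!r} may only follow B or I of the "
                    f"same category (previous: {_join(prev_sym, prev_cat)!r})")
            if prev_sym == "I" and (sym not in ("I", "E") or tcat != prev_cat):
                raise SchemeError(
                    f"position {pos}: {tag!r} leaves the entity opened by "
                    f"{_join('I', prev_cat)!r} unterminated")
        if sym == "B":
            close(pos)
            start, cat = pos, tcat
        elif sym == "I":
            if start is None or tcat != cat:
                close(pos)   # orphan I: not a span start under this scheme
        elif sym == "E":
            if start is not None and tcat == cat:
                close(pos + 1)
            else:
                close(pos)   # orphan E ignored
        else:  # O
            close(pos)
        prev_sym, prev_cat = sym, tcat
    if mode == "strict" and prev_sym == "I":
        raise SchemeError(
            f"position {len(tags) - 1}: sequence ends inside an entity (I)")
    close(len(tags))
    return spans


def label_inventory(categories: Sequence[str] = ("",)) -> list[str]:
    """The full tag alphabet for the given categories, ``O`` first.

    Order is deterministic: O, then B/I/E per category in the given order.
    """
    labels = ["O"]
    for cat in categories:
        labels.extend(_join(s, cat) for s in ("B", "I", "E"))
    return labels


def transition_mask(labels: Sequence[str]) -> np.ndarray:
    """Boolean matrix: ``mask[i, j]`` iff tag j may follow tag i (strict rules).

    From B: anything except I/E of a different category (a lone B closes).
    From I: only I/E of the same category.  From E or O: only B or O.
    """
    L = len(labels)
    mask = np.zeros((L, L), dtype=bool)
    parsed = [_split(t) for t in labels]
    for i, (si, ci) in enumerate(parsed):
        for j, (sj, cj) in enumerate(parsed):
            if si == "B":
                ok = sj in ("B", "O") or (sj in ("I", "E") and cj == ci)
            elif si == "I":
                ok = sj in ("I", "E") and cj == ci
            else:  # E or O close/stay outside an entity
                ok = sj in ("B", "O")
            mask[i, j] = ok
    return mask


def boundary_masks(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(may-start, may-end) boolean vectors under strict BIEO rules.

    A sequence may start with B or O and may end with anything but I
    (a trailing lone B is a complete entity).
    """
    start = np.array([_split(t)[0] in ("B", "O") for t in labels])
    end = np.array([_split(t)[0] != "I" for t in labels])
    return start, end
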