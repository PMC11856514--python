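"""Entity-level exact-match evaluation.

An entity counts as correct only when predicted and gold spans agree on
(start, end, category) — partial overlap earns no credit.  Counts are
micro-aggregated by summation across sentences, and

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R),

reported on the 0–100 scale at two decimals; every 0/0 is defined as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .tagging import EntitySpan

__all__ = ["MatchCounts", "match_entities", "prf", "evaluate_corpus",
           "format_report", "write_report_kv", "token_accuracy"]


@dataclass
class MatchCounts:
    """TP/FP/FN tallies, overall and per entity category."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_category: dict[str, "MatchCounts"] = field(default_factory=dict)

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        for cat, c in other.per_category.items():
            mine = self.per_category.setdefault(cat, MatchCounts())
            mine.tp += c.tp
            mine.fp += c.fp
            mine.fn += c.fn
        return self

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp

    @property
    def n_gold(self) -> int:
        return self.tp + self.fn


def match_entities(gold: Sequence[EntitySpan],
                   pred: Sequence[EntitySpan]) -> MatchCounts:
    """Exact (start, end, category) matching within one sentence.

    Duplicate spans are matched with multiplicity (gold spans within a valid
    sentence are disjoint, so duplicates cannot occur there, but the counter
    form keeps the operation total on arbitrary input).
    """
    gold_c = Counter((s.start, s.end, s.category) for s in gold)
    pred_c = Counter((s.start, s.end, s.category) for s in pred)
    counts = MatchCounts()
    for key in gold_c.keys() | pred_c.keys():
        g, p = gold_c.get(key, 0), pred_c.get(key, 0)
        hit = min(g, p)
        cat = counts.per_category.setdefault(key[2], MatchCounts())
        for c in (counts, cat):
            c.tp += hit
            c.fp += p - hit
            c.fn += g - hit
    return counts


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) in percent, rounded to 2 decimals."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return round(p, 2), round(r, 2), round(f1, 2)


def evaluate_corpus(gold_spans: Iterable[Sequence[EntitySpan]],
                    pred_spans: Iterable[Sequence[EntitySpan]]) -> MatchCounts:
    """Micro-aggregate exact-match counts over aligned sentence lists."""
    total = MatchCounts()
    n_g = n_p = 0
    for g, p in zip(gold_spans, pred_spans, strict=True):
        total += match_entities(g, p)
        n_g += 1
        n_p += 1
    return total


def token_accuracy(gold_tags: Sequence[Sequence[str]],
                   pred_tags: Sequence[Sequence[str]]) -> float:
    """Per-token tag accuracy — a debug statistic, not a headline metric."""
    hit = tot = 0
    for g, p in zip(gold_tags, pred_tags, strict=True):
        for gt, pt in zip(g, p, strict=True):
            hit += gt == pt
            tot += 1
    return hit / tot if tot else 0.0


def format_report(counts: MatchCounts) -> str:
    """Plain-text table: overall row plus one row per category."""
    lines = [f"{'scope':<12}{'P':>8}{'R':>8}{'F1':>8}{'gold':>7}{'pred':>7}"]

    def row(name: str, c: MatchCounts) -> str:
        p, r, f1 = prf(c)
        return f"{name:<12}{p:>8.2f}{r:>8.2f}{f1:>8.2f}{c.n_gold:>7}{c.n_predicted:>7}"

    lines.append(row("overall", counts))
    for cat in sorted(counts.per_category):
        lines.append(row(cat or "(none)", counts.per_category[cat]))
    return "\n".join(lines)


def write_report_kv(counts: MatchCounts, fh: TextIO) -> None:
    """Machine-readable metric/scope/value triples, tab-separated."""
    def emit(scope: str, c: MatchCounts) -> None:
        p, r, f1 = prf(c)
        for metric, value in (("precision", p), ("recall", r), ("f1", f1),
                              ("tp", c.tp), ("fp", c.fp), ("fn", c.fn)):
            fh.write(f"{metric}\t{scope}\t{value}\n")

    emit("overall", counts)
    for cat in sorted(counts.per_category):
        emit(cat or "(none)", counts.per_category[cat])
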