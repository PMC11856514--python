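"""CoNLL-style corpus I/O and run configuration.

Corpus files are UTF-8 text, one ``character<TAB>tag`` pair per line, a
blank line between sentences, ``#`` starting a comment line.  Prediction
files add a third column (``token<TAB>gold<TAB>pred``) and read back through
the same parser in lenient mode.

Run configuration is a flat YAML mapping; unknown keys are rejected so a
typo never silently trains with a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .gca import ABLATIONS
from .tagging import SchemeError, TaggedSentence, decode_tags

__all__ = ["CorpusParseError", "ConfigError", "RunConfig",
           "read_corpus", "write_corpus", "write_predictions",
           "read_predictions", "load_config"]


class CorpusParseError(ValueError):
    """Malformed corpus line; message carries the file and line number."""


class ConfigError(ValueError):
    """Invalid or unknown configuration key."""


def _parse_blocks(path: Path, allow_space: bool):
    """Yield (line_number, columns) grouped into sentence blocks."""
    block: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                if block:
                    yield block
                    block = []
                continue
            cols = line.split("\t")
            if len(cols) == 1 and allow_space:
                cols = line.split(" ")
            block.append((lineno, cols))
    if block:
        yield block


def read_corpus(path, strict: bool = True,
                allow_space_separator: bool = False) -> list[TaggedSentence]:
    """Parse a two-column tagged corpus into sentences, in file order.

    With ``strict`` (default) every sentence must satisfy the BIEO
    transition rules; a violation or a malformed line raises
    :class:`CorpusParseError` naming the line.  Lenient mode accepts any
    tags over the alphabet and tolerates extra columns (prediction files).
    """
    path = Path(path)
    sentences: list[TaggedSentence] = []
    for block in _parse_blocks(path, allow_space_separator):
        tokens, tags = [], []
        for lineno, cols in block:
            if len(cols) != 2 and (strict or len(cols) < 2):
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}")
            tokens.append(cols[0])
            tags.append(cols[1])
        if strict:
            try:
                decode_tags(tags, mode="strict")
            except SchemeError as exc:
                first = block[0][0]
                raise CorpusParseError(
                    f"{path}: sentence starting at line {first}: {exc}") from exc
        sentences.append(TaggedSentence(tokens, tags))
    return sentences


def write_corpus(sentences: Iterable[TaggedSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for tok, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def write_predictions(sentences: Sequence[TaggedSentence],
                      predicted: Sequence[Sequence[str]], path) -> None:
    """Three-column ``token<TAB>gold<TAB>pred`` file, one block per sentence."""
    if len(sentences) != len(predicted):
        raise ValueError(f"{len(sentences)} sentences but {len(predicted)} "
                         "prediction sequences")
    with open(path, "w", encoding="utf-8") as fh:
        for sent, tags in zip(sentences, predicted):
            if len(sent) != len(tags):
                raise ValueError(
                    f"sentence of length {len(sent)} with {len(tags)} "
                    "predicted tags")
            for tok, gold, pred in zip(sent.tokens, sent.tags, tags):
                fh.write(f"{tok}\t{gold}\t{pred}\n")
            fh.write("\n")


def read_predictions(path) -> tuple[list[TaggedSentence], list[list[str]]]:
    """Read a prediction file back into (gold sentences, predicted tags)."""
    path = Path(path)
    sentences, predictions = [], []
    for block in _parse_blocks(path, allow_space=False):
        tokens, gold, pred = [], [], []
        for lineno, cols in block:
            if len(cols) != 3:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            tokens.append(cols[0])
            gold.append(cols[1])
            pred.append(cols[2])
        sentences.append(TaggedSentence(tokens, gold))
        predictions.append(pred)
    return sentences, predictions


# ------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Hyperparameters of a training run.

    Defaults follow the reference experimental protocol (100 epochs, batch
    16, learning rate 5e-5, weight decay 0.01, max length 512, recurrent
    hidden size 512 per direction, five folds); desk-scale example configs
    override the sizes for CPU runs.
    """

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    max_len: int = 512
    hidden_dim: int = 512
    embedding_dim: int = 128
    model_dim: int = 256
    alpha: float = 0.5
    heads: int = 4
    segment_k: int = 2
    ablation: str = "none"
    seed: int = 0
    folds: int = 5
    grad_clip: float = 5.0
    min_count: int = 1
    use_transition_mask: bool = True

    def __post_init__(self):
        positive = ("epochs", "batch_size", "learning_rate", "max_len",
                    "hidden_dim", "embedding_dim", "model_dim", "heads",
                    "segment_k", "folds", "min_count")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"config key {name!r} must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must lie in [0, 1]; got {self.alpha}")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be >= 0")
        if self.ablation not in ABLATIONS:
            raise ConfigError(f"ablation must be one of {ABLATIONS}; "
                              f"got {self.ablation!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected, absences default."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key: value mapping")
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
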