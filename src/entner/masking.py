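"""Masked-input construction for continued pre-training.

Three strategies are supported:

* random MLM — every ordinary token is a candidate, masked with probability
  ``p`` (default 0.15) under the standard 80/10/10 corruption split;
* entity MLM (EMLM) — a label token encoding each entity token's BIO tag is
  inserted immediately before and after it, then *only entity tokens* are
  masked, each with probability ``eta`` (default 0.7), by pure mask-token
  replacement; the label tokens act as ordinary context and are never masked;
* the EMLM variant consumed by contrastive pre-training reuses the same
  machinery (the student sees the masked sequence, the frozen teacher the
  unmasked one).

Masks are re-drawn on every call, so an epoch loop gets dynamic masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, IntegrityError, SchemeError
from .formats import LabelScheme, TaggedSentence
from .vocab import Vocab

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskingConfig:
    p: float = 0.15
    eta: float = 0.7
    seed: int = 0
    strategy: str = "mlm"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ConfigurationError(f"p must be in [0,1], got {self.p}")
        if not (0.0 <= self.eta <= 1.0):
            raise ConfigurationError(f"eta must be in [0,1], got {self.eta}")
        if self.strategy not in ("mlm", "emlm"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")


@dataclass
class MaskedBatch:
    """A masked sequence (student input) plus its restoration targets.

    ``input_ids`` is the corrupted sequence X^m, ``target_ids`` the original X,
    and ``mask_indicator`` the binary vector with 1 exactly at positions
    selected for prediction. Label-token positions are never masked.
    """

    input_ids: np.ndarray
    target_ids: np.ndarray
    mask_indicator: np.ndarray
    label_token_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        if not (len(self.input_ids) == len(self.target_ids) == len(self.mask_indicator)):
            raise IntegrityError("masked batch arrays must have equal length")
        if np.intersect1d(
            np.nonzero(self.mask_indicator)[0], self.label_token_positions
        ).size:
            raise IntegrityError("a label token position was masked")


@dataclass
class LabeledSequence:
    """Tokens with label tokens interleaved around each entity token.

    ``origin_map[i]`` is the source position of token ``i`` in the unlabeled
    sentence, or None for an inserted label token; stripping by the origin map
    recovers the original sequence exactly.
    """

    tokens: list[str]
    origin_map: list[Optional[int]]
    entity_positions: list[int]
    entity_tags: list[str]

    @property
    def label_token_positions(self) -> list[int]:
        return [i for i, o in enumerate(self.origin_map) if o is None]


def insert_entity_labels(
    sentence: TaggedSentence, scheme: LabelScheme = LabelScheme()
) -> LabeledSequence:
    """Place a label token encoding the BIO tag immediately before and after
    every entity (non-O) token; e.g. ``Crohns``/B-diagnosis becomes
    ``<B-diagnosis> Crohns <B-diagnosis>``."""
    tokens: list[str] = []
    origin: list[Optional[int]] = []
    entity_positions: list[int] = []
    entity_tags: list[str] = []
    for i, (tok, tag) in enumerate(zip(sentence.tokens, sentence.tags)):
        scheme.validate_tag(tag)
        if tag == "O":
            tokens.append(tok.surface)
            origin.append(i)
        else:
            label_token = f"<{tag}>"
            tokens.append(label_token)
            origin.append(None)
            entity_positions.append(len(tokens))
            entity_tags.append(tag)
            tokens.append(tok.surface)
            origin.append(i)
            tokens.append(label_token)
            origin.append(None)
    return LabeledSequence(tokens, origin, entity_positions, entity_tags)


def strip_entity_labels(seq: LabeledSequence) -> list[str]:
    """Exact inverse of :func:`insert_entity_labels`."""
    kept = [(o, t) for o, t in zip(seq.origin_map, seq.tokens) if o is not None]
    kept.sort(key=lambda x: x[0])
    positions = [o for o, _ in kept]
    if positions != list(range(len(positions))):
        raise IntegrityError(f"corrupted origin map: {positions}")
    return [t for _, t in kept]


def mlm_mask(
    ids: np.ndarray,
    vocab: Vocab,
    config: MaskingConfig,
    rng: np.random.Generator,
) -> MaskedBatch:
    """Random MLM masking with the standard 80/10/10 corruption split
    (mask-token / random word / keep). Special and label tokens are never
    candidates."""
    ids = np.asarray(ids, dtype=np.int64)
    target = ids.copy()
    inp = ids.copy()
    candidates = vocab.maskable_mask(ids)
    selected = candidates & (rng.random(len(ids)) < config.p)
    for pos in np.nonzero(selected)[0]:
        u = rng.random()
        if u < 0.8:
            inp[pos] = vocab.mask_id
        elif u < 0.9:
            inp[pos] = rng.integers(vocab.first_word_id, len(vocab))
        # else: keep the original token
    label_positions = np.nonzero(
        (ids >= vocab.label_block[0]) & (ids < vocab.label_block[1])
    )[0]
    return MaskedBatch(inp, target, selected.astype(np.int64), label_positions)


def emlm_mask(
    seq: LabeledSequence,
    vocab: Vocab,
    config: MaskingConfig,
    rng: np.random.Generator,
) -> MaskedBatch:
    """Entity masking: only entity-token positions are candidates, each masked
    independently with probability ``eta`` by pure mask-token replacement.

    A sentence without entity tokens yields an empty mask (logged), not an
    error — pseudo-labeled pre-training data may contain such sentences.
    """
    ids = vocab.encode(seq.tokens)
    target = ids.copy()
    inp = ids.copy()
    indicator = np.zeros(len(ids), dtype=np.int64)
    if not seq.entity_positions:
        logger.debug("emlm_mask: sentence has no entity tokens; empty mask")
    for pos in seq.entity_positions:
        if rng.random() < config.eta:
            inp[pos] = vocab.mask_id
            indicator[pos] = 1
    label_positions = np.array(seq.label_token_positions, dtype=np.int64)
    return MaskedBatch(inp, target, indicator, label_positions)


def render_masked(batch: MaskedBatch, vocab: Vocab) -> str:
    """Human-readable dump of a masked sequence (debug aid)."""
    parts = []
    for i, (a, b, m) in enumerate(zip(batch.input_ids, batch.target_ids, batch.mask_indicator)):
        tok = vocab.tokens[int(a)]
        parts.append(f"{tok}(->{vocab.tokens[int(b)]})" if m else tok)
    return " ".join(parts)
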