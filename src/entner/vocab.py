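"""Token vocabulary with special markers and a reserved label-token block.

Special tokens ([CLS]/[SEP]/[PAD]/[MASK]...) are inserted at batch-assembly
time only and never stored in corpus files. Label tokens (``<B-diagnosis>``
etc.) occupy a contiguous reserved block so masking code can exclude them
cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import LabelScheme, TaggedSentence

PAD, UNK, CLS, SEP, MASK, SEC = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]", "[SEC]"
SPECIALS = (PAD, UNK, CLS, SEP, MASK, SEC)


@dataclass
class Vocab:
    tokens: list[str]
    scheme: LabelScheme

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}
        n_labels = len(self.scheme.label_token_names)
        self.label_block = (len(SPECIALS), len(SPECIALS) + n_labels)

    # -- construction ---------------------------------------------------------

    @classmethod
    def build(cls, sentences: Iterable[TaggedSentence], scheme: LabelScheme) -> "Vocab":
        words: dict[str, None] = {}
        for sent in sentences:
            for tok in sent.tokens:
                words.setdefault(tok.surface, None)
        tokens = list(SPECIALS) + list(scheme.label_token_names) + sorted(words)
        return cls(tokens=tokens, scheme=scheme)

    # -- mapping ----------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def unk_id(self) -> int:
        return self.index[UNK]

    @property
    def cls_id(self) -> int:
        return self.index[CLS]

    @property
    def sep_id(self) -> int:
        return self.index[SEP]

    @property
    def mask_id(self) -> int:
        return self.index[MASK]

    @property
    def sec_id(self) -> int:
        return self.index[SEC]

    def encode(self, surfaces: Sequence[str]) -> np.ndarray:
        unk = self.unk_id
        return np.array([self.index.get(s, unk) for s in surfaces], dtype=np.int64)

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.tokens[int(i)] for i in ids]

    def label_token_id(self, tag: str) -> int:
        return self.index[f"<{tag}>"]

    def is_label_token(self, token_id: int) -> bool:
        lo, hi = self.label_block
        return lo <= token_id < hi

    def is_maskable(self, token_id: int) -> bool:
        """Ordinary word tokens only: never specials, never label tokens."""
        lo, hi = self.label_block
        return token_id >= hi

    def maskable_mask(self, ids: np.ndarray) -> np.ndarray:
        return ids >= self.label_block[1]

    @property
    def first_word_id(self) -> int:
        return self.label_block[1]

    # -- serialization ----------------------------------------------------------

    def to_dict(self) -> dict:
        return {"tokens": self.tokens, "entity_types": list(self.scheme.entity_types)}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocab":
        return cls(tokens=list(d["tokens"]),
                   scheme=LabelScheme(entity_types=tuple(d["entity_types"])))
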