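"""Token-classification model for clinical NER.

The encoder feeds a linear classifier over the BIO label space. Three
section-fusion injection points can enrich it with the note's section title:

* ``embed`` — a learned section-attribute embedding is concatenated to every
  token embedding and projected back to the hidden size (the projection is
  initialized as [I; 0], so at initialization this mode is an exact identity
  with respect to ``none``);
* ``text``  — the section title tokens are prepended to the input followed by
  a separator token;
* ``bias``  — a learned per-section offset vector is added to every token's
  label scores, shifting the output distribution.

Label dependencies are modeled by an additional transition-score layer over
label bigrams (a simulated CRF) consumed by Viterbi decoding; optionally the
transition scores are trained with a linear-chain sequence NLL. A multi-task
head can jointly predict a sentence-level flag (peri-anal disease mention)
from the first-position state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError
from .formats import LabelScheme, TaggedSentence
from .nn import (
    Adam,
    EncoderConfig,
    Linear,
    Module,
    Tensor,
    TransformerEncoder,
    log_softmax,
    logsumexp,
    softmax,
)
from .vocab import Vocab

logger = logging.getLogger(__name__)

FUSION_MODES = ("none", "embed", "text", "bias")
UNKNOWN_SECTION = "<UNK-SECTION>"
_FORBIDDEN = -1e4  # structural penalty for invalid BIO bigrams


@dataclass
class TransitionMatrix:
    """Square score matrix over BIO labels plus start/stop states."""

    scores: np.ndarray  # [(C+2), (C+2)]
    n_labels: int

    @property
    def start(self) -> int:
        return self.n_labels

    @property
    def stop(self) -> int:
        return self.n_labels + 1


def build_transitions(scheme: LabelScheme) -> TransitionMatrix:
    """Zero scores except structural BIO penalties: I-x may only follow B-x or
    I-x (never O, a different type, or the start state)."""
    labels = scheme.bio_labels
    C = len(labels)
    scores = np.zeros((C + 2, C + 2))
    for j, to in enumerate(labels):
        if not to.startswith("I-"):
            continue
        etype = to[2:]
        for i, frm in enumerate(labels):
            if frm not in (f"B-{etype}", f"I-{etype}"):
                scores[i, j] = _FORBIDDEN
        scores[C, j] = _FORBIDDEN  # start -> I-x
    return TransitionMatrix(scores=scores, n_labels=C)


def viterbi_decode(emissions: np.ndarray, transitions: TransitionMatrix) -> list[int]:
    """Best label sequence maximizing sum of emission + transition scores.

    Ties break deterministically toward the lowest label index (argmax picks
    the first maximum).
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ContractError("emissions must be a non-empty [T, C] matrix")
    T, C = emissions.shape
    tr = transitions.scores
    delta = tr[transitions.start, :C] + emissions[0]
    back = np.zeros((T, C), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + tr[:C, :C]  # [from, to]
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + emissions[t]
    delta = delta + tr[:C, transitions.stop]
    path = [int(delta.argmax())]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


@dataclass
class MultiTaskOutput:
    sentence_prob: float
    token_dists: np.ndarray  # [n_tokens, C]


class NERModel(Module):
    """Encoder + BIO classifier with optional section fusion and multi-task head."""

    def __init__(
        self,
        encoder_config: EncoderConfig,
        vocab: Vocab,
        scheme: LabelScheme = LabelScheme(),
        fusion_mode: str = "none",
        section_titles: Sequence[str] = (),
        multitask: bool = False,
        crf_nll: bool = False,
        sec_emb_dim: int = 16,
        seed: int = 0,
    ):
        if fusion_mode not in FUSION_MODES:
            raise ConfigurationError(f"unknown fusion mode {fusion_mode!r}")
        self.scheme = scheme
        self.vocab = vocab
        self.fusion_mode = fusion_mode
        self.multitask = multitask
        self.crf_nll = crf_nll
        self.sec_emb_dim = sec_emb_dim
        self.section_titles = list(section_titles)
        self._sec_index = {t: i for i, t in enumerate(self.section_titles)}
        self._unk_sec = len(self.section_titles)

        self.encoder = TransformerEncoder(encoder_config)
        rng = np.random.default_rng(seed + 7)
        C = len(scheme.bio_labels)
        D = encoder_config.hidden_dim
        self.classifier = Linear(rng, D, C)
        n_sec = len(self.section_titles) + 1

        if fusion_mode == "embed":
            self.sec_emb = Tensor(np.zeros((n_sec, sec_emb_dim)), requires_grad=True)
            proj = np.zeros((D + sec_emb_dim, D))
            proj[:D] = np.eye(D)  # identity injection at initialization
            self.fuse_proj = Tensor(proj, requires_grad=True)
        elif fusion_mode == "bias":
            self.sec_bias = Tensor(np.zeros((n_sec, C)), requires_grad=True)
        if multitask:
            self.sent_head = Linear(rng, D, 1)

        self._structural = build_transitions(scheme)
        if crf_nll:
            self.trans = Tensor(self._structural.scores.copy(), requires_grad=True)

    # -- sections --------------------------------------------------------------

    def section_id(self, title: Optional[str]) -> int:
        if title is None:
            return self._unk_sec
        idx = self._sec_index.get(title)
        if idx is None:
            logger.warning("unknown section title %r; using learned UNK attribute", title)
            return self._unk_sec
        return idx

    @property
    def transitions(self) -> TransitionMatrix:
        if self.crf_nll:
            return TransitionMatrix(self.trans.data, self._structural.n_labels)
        return self._structural

    # -- batch assembly ----------------------------------------------------------

    def assemble(self, sentences: Sequence[TaggedSentence]) -> dict:
        """Pack sentences into padded arrays.

        ``token_pos[b]`` holds the positions of the original tokens within the
        assembled sequence (excluding [CLS]/[SEP]/padding and, for text-mode
        fusion, the prepended title tokens).
        """
        vocab = self.vocab
        rows, labels_rows, token_pos, sec_ids, flags = [], [], [], [], []
        budget = self.encoder.config.max_len - 2
        for sent in sentences:
            prefix: list[int] = []
            if self.fusion_mode == "text" and sent.section:
                prefix = list(vocab.encode(sent.section.split())) + [vocab.sec_id]
            ids = list(vocab.encode(sent.surfaces()))
            lab = [self.scheme.label_index(t) for t in sent.tags]
            room = budget - len(prefix)
            ids, lab = ids[:room], lab[:room]
            row = [vocab.cls_id] + prefix + ids + [vocab.sep_id]
            rows.append(row)
            labels_rows.append(lab)
            start = 1 + len(prefix)
            token_pos.append(list(range(start, start + len(ids))))
            sec_ids.append(self.section_id(sent.section))
            flags.append(sent.sentence_flag if sent.sentence_flag is not None else 0)
        T = max(len(r) for r in rows)
        B = len(rows)
        ids_arr = np.full((B, T), vocab.pad_id, dtype=np.int64)
        pad = np.zeros((B, T), bool)
        for b, row in enumerate(rows):
            ids_arr[b, : len(row)] = row
            pad[b, : len(row)] = True
        return {
            "ids": ids_arr,
            "pad_mask": pad,
            "labels": labels_rows,
            "token_pos": token_pos,
            "sec_ids": np.array(sec_ids, dtype=np.int64),
            "flags": np.array(flags, dtype=np.float64),
        }

    # -- forward -----------------------------------------------------------------

    def encode(
        self,
        ids: np.ndarray,
        pad_mask: np.ndarray,
        sec_ids: Optional[np.ndarray] = None,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        if self.fusion_mode in ("embed", "bias", "text") and sec_ids is None:
            if self.fusion_mode == "embed":
                raise ContractError("embed fusion requires section ids")
        override = None
        if self.fusion_mode == "embed":
            from .nn import concat, embedding

            B, T = ids.shape
            tok = self.encoder.embed(ids)
            sec = embedding(self.sec_emb, np.repeat(sec_ids[:, None], T, axis=1))
            override = concat([tok, sec], axis=-1) @ self.fuse_proj
        return self.encoder(ids, pad_mask, training=training, rng=rng,
                            token_emb_override=override)

    def token_logits(self, h: Tensor, sec_ids: Optional[np.ndarray] = None) -> Tensor:
        """Per-position scores over the BIO labels; in bias mode a per-section
        offset vector shifts every position's scores identically."""
        logits = self.classifier(h)
        if self.fusion_mode == "bias":
            if sec_ids is None:
                raise ContractError("bias fusion requires section ids")
            from .nn import embedding

            bias = embedding(self.sec_bias, sec_ids)  # [B, C]
            logits = logits + bias.reshape(bias.shape[0], 1, bias.shape[1])
        return logits

    def forward(
        self,
        batch: dict,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[Tensor, Tensor]:
        """Returns (hidden states, label logits) for an assembled batch."""
        h = self.encode(batch["ids"], batch["pad_mask"], batch["sec_ids"],
                        training=training, rng=rng)
        return h, self.token_logits(h, batch["sec_ids"])

    # -- multi-task ---------------------------------------------------------------

    def multitask_forward(self, sentence: TaggedSentence) -> MultiTaskOutput:
        """Joint forward: the sentence head reads only the first-position
        ([CLS]) state; the token head reads the remaining positions."""
        if not self.multitask:
            raise ContractError("multi-task head is disabled on this model")
        batch = self.assemble([sentence])
        h, logits = self.forward(batch)
        z = (Tensor(h.data[0, 0]) @ self.sent_head.w + self.sent_head.b).data
        prob = float(1.0 / (1.0 + np.exp(-z[0])))
        pos = batch["token_pos"][0]
        dists = softmax(Tensor(logits.data[0][pos]), axis=-1).data
        return MultiTaskOutput(sentence_prob=prob, token_dists=dists)

    # -- CRF ------------------------------------------------------------------------

    def crf_nll_loss(self, emissions: Tensor, tags: Sequence[int]) -> Tensor:
        """Linear-chain sequence NLL  -[score(gold path) - log Z] for one
        sentence's emissions [T, C] using the learnable transition scores."""
        if not self.crf_nll:
            raise ContractError("crf_nll mode is disabled")
        tr = self.trans
        C = self._structural.n_labels
        start, stop = self._structural.start, self._structural.stop
        T = emissions.shape[0]
        gold = emissions[(np.arange(T), np.asarray(tags))].sum()
        gold = gold + tr[(start, tags[0])] + tr[(tags[-1], stop)]
        idx_from = np.asarray(tags[:-1])
        idx_to = np.asarray(tags[1:])
        if T > 1:
            gold = gold + tr[(idx_from, idx_to)].sum()
        alpha = tr[start, :C] + emissions[0]
        for t in range(1, T):
            alpha = logsumexp(alpha.reshape(C, 1) + tr[:C, :C], axis=0) + emissions[t]
        logz = logsumexp(alpha + tr[:C, stop], axis=0)
        return logz - gold

    # -- prediction -------------------------------------------------------------------

    def predict(
        self, sentences: Sequence[TaggedSentence], batch_size: int = 32
    ) -> tuple[list[list[str]], list[np.ndarray]]:
        """Viterbi-decoded BIO tags plus per-token max-probability scores."""
        all_tags: list[list[str]] = []
        all_scores: list[np.ndarray] = []
        labels = self.scheme.bio_labels
        for lo in range(0, len(sentences), batch_size):
            chunk = sentences[lo : lo + batch_size]
            batch = self.assemble(chunk)
            _, logits = self.forward(batch, training=False)
            probs = softmax(logits, axis=-1).data
            for b, pos in enumerate(batch["token_pos"]):
                emis = np.log(np.clip(probs[b][pos], 1e-12, None))
                if len(pos) == 0:
                    all_tags.append([])
                    all_scores.append(np.array([]))
                    continue
                path = viterbi_decode(emis, self.transitions)
                all_tags.append([labels[i] for i in path])
                all_scores.append(probs[b][pos].max(axis=-1))
        return all_tags, all_scores

    # -- serialization ------------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = {
            "encoder_config": self.encoder.config.to_dict(),
            "vocab": self.vocab.to_dict(),
            "fusion_mode": self.fusion_mode,
            "section_titles": self.section_titles,
            "multitask": self.multitask,
            "crf_nll": self.crf_nll,
            "sec_emb_dim": self.sec_emb_dim,
        }
        arrays = {f"w::{k}": v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "NERModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            weights = {k[3:]: f[k] for k in f.files if k.startswith("w::")}
        model = cls(
            encoder_config=EncoderConfig(**meta["encoder_config"]),
            vocab=Vocab.from_dict(meta["vocab"]),
            scheme=Vocab.from_dict(meta["vocab"]).scheme,
            fusion_mode=meta["fusion_mode"],
            section_titles=meta["section_titles"],
            multitask=meta["multitask"],
            crf_nll=meta["crf_nll"],
            sec_emb_dim=meta["sec_emb_dim"],
        )
        model.load_state_dict(weights)
        return model

    @classmethod
    def from_checkpoint(
        cls,
        checkpoint,
        fusion_mode: str = "none",
        section_titles: Sequence[str] = (),
        multitask: bool = False,
        crf_nll: bool = False,
        seed: int = 0,
    ) -> "NERModel":
        """Initialize from a continued-pre-training checkpoint: encoder weights
        are transferred, the classifier starts fresh."""
        model = cls(
            encoder_config=checkpoint.encoder_config,
            vocab=checkpoint.vocab,
            scheme=checkpoint.vocab.scheme,
            fusion_mode=fusion_mode,
            section_titles=section_titles,
            multitask=multitask,
            crf_nll=crf_nll,
            seed=seed,
        )
        enc_state = {
            k[len("encoder."):]: v
            for k, v in checkpoint.weights.items()
            if k.startswith("encoder.")
        }
        model.encoder.load_state_dict(enc_state)
        return model
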