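"""Continued pre-training objectives over a small trainable encoder.

Three runnable variants:

* ``mlm`` — random masked-language-modeling on in-domain text;
* ``emlm`` — entity MLM: only entity tokens are masked (rate ``eta``), with
  their BIO tag inserted as label tokens before and after each entity token,
  trained with the masked-token negative log-likelihood;
* ``emlm_cl`` — EMLM plus a masked-entity contrastive objective against a
  frozen teacher initialized from the identical checkpoint: the student's
  representation of each masked entity token is pulled toward the teacher's
  representation of the same (unmasked) position and pushed away from the
  other positions of the sentence via a temperature-scaled cosine softmax.

The total pre-training loss is the plain sum  L_pretrain = L_CL + L_E-MLM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, IntegrityError
from .formats import LabelScheme, TaggedSentence
from .masking import (
    LabeledSequence,
    MaskedBatch,
    MaskingConfig,
    emlm_mask,
    insert_entity_labels,
    mlm_mask,
)
from .nn import (
    Adam,
    EncoderConfig,
    Linear,
    Module,
    Tensor,
    TransformerEncoder,
    log_softmax,
)
from .vocab import Vocab

logger = logging.getLogger(__name__)

VARIANTS = ("mlm", "emlm", "emlm_cl")


@dataclass(frozen=True)
class ContrastiveConfig:
    """Optimization settings for continued pre-training. The temperature tau
    scales the cosine similarities inside the contrastive softmax; small values
    sharpen the distinction between the positive pair and other positions."""

    tau: float = 0.01
    steps: int = 200
    batch_size: int = 32
    lr: float = 1e-3  # scratch-scale encoder; a pre-trained LM would want ~1e-4
    warmup_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if self.steps <= 0 or self.batch_size <= 0:
            raise ConfigurationError("steps and batch_size must be positive")


@dataclass
class LossBundle:
    """Named scalar losses; pre-training maintains l_pretrain = l_cl + l_emlm."""

    l_emlm: float = 0.0
    l_cl: float = 0.0
    l_pretrain: float = 0.0
    l_ce: float = 0.0
    l_rdrop: float = 0.0
    l_finetune: float = 0.0

    def check_finite(self) -> None:
        for name, val in vars(self).items():
            if not np.isfinite(val):
                raise IntegrityError(f"non-finite loss {name}={val}")


class PretrainModel(Module):
    """Encoder plus a language-modeling head projecting to the vocabulary."""

    def __init__(self, config: EncoderConfig):
        self.encoder = TransformerEncoder(config)
        rng = np.random.default_rng(config.seed + 1)
        self.lm_head = Linear(rng, config.hidden_dim, config.vocab_size)

    def __call__(self, ids, pad_mask, training=False, rng=None):
        h = self.encoder(ids, pad_mask, training=training, rng=rng)
        return h, self.lm_head(h)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def emlm_loss(logits: "Tensor | np.ndarray", batch: MaskedBatch) -> "Tensor | float":
    """Masked-token negative log-likelihood  -sum_i m_i log P(x_i | X^m).

    ``logits`` are unnormalized per-position scores over the vocabulary,
    aligned with ``batch``; positions with mask indicator 0 contribute zero.
    Returns a graph node when given a Tensor, else a float.
    """
    as_tensor = isinstance(logits, Tensor)
    t = logits if as_tensor else Tensor(np.asarray(logits, dtype=np.float64))
    if t.shape[0] != len(batch.target_ids):
        raise ContractError("logits not aligned with batch positions")
    masked = np.nonzero(batch.mask_indicator)[0]
    if masked.size == 0:
        return Tensor(0.0) if as_tensor else 0.0
    lp = log_softmax(t, axis=-1)
    picked = lp[(masked, batch.target_ids[masked])]
    loss = -picked.sum()
    return loss if as_tensor else loss.item()


def contrastive_loss(
    student: "Tensor | np.ndarray",
    teacher: np.ndarray,
    mask_indicator: np.ndarray,
    tau: float,
) -> "Tensor | float":
    """Masked-entity contrastive loss.

    For each position i with mask indicator 1, the student representation of
    the masked token is aligned with the teacher representation of the same
    position:  -log softmax_j( cos(h_i^m, h_j) / tau ) evaluated at j = i,
    with the softmax taken over all positions j of the same sentence.
    Gradients flow to the student only (the teacher enters as constants).
    """
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    as_tensor = isinstance(student, Tensor)
    s = student if as_tensor else Tensor(np.asarray(student, dtype=np.float64))
    t = np.asarray(teacher.data if isinstance(teacher, Tensor) else teacher, dtype=np.float64)
    if s.shape != t.shape:
        raise ContractError("student/teacher shapes differ")
    indicator = np.asarray(mask_indicator)
    masked = np.nonzero(indicator)[0]
    if masked.size == 0:
        return Tensor(0.0) if as_tensor else 0.0

    t_norms = np.linalg.norm(t, axis=-1)
    s_norms = np.linalg.norm(s.data, axis=-1)
    if np.any(t_norms == 0) or np.any(s_norms[masked] == 0):
        raise ValueError("zero-norm representation: cosine similarity undefined")

    s_unit = s / (s * s).sum(axis=-1, keepdims=True).pow(0.5)
    t_unit = Tensor(t / t_norms[:, None])
    sims = (s_unit @ t_unit.data.T) * (1.0 / tau)  # [n, n]
    lp = log_softmax(sims, axis=-1)
    loss = -lp[(masked, masked)].sum()
    return loss if as_tensor else loss.item()


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------

def assemble_batch(
    items: Sequence[MaskedBatch], vocab: Vocab, max_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad per-sentence masked sequences into [B, T] arrays, adding [CLS]/[SEP].

    Returns (input_ids, target_ids, mask_indicator, pad_mask).
    """
    budget = max_len - 2
    trimmed = [
        (it.input_ids[:budget], it.target_ids[:budget], it.mask_indicator[:budget])
        for it in items
    ]
    T = max(len(x[0]) for x in trimmed) + 2
    B = len(trimmed)
    inp = np.full((B, T), vocab.pad_id, dtype=np.int64)
    tgt = np.full((B, T), vocab.pad_id, dtype=np.int64)
    ind = np.zeros((B, T), dtype=np.int64)
    pad = np.zeros((B, T), dtype=bool)
    for b, (i_ids, t_ids, m) in enumerate(trimmed):
        n = len(i_ids)
        inp[b, 0] = vocab.cls_id
        inp[b, 1 : n + 1] = i_ids
        inp[b, n + 1] = vocab.sep_id
        tgt[b, 0] = vocab.cls_id
        tgt[b, 1 : n + 1] = t_ids
        tgt[b, n + 1] = vocab.sep_id
        ind[b, 1 : n + 1] = m
        pad[b, : n + 2] = True
    return inp, tgt, ind, pad


def init_label_token_embeddings(encoder: TransformerEncoder, vocab: Vocab) -> None:
    """Initialize each label-token embedding as the mean of the embeddings of
    the words making up its entity-type name (e.g. ``<B-disease_location>``
    from "disease" and "location"), so inserted labels start out semantically
    close to related vocabulary."""
    for tag_token in vocab.scheme.label_token_names:
        etype = tag_token[3:-1]  # strip "<B-" / "<I-" and ">"
        word_ids = [
            vocab.index[w] for w in etype.split("_") if w in vocab.index
        ]
        if word_ids:
            mean_emb = encoder.tok_emb.data[word_ids].mean(axis=0)
            encoder.tok_emb.data[vocab.index[tag_token]] = mean_emb


# ---------------------------------------------------------------------------
# Training step and loop
# ---------------------------------------------------------------------------

def pretrain_step(
    student: PretrainModel,
    teacher: Optional[TransformerEncoder],
    items: Sequence[MaskedBatch],
    vocab: Vocab,
    tau: float,
    optimizer: Adam,
    rng: np.random.Generator,
    use_cl: bool,
) -> LossBundle:
    """One optimization step on a batch of masked sentences.

    The student is updated in place; the teacher (when present) is read-only —
    its parameters are bit-identical before and after the step.
    """
    max_len = student.encoder.config.max_len
    inp, tgt, ind, pad = assemble_batch(items, vocab, max_len)
    h, logits = student(inp, pad, training=True, rng=rng)

    l_emlm = Tensor(0.0)
    n_masked = 0
    for b in range(inp.shape[0]):
        row = MaskedBatch(inp[b], tgt[b], ind[b])
        l_emlm = l_emlm + emlm_loss(logits[b], row)
        n_masked += int(ind[b].sum())

    l_cl = Tensor(0.0)
    if use_cl:
        if teacher is None:
            raise ContractError("contrastive variant requires a teacher")
        h_teacher = teacher(tgt, pad, training=False)
        for b in range(inp.shape[0]):
            real = np.nonzero(pad[b])[0]
            if ind[b].sum() == 0:
                continue
            l_cl = l_cl + contrastive_loss(
                h[b][real], h_teacher.data[b][real], ind[b][real], tau
            )

    bundle = LossBundle(
        l_emlm=float(l_emlm.data),
        l_cl=float(l_cl.data),
        l_pretrain=float(l_cl.data) + float(l_emlm.data),
    )
    bundle.check_finite()

    total = (l_cl + l_emlm) * (1.0 / max(1, n_masked))
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return bundle


@dataclass
class Checkpoint:
    """Self-describing archive: encoder config, vocabulary, weights, rng state."""

    encoder_config: EncoderConfig
    vocab: Vocab
    weights: dict[str, np.ndarray]
    variant: str
    rng_state: Optional[dict] = None
    log: list[dict] = field(default_factory=list)

    def build_model(self) -> PretrainModel:
        model = PretrainModel(self.encoder_config)
        model.load_state_dict(self.weights)
        return model

    def build_encoder(self) -> TransformerEncoder:
        enc = TransformerEncoder(self.encoder_config)
        enc.load_state_dict(
            {k[len("encoder."):]: v for k, v in self.weights.items() if k.startswith("encoder.")}
        )
        return enc

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = {
            "encoder_config": self.encoder_config.to_dict(),
            "vocab": self.vocab.to_dict(),
            "variant": self.variant,
            "rng_state": self.rng_state,
            "log": self.log,
        }
        arrays = {f"w::{k}": v for k, v in self.weights.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            weights = {k[3:]: f[k] for k in f.files if k.startswith("w::")}
        return cls(
            encoder_config=EncoderConfig(**meta["encoder_config"]),
            vocab=Vocab.from_dict(meta["vocab"]),
            weights=weights,
            variant=meta["variant"],
            rng_state=meta.get("rng_state"),
            log=meta.get("log", []),
        )


def _sentence_items(
    sentences: Sequence[TaggedSentence],
    vocab: Vocab,
    variant: str,
    masking: MaskingConfig,
    rng: np.random.Generator,
    idx: np.ndarray,
) -> list[MaskedBatch]:
    items = []
    for i in idx:
        sent = sentences[int(i)]
        if variant == "mlm":
            ids = vocab.encode(sent.surfaces())
            items.append(mlm_mask(ids, vocab, masking, rng))
        else:
            seq = insert_entity_labels(sent, vocab.scheme)
            items.append(emlm_mask(seq, vocab, masking, rng))
    return items


def run_pretraining(
    sentences: Sequence[TaggedSentence],
    variant: str,
    encoder_config: Optional[EncoderConfig] = None,
    masking: Optional[MaskingConfig] = None,
    contrastive: ContrastiveConfig = ContrastiveConfig(),
    scheme: LabelScheme = LabelScheme(),
    vocab: Optional[Vocab] = None,
    seed: int = 0,
) -> Checkpoint:
    """Continually pre-train an encoder on tagged sentences under one variant.

    The ``mlm`` variant ignores BIO annotations entirely; ``emlm``/``emlm_cl``
    require at least one entity token in the corpus (pseudo-labels qualify).
    Returns a checkpoint carrying config, vocabulary, weights, rng state and
    a per-step loss log.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown pre-training variant {variant!r}")
    if not sentences:
        raise ConfigurationError("empty pre-training corpus")
    if masking is None:
        masking = MaskingConfig(strategy="mlm" if variant == "mlm" else "emlm")
    if vocab is None:
        vocab = Vocab.build(sentences, scheme)
    if encoder_config is None:
        encoder_config = EncoderConfig(vocab_size=len(vocab), seed=seed)
    elif encoder_config.vocab_size != len(vocab):
        raise ConfigurationError("encoder_config.vocab_size must match the vocabulary")

    if variant in ("emlm", "emlm_cl"):
        if not any(tag != "O" for s in sentences for tag in s.tags):
            raise ConfigurationError(
                f"variant {variant!r} needs entity annotations, corpus has none"
            )

    student = PretrainModel(encoder_config)
    init_label_token_embeddings(student.encoder, vocab)
    teacher: Optional[TransformerEncoder] = None
    if variant == "emlm_cl":
        # frozen teacher initialized from the identical starting checkpoint
        teacher = TransformerEncoder(encoder_config)
        teacher.load_state_dict(student.encoder.state_dict())

    rng = np.random.default_rng(seed)
    optimizer = Adam(
        student.parameters(),
        lr=contrastive.lr,
        warmup_ratio=contrastive.warmup_ratio,
        total_steps=contrastive.steps,
    )
    log: list[dict] = []
    n = len(sentences)
    for step in range(contrastive.steps):
        idx = rng.integers(0, n, size=min(contrastive.batch_size, n))
        items = _sentence_items(sentences, vocab, variant, masking, rng, idx)
        if all(it.mask_indicator.sum() == 0 for it in items):
            logger.debug("step %d: batch had no masked positions; skipped", step)
            continue
        bundle = pretrain_step(
            student, teacher, items, vocab, contrastive.tau, optimizer, rng,
            use_cl=(variant == "emlm_cl"),
        )
        n_masked = int(sum(it.mask_indicator.sum() for it in items))
        log.append(
            {"step": step, "l_emlm": bundle.l_emlm, "l_cl": bundle.l_cl,
             "l_pretrain": bundle.l_pretrain, "n_masked": n_masked,
             "l_per_masked": bundle.l_pretrain / max(1, n_masked),
             "lr": optimizer.current_lr()}
        )

    return Checkpoint(
        encoder_config=encoder_config,
        vocab=vocab,
        weights=student.state_dict(),
        variant=variant,
        rng_state=rng.bit_generator.state,
        log=log,
    )


def masked_entity_alignment(
    encoder: TransformerEncoder,
    teacher: TransformerEncoder,
    sentences: Sequence[TaggedSentence],
    vocab: Vocab,
    masking: MaskingConfig,
    seed: int = 0,
) -> float:
    """Mean cosine similarity between the student's masked-entity
    representations and the teacher's unmasked ones (alignment diagnostic)."""
    rng = np.random.default_rng(seed)
    sims: list[float] = []
    for sent in sentences:
        seq = insert_entity_labels(sent, vocab.scheme)
        if not seq.entity_positions:
            continue
        item = emlm_mask(seq, vocab, masking, rng)
        inp, tgt, ind, pad = assemble_batch([item], vocab, encoder.config.max_len)
        hs = encoder(inp, pad).data[0]
        ht = teacher(tgt, pad).data[0]
        for pos in np.nonzero(ind[0])[0]:
            a, b = hs[pos], ht[pos]
            sims.append(float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b))))
    return float(np.mean(sims)) if sims else float("nan")
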