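"""Supervised NER fine-tuning.

Training combines label-smoothed token cross-entropy with an optional R-drop
consistency term: the same batch is passed through the encoder twice under
independent dropout draws and the two per-token label distributions are pulled
together with a symmetric (bidirectional) KL penalty,

    L_finetune = L_CE + alpha * L_rdrop .

Class imbalance is handled by sentence up-sampling, unlabeled notes by a
single pseudo-labeling pass whose output is kept as silver data, flagged
distinct from gold. Model selection is early stopping on dev strict micro-F1.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError
from .evaluation import evaluate
from .formats import (
    ClinicalNote,
    LabelScheme,
    TaggedSentence,
    bio_to_spans,
    note_to_sentences,
    repair_bio,
)
from .model import NERModel
from .nn import Adam, Tensor, log_softmax
from .pretraining import LossBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FinetuneConfig:
    """Fine-tuning hyper-parameters.

    ``alpha`` weights the R-drop term, ``epsilon`` is the label-smoothing mass
    spread uniformly over the label space, ``patience`` the number of epochs
    without dev-F1 improvement before stopping. The learning rate default suits
    the small from-scratch encoder used at desk scale.
    """

    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    alpha: float = 1.0
    epsilon: float = 0.1
    patience: int = 10
    seed: int = 0
    upsample_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if not (0.0 <= self.epsilon < 1.0):
            raise ConfigurationError("epsilon must be in [0, 1)")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")


@dataclass
class DistributionPair:
    """Two per-token label distributions from two stochastic forward passes."""

    p1: np.ndarray  # [n_tokens, C]
    p2: np.ndarray

    def __post_init__(self) -> None:
        if self.p1.shape != self.p2.shape:
            raise ContractError("distribution pair shapes differ")
        for p in (self.p1, self.p2):
            if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
                raise ContractError("distribution rows must be normalized")


@dataclass
class PseudoLabelSet:
    """Model-generated silver annotations, never to be confused with gold."""

    sentences: list[TaggedSentence]
    provenance: str
    scores: list[float]
    is_silver: bool = True


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def token_ce_loss(
    pred_dists: np.ndarray, gold: Sequence[int], epsilon: float = 0.0
) -> float:
    """Label-smoothed cross-entropy, averaged over tokens:
    targets are (1-eps)*onehot + eps/|C|; eps=0 recovers plain CE."""
    p = np.asarray(pred_dists, dtype=np.float64)
    gold = np.asarray(gold, dtype=np.int64)
    if p.ndim != 2 or p.shape[0] != len(gold):
        raise ContractError("shape mismatch between distributions and gold tags")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ContractError("prediction rows must be normalized distributions")
    C = p.shape[1]
    if np.any(gold < 0) or np.any(gold >= C):
        raise ContractError("gold tag index outside label space")
    logp = np.log(np.clip(p, 1e-12, None))
    smooth = epsilon / C
    per_tok = -(1.0 - epsilon) * logp[np.arange(len(gold)), gold] - smooth * logp.sum(axis=-1)
    return float(per_tok.mean())


def rdrop_loss(pair: DistributionPair) -> float:
    """Mean over tokens of the symmetric KL  (1/2)[KL(P1||P2) + KL(P2||P1)].

    Zero probabilities facing positive mass are epsilon-clamped.
    """
    p1 = np.clip(pair.p1, 1e-12, None)
    p2 = np.clip(pair.p2, 1e-12, None)
    kl12 = (pair.p1 * (np.log(p1) - np.log(p2))).sum(axis=-1)
    kl21 = (pair.p2 * (np.log(p2) - np.log(p1))).sum(axis=-1)
    return float((0.5 * (kl12 + kl21)).mean())


def finetune_loss(l_ce, l_rdrop, alpha: float):
    """Exact weighted sum L_CE + alpha * L_rdrop (floats or graph nodes)."""
    return l_ce + alpha * l_rdrop


def _ce_from_logprobs(lp: Tensor, gold: np.ndarray, epsilon: float) -> Tensor:
    """Tensor-path label-smoothed CE over flattened valid token rows [n, C]."""
    n, C = lp.shape
    picked = lp[(np.arange(n), gold)]
    loss = -(1.0 - epsilon) * picked.sum() - (epsilon / C) * lp.sum()
    return loss * (1.0 / n)


def _rdrop_from_logprobs(lp1: Tensor, lp2: Tensor) -> Tensor:
    n = lp1.shape[0]
    p1, p2 = lp1.exp(), lp2.exp()
    kl12 = (p1 * (lp1 - lp2)).sum()
    kl21 = (p2 * (lp2 - lp1)).sum()
    return (kl12 + kl21) * (0.5 / n)


# ---------------------------------------------------------------------------
# Two-pass forward
# ---------------------------------------------------------------------------

def two_pass_forward(
    model: NERModel,
    sentences: Sequence[TaggedSentence],
    rng: np.random.Generator,
    training: bool = True,
) -> DistributionPair:
    """Pass the same sentences through the encoder twice with independent
    dropout draws; returns the two token-level distribution sets. With dropout
    rate 0 the passes coincide exactly."""
    if not training:
        raise ContractError("two_pass_forward requires training mode")
    from .nn import softmax

    batch = model.assemble(sentences)
    dists = []
    for _ in range(2):
        _, logits = model.forward(batch, training=True, rng=rng)
        probs = softmax(logits, axis=-1).data
        rows = [probs[b][pos] for b, pos in enumerate(batch["token_pos"])]
        dists.append(np.concatenate(rows, axis=0))
    return DistributionPair(p1=dists[0], p2=dists[1])


# ---------------------------------------------------------------------------
# Data augmentation
# ---------------------------------------------------------------------------

def upsample(
    sentences: Sequence[TaggedSentence],
    scheme: LabelScheme = LabelScheme(),
    ratio: float = 2.0,
) -> list[TaggedSentence]:
    """Duplicate sentences mentioning under-represented entity classes until
    each class's sentence count reaches (max class count) / ratio.

    The output is a multiset superset of the input; nothing is dropped.
    """
    if not sentences:
        raise ConfigurationError("empty training set")
    out = list(sentences)

    def class_counts(sents: Sequence[TaggedSentence]) -> dict[str, int]:
        counts = {t: 0 for t in scheme.entity_types}
        for s in sents:
            present = {tag[2:] for tag in s.tags if tag.startswith("B-")}
            for t in present:
                counts[t] += 1
        return counts

    counts = class_counts(out)
    max_count = max(counts.values())
    if max_count == 0:
        return out
    floor = max_count / ratio
    for etype in scheme.entity_types:
        if counts[etype] == 0 or counts[etype] >= floor:
            continue
        pool = [s for s in sentences if f"B-{etype}" in s.tags]
        i = 0
        need = math.ceil(floor) - counts[etype]
        while need > 0:
            out.append(copy.deepcopy(pool[i % len(pool)]))
            i += 1
            need -= 1
            counts[etype] += 1
    return out


# ---------------------------------------------------------------------------
# Pseudo-labeling
# ---------------------------------------------------------------------------

def pseudo_label(
    model: NERModel,
    notes: Sequence[ClinicalNote],
    threshold: Optional[float] = None,
    provenance: str = "unnamed-checkpoint",
) -> PseudoLabelSet:
    """Predict entities on unlabeled notes and keep them as silver data.

    Predictions are Viterbi-decoded and BIO-repaired. With a threshold, only
    sentences whose mean per-token max probability passes it are kept; the
    default keeps everything (silver data stays silver either way).
    """
    if not notes:
        logger.warning("pseudo_label called with an empty unlabeled pool")
        return PseudoLabelSet([], provenance, [])
    sents: list[TaggedSentence] = []
    for note in notes:
        sents.extend(note_to_sentences(note, spans=()))
    tags_list, scores_list = model.predict(sents)
    silver: list[TaggedSentence] = []
    scores: list[float] = []
    for sent, tags, tok_scores in zip(sents, tags_list, scores_list):
        if not tags:
            continue
        fixed, _ = repair_bio(tags, model.scheme)
        conf = float(tok_scores.mean()) if len(tok_scores) else 0.0
        if threshold is not None and conf < threshold:
            continue
        flag = int(any(t.endswith("peri_anal_disease") for t in fixed))
        silver.append(
            TaggedSentence(tokens=sent.tokens, tags=fixed, section=sent.section,
                           sentence_flag=flag, doc_id=sent.doc_id)
        )
        scores.append(conf)
    return PseudoLabelSet(silver, provenance, scores)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def dev_strict_f1(model: NERModel, dev: Sequence[TaggedSentence]) -> float:
    tags_list, _ = model.predict(dev)
    gold, pred = [], []
    for sent, ptags in zip(dev, tags_list):
        gold.append(bio_to_spans(sent.tokens, sent.tags, model.scheme))
        pred.append(bio_to_spans(sent.tokens, ptags, model.scheme))
    return evaluate(gold, pred, collect_errors=False).strict.f1


def train(
    model: NERModel,
    train_sentences: Sequence[TaggedSentence],
    dev_sentences: Sequence[TaggedSentence],
    config: FinetuneConfig = FinetuneConfig(),
    use_rdrop: bool = False,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train with per-epoch dev evaluation and early stopping.

    Returns the best state dict (also loaded back into ``model``) and a log
    with one record per completed epoch (losses, dev strict F1).
    """
    if not train_sentences:
        raise ConfigurationError("empty training set")
    if not dev_sentences:
        raise ConfigurationError("empty dev set")
    rng = np.random.default_rng(config.seed)
    data = [s for s in train_sentences if s.tokens]
    n_steps = config.epochs * max(1, len(data) // config.batch_size)
    optimizer = Adam(model.parameters(), lr=config.lr, warmup_ratio=0.1,
                     total_steps=n_steps)
    best_f1 = -1.0
    best_state = model.state_dict()
    bad_epochs = 0
    log: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        ep_ce = ep_rd = ep_total = 0.0
        n_batches = 0
        for lo in range(0, len(data), config.batch_size):
            chunk = [data[int(i)] for i in order[lo : lo + config.batch_size]]
            batch = model.assemble(chunk)
            gold = np.concatenate([np.asarray(l, dtype=np.int64) for l in batch["labels"]])
            if gold.size == 0:
                continue

            def pass_logprobs() -> tuple[Tensor, Tensor]:
                h, logits = model.forward(batch, training=True, rng=rng)
                rows = [logits[b][pos] for b, pos in enumerate(batch["token_pos"]) if pos]
                flat = rows[0] if len(rows) == 1 else _vcat(rows)
                return h, log_softmax(flat, axis=-1)

            h1, lp1 = pass_logprobs()
            if use_rdrop:
                _, lp2 = pass_logprobs()
                l_ce = (_ce_from_logprobs(lp1, gold, config.epsilon)
                        + _ce_from_logprobs(lp2, gold, config.epsilon)) * 0.5
                l_rd = _rdrop_from_logprobs(lp1, lp2)
            else:
                l_ce = _ce_from_logprobs(lp1, gold, config.epsilon)
                l_rd = Tensor(0.0)
            total = finetune_loss(l_ce, l_rd, config.alpha if use_rdrop else 0.0)

            if model.multitask:
                z = h1[(slice(None), 0)] @ model.sent_head.w + model.sent_head.b
                flags = batch["flags"]
                # binary cross-entropy via log-sigmoid, numerically stable
                zt = z.reshape(z.shape[0])
                bce = (_softplus(zt) - zt * Tensor(flags)).mean()
                total = total + bce

            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            ep_ce += float(l_ce.data)
            ep_rd += float(l_rd.data)
            ep_total += float(total.data)
            n_batches += 1

        f1 = dev_strict_f1(model, dev_sentences)
        bundle = LossBundle(
            l_ce=ep_ce / max(1, n_batches),
            l_rdrop=ep_rd / max(1, n_batches),
            l_finetune=ep_total / max(1, n_batches),
        )
        bundle.check_finite()
        log.append({"epoch": epoch, "l_ce": bundle.l_ce, "l_rdrop": bundle.l_rdrop,
                    "l_finetune": bundle.l_finetune, "dev_strict_f1": f1})
        if f1 > best_f1:
            best_f1 = f1
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    model.load_state_dict(best_state)
    return best_state, log


def _vcat(rows: list[Tensor]) -> Tensor:
    from .nn import concat

    return concat(rows, axis=0)


def _softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) = max(x,0) + log(1 + e^-|x|), with the max detached constants
    m = np.maximum(x.data, 0.0)
    return (((x - m).exp() + Tensor(np.exp(-m))).log()) + m
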