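"""Runnable experiment matrix: the compared method settings as named variants.

Each variant name encodes its switches: the continued-pre-training flavor
(none / MLM / EMLM / EMLM+CL), whether section information is fused into the
model (FS), and whether pseudo-labels plus R-drop consistency are used (PL).
All variants of one run share the same document-level train/dev/test splits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .finetuning import FinetuneConfig, pseudo_label, train, upsample
from .formats import LabelScheme, TaggedSentence, bio_to_spans, note_to_sentences
from .evaluation import evaluate
from .masking import MaskingConfig
from .model import NERModel
from .nn import EncoderConfig
from .pretraining import ContrastiveConfig, run_pretraining
from .synthetic import CorpusSpec, GeneratedNote, generate_corpus
from .vocab import Vocab

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSpec:
    """Switches derived uniquely from a variant name."""

    name: str
    pretrain_variant: Optional[str]  # None | mlm | emlm | emlm_cl
    fusion_mode: str                 # none | embed | text | bias
    pseudo_labels: bool
    rdrop: bool


VARIANT_TABLE: dict[str, VariantSpec] = {
    "FT": VariantSpec("FT", None, "none", False, False),
    "FT-FS": VariantSpec("FT-FS", None, "embed", False, False),
    "FT-FS-PL": VariantSpec("FT-FS-PL", None, "embed", True, True),
    "MLM-FT-FS-PL": VariantSpec("MLM-FT-FS-PL", "mlm", "embed", True, True),
    "EMLM-FT": VariantSpec("EMLM-FT", "emlm", "none", False, False),
    "EMLM-FT-FS-PL": VariantSpec("EMLM-FT-FS-PL", "emlm", "embed", True, True),
    "EMLM-CL-FT-FS-PL": VariantSpec("EMLM-CL-FT-FS-PL", "emlm_cl", "embed", True, True),
}


def variant_spec(name: str) -> VariantSpec:
    try:
        return VARIANT_TABLE[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown variant {name!r}; choose from {sorted(VARIANT_TABLE)}"
        ) from None


@dataclass
class RunConfig:
    """Everything needed to reproduce a matrix run, serialized alongside results."""

    corpus: CorpusSpec = field(default_factory=CorpusSpec)
    variants: tuple[str, ...] = ("FT", "EMLM-CL-FT-FS-PL")
    seeds: tuple[int, ...] = (0, 1, 2)
    split_seed: int = 12345
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    hidden_dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    max_len: int = 48
    dropout_rate: float = 0.1
    masking: MaskingConfig = field(default_factory=lambda: MaskingConfig(strategy="emlm"))
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corpus"]["section_inventory"] = [
            {"title": s.title, "admissible": list(s.admissible)}
            for s in self.corpus.section_inventory
        ]
        return d


@dataclass
class Splits:
    train: list[GeneratedNote]
    dev: list[GeneratedNote]
    test: list[GeneratedNote]
    unlabeled: list[GeneratedNote]


def split_corpus(
    notes: Sequence[GeneratedNote],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 12345,
) -> Splits:
    """Document-level random split of the labeled notes; unlabeled notes form a
    separate pool used only for pre-training text and pseudo-labeling. Test
    documents never enter any training pool."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    labeled = [n for n in notes if n.is_labeled]
    unlabeled = [n for n in notes if not n.is_labeled]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labeled))
    n_train = int(round(fractions[0] * len(labeled)))
    n_dev = int(round(fractions[1] * len(labeled)))
    train = [labeled[i] for i in order[:n_train]]
    dev = [labeled[i] for i in order[n_train : n_train + n_dev]]
    test = [labeled[i] for i in order[n_train + n_dev :]]
    return Splits(train=train, dev=dev, test=test, unlabeled=unlabeled)


def notes_to_sentences(notes: Sequence[GeneratedNote]) -> list[TaggedSentence]:
    out: list[TaggedSentence] = []
    for gn in notes:
        out.extend(note_to_sentences(gn.note, gn.gold_spans if gn.is_labeled else ()))
    return out


def _section_titles(config: RunConfig) -> list[str]:
    return [s.title for s in config.corpus.section_inventory]


def run_variant(
    name: str,
    splits: Splits,
    config: RunConfig,
    seed: int,
    multitask: bool = False,
) -> dict:
    """Run one variant end to end for one seed; returns a Table-2-style row
    fragment (strict P/R/F1 and entity-type F1 on the test split)."""
    spec = variant_spec(name)
    scheme = LabelScheme()
    train_sents = notes_to_sentences(splits.train)
    dev_sents = notes_to_sentences(splits.dev)
    unlabeled_text_sents = notes_to_sentences(splits.unlabeled)

    vocab = Vocab.build(list(train_sents) + unlabeled_text_sents, scheme)
    enc_cfg = EncoderConfig(
        vocab_size=len(vocab),
        hidden_dim=config.hidden_dim,
        n_layers=config.n_layers,
        n_heads=config.n_heads,
        max_len=config.max_len,
        dropout_rate=config.dropout_rate,
        seed=seed,
    )

    sections = _section_titles(config)
    if spec.pretrain_variant is not None:
        # MLM can exploit unlabeled text; entity masking needs tagged sentences.
        if spec.pretrain_variant == "mlm":
            pretrain_sents = list(train_sents) + unlabeled_text_sents
        else:
            pretrain_sents = list(train_sents)
        ckpt = run_pretraining(
            pretrain_sents,
            variant=spec.pretrain_variant,
            encoder_config=enc_cfg,
            masking=config.masking,
            contrastive=config.contrastive,
            scheme=scheme,
            vocab=vocab,
            seed=seed,
        )
        model = NERModel.from_checkpoint(
            ckpt, fusion_mode=spec.fusion_mode, section_titles=sections,
            multitask=multitask, seed=seed,
        )
    else:
        model = NERModel(
            encoder_config=enc_cfg, vocab=vocab, scheme=scheme,
            fusion_mode=spec.fusion_mode, section_titles=sections,
            multitask=multitask, seed=seed,
        )

    ft = FinetuneConfig(
        lr=config.finetune.lr,
        batch_size=config.finetune.batch_size,
        epochs=config.finetune.epochs,
        alpha=config.finetune.alpha,
        epsilon=config.finetune.epsilon,
        patience=config.finetune.patience,
        seed=seed,
        upsample_ratio=config.finetune.upsample_ratio,
    )
    gold_train = upsample(train_sents, scheme, ratio=ft.upsample_ratio)
    _, log = train(model, gold_train, dev_sents, ft, use_rdrop=spec.rdrop)

    if spec.pseudo_labels and splits.unlabeled:
        silver = pseudo_label(
            model, [gn.note for gn in splits.unlabeled], provenance=f"{name}/seed{seed}"
        )
        combined = gold_train + silver.sentences
        _, log2 = train(model, combined, dev_sents, ft, use_rdrop=spec.rdrop)
        log = log + [{**rec, "phase": "silver"} for rec in log2]

    # test evaluation
    gold_spans, pred_spans = [], []
    test_sents = notes_to_sentences(splits.test)
    tags_list, _ = model.predict(test_sents)
    for sent, ptags in zip(test_sents, tags_list):
        gold_spans.append(bio_to_spans(sent.tokens, sent.tags, scheme))
        pred_spans.append(bio_to_spans(sent.tokens, ptags, scheme))
    report = evaluate(gold_spans, pred_spans, collect_errors=False)
    return {
        "variant": name,
        "seed": seed,
        "strict_precision": report.strict.precision,
        "strict_recall": report.strict.recall,
        "strict_f1": report.strict.f1,
        "type_f1": report.entity_type.f1,
        "best_dev_strict_f1": max(rec["dev_strict_f1"] for rec in log),
        "epochs_ran": len(log),
    }


def run_matrix(config: RunConfig, multitask: bool = False) -> list[dict]:
    """Run every configured variant over every seed on shared splits.

    Returns one row per variant with per-seed metrics plus mean and sd,
    mirroring a precision/recall/F1 results table.
    """
    notes = generate_corpus(config.corpus)
    splits = split_corpus(notes, config.split_fractions, config.split_seed)
    rows: list[dict] = []
    for name in config.variants:
        per_seed = [
            run_variant(name, splits, config, seed, multitask=multitask)
            for seed in config.seeds
        ]
        row: dict = {"variant": name, "runs": per_seed}
        for metric in ("strict_precision", "strict_recall", "strict_f1", "type_f1"):
            vals = np.array([r[metric] for r in per_seed])
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{metric}_median"] = float(np.median(vals))
        rows.append(row)
    return rows


def save_results(rows: list[dict], config: RunConfig, out_dir: str | Path) -> Path:
    """Write results as JSON + CSV together with the fully serialized config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    (out_dir / "results.json").write_text(json.dumps(rows, indent=2))
    csv_lines = ["variant,strict_P,strict_R,strict_F1,type_F1,strict_F1_sd"]
    for row in rows:
        csv_lines.append(
            f"{row['variant']},{row['strict_precision_mean']:.4f},"
            f"{row['strict_recall_mean']:.4f},{row['strict_f1_mean']:.4f},"
            f"{row['type_f1_mean']:.4f},{row['strict_f1_sd']:.4f}"
        )
    (out_dir / "results.csv").write_text("\n".join(csv_lines) + "\n")
    return out_dir / "results.json"
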