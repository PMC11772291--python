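"""Span-level NER evaluation and the five-category error taxonomy.

Two matching regimes:

* strict — a predicted span counts only as an exact (start, end, label) match;
* entity-type — the label must match and the surfaces must overlap by at least
  one character, so boundary disagreements (the chief source of annotation
  variability between doctors) still count. Matching is greedy by overlap
  size, ties broken leftmost; each gold and each prediction is used at most
  once.

Headline numbers are micro-averaged. A token-level tagging accuracy is exposed
as a secondary diagnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ContractError
from .formats import EntitySpan, tokenize

DEFAULT_CONJUNCTIONS = ("en", "of")

ERROR_CATEGORIES = (
    "missing_information",
    "extra_information",
    "conjunction_merge",
    "missing_gold_annotation",
    "different_entity_type",
    "uncategorized",
)


@dataclass
class Metrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def add(self, other: "Metrics") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn


@dataclass
class ErrorCase:
    category: str
    gold: list[EntitySpan]
    pred: list[EntitySpan]


@dataclass
class EvalReport:
    strict: Metrics
    entity_type: Metrics
    strict_per_class: dict[str, Metrics]
    type_per_class: dict[str, Metrics]
    n_gold: int
    n_pred: int
    errors: list[ErrorCase] = field(default_factory=list)

    def to_dict(self) -> dict:
        def block(m: Metrics) -> dict:
            return {"precision": m.precision, "recall": m.recall, "f1": m.f1,
                    "tp": m.tp, "fp": m.fp, "fn": m.fn}

        return {
            "strict": block(self.strict),
            "entity_type": block(self.entity_type),
            "strict_per_class": {k: block(v) for k, v in self.strict_per_class.items()},
            "type_per_class": {k: block(v) for k, v in self.type_per_class.items()},
            "n_gold": self.n_gold,
            "n_pred": self.n_pred,
            "error_counts": dict(Counter(e.category for e in self.errors)),
        }

    def table(self) -> str:
        rows = [f"{'class':<22}{'strict P':>9}{'R':>7}{'F1':>7}{'type F1':>9}"]
        for cls in sorted(set(self.strict_per_class) | set(self.type_per_class)):
            s = self.strict_per_class.get(cls, Metrics())
            t = self.type_per_class.get(cls, Metrics())
            rows.append(
                f"{cls:<22}{s.precision:>9.3f}{s.recall:>7.3f}{s.f1:>7.3f}{t.f1:>9.3f}"
            )
        rows.append(
            f"{'micro':<22}{self.strict.precision:>9.3f}{self.strict.recall:>7.3f}"
            f"{self.strict.f1:>7.3f}{self.entity_type.f1:>9.3f}"
        )
        return "\n".join(rows)


def _strict_counts(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]) -> Metrics:
    g = Counter((s.start, s.end, s.label) for s in gold)
    p = Counter((s.start, s.end, s.label) for s in pred)
    tp = sum((g & p).values())
    return Metrics(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def match_by_type(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
) -> list[tuple[int, int]]:
    """Entity-type matching: candidate (gold, pred) pairs need an equal label
    and an overlap of >= 1 character; each gold and each prediction is matched
    at most once. Pairs are preferred in order of decreasing overlap, ties
    broken by leftmost gold then leftmost pred, and augmenting paths ensure the
    matching has maximum cardinality (a greedy pass alone can strand a
    matchable pair when spans interleave)."""
    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if g.label == p.label and g.overlap(p) > 0:
                candidates.append((-g.overlap(p), g.start, p.start, gi, pi))
    candidates.sort()
    adj: dict[int, list[int]] = {}
    for _, _, _, gi, pi in candidates:
        adj.setdefault(gi, []).append(pi)
    match_of_pred: dict[int, int] = {}

    def try_assign(gi: int, banned: set[int]) -> bool:
        for pi in adj.get(gi, ()):
            if pi in banned:
                continue
            banned.add(pi)
            if pi not in match_of_pred or try_assign(match_of_pred[pi], banned):
                match_of_pred[pi] = gi
                return True
        return False

    for _, _, _, gi, _ in candidates:  # seed in greedy preference order
        if gi not in {g for g in match_of_pred.values()}:
            try_assign(gi, set())
    return sorted((gi, pi) for pi, gi in match_of_pred.items())


def _type_counts(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]) -> Metrics:
    tp = len(match_by_type(gold, pred))
    return Metrics(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def evaluate(
    gold: Sequence[Sequence[EntitySpan]],
    pred: Sequence[Sequence[EntitySpan]],
    conjunctions: Sequence[str] = DEFAULT_CONJUNCTIONS,
    collect_errors: bool = True,
) -> EvalReport:
    """Evaluate predictions against gold annotations, paired per document.

    ``gold[i]`` and ``pred[i]`` must come from the same document — offsets are
    only comparable within a document, so the pairing is the contract.
    """
    if len(gold) != len(pred):
        raise ContractError(
            f"gold has {len(gold)} documents but pred has {len(pred)}; "
            "spans from different documents must not be mixed"
        )
    strict, etype = Metrics(), Metrics()
    strict_cls: dict[str, Metrics] = {}
    type_cls: dict[str, Metrics] = {}
    errors: list[ErrorCase] = []
    n_gold = n_pred = 0
    for g_doc, p_doc in zip(gold, pred):
        n_gold += len(g_doc)
        n_pred += len(p_doc)
        strict.add(_strict_counts(g_doc, p_doc))
        etype.add(_type_counts(g_doc, p_doc))
        labels = {s.label for s in g_doc} | {s.label for s in p_doc}
        for lab in labels:
            gl = [s for s in g_doc if s.label == lab]
            pl = [s for s in p_doc if s.label == lab]
            strict_cls.setdefault(lab, Metrics()).add(_strict_counts(gl, pl))
            type_cls.setdefault(lab, Metrics()).add(_type_counts(gl, pl))
        if collect_errors:
            errors.extend(classify_errors(g_doc, p_doc, conjunctions))
    return EvalReport(
        strict=strict,
        entity_type=etype,
        strict_per_class=strict_cls,
        type_per_class=type_cls,
        n_gold=n_gold,
        n_pred=n_pred,
        errors=errors,
    )


def token_accuracy(gold_tags: Sequence[Sequence[str]], pred_tags: Sequence[Sequence[str]]) -> float:
    """Secondary diagnostic: fraction of tokens with the exact BIO tag."""
    total = correct = 0
    for g, p in zip(gold_tags, pred_tags):
        if len(g) != len(p):
            raise ContractError("tag sequences of unequal length")
        total += len(g)
        correct += sum(a == b for a, b in zip(g, p))
    return correct / total if total else 0.0


def _strictly_inside(inner: EntitySpan, outer: EntitySpan) -> bool:
    return (
        inner.start >= outer.start
        and inner.end <= outer.end
        and (inner.start > outer.start or inner.end < outer.end)
    )


def classify_errors(
    gold: Sequence[EntitySpan],
    pred: Sequence[EntitySpan],
    conjunctions: Sequence[str] = DEFAULT_CONJUNCTIONS,
) -> list[ErrorCase]:
    """Deterministic assignment of non-exact predictions to the error taxonomy.

    Categories, in precedence order per prediction:

    * conjunction_merge — one prediction covers >= 2 same-type gold spans whose
      gap contains a conjunction token ("terminaal ileum en colitis tot 40 cm");
    * extra_information — a same-type gold lies strictly inside the prediction;
    * missing_information — the prediction lies strictly inside a same-type gold;
    * different_entity_type — overlap exists but only with other types;
    * missing_gold_annotation — the prediction overlaps no gold at all.

    Gold spans no prediction touches are reported as uncategorized misses.
    """
    conj = {c.lower() for c in conjunctions}
    exact = {(s.start, s.end, s.label) for s in gold}
    errors: list[ErrorCase] = []
    touched_gold: set[int] = set()
    for p in pred:
        overlapping = [(gi, g) for gi, g in enumerate(gold) if g.overlap(p) > 0]
        touched_gold.update(gi for gi, _ in overlapping)
        if (p.start, p.end, p.label) in exact:
            continue
        same_type = [g for _, g in overlapping if g.label == p.label]
        contained = sorted(
            (g for g in same_type if _strictly_inside(g, p)), key=lambda s: s.start
        )
        if len(contained) >= 2 and _gaps_have_conjunction(p, contained, conj):
            errors.append(ErrorCase("conjunction_merge", contained, [p]))
        elif any(_strictly_inside(g, p) for g in same_type):
            inner = [g for g in same_type if _strictly_inside(g, p)]
            errors.append(ErrorCase("extra_information", inner, [p]))
        elif any(_strictly_inside(p, g) for g in same_type):
            outer = [g for g in same_type if _strictly_inside(p, g)]
            errors.append(ErrorCase("missing_information", outer, [p]))
        elif overlapping and not same_type:
            errors.append(ErrorCase("different_entity_type", [overlapping[0][1]], [p]))
        elif not overlapping:
            errors.append(ErrorCase("missing_gold_annotation", [], [p]))
        else:
            errors.append(ErrorCase("uncategorized", [g for _, g in overlapping], [p]))
    for gi, g in enumerate(gold):
        if gi not in touched_gold:
            errors.append(ErrorCase("uncategorized", [g], []))
    return errors


def _gaps_have_conjunction(
    pred: EntitySpan, contained: Sequence[EntitySpan], conj: set[str]
) -> bool:
    for a, b in zip(contained, contained[1:]):
        gap = pred.surface[a.end - pred.start : b.start - pred.start]
        if any(t.surface.lower() in conj for t in tokenize(gap)):
            return True
    return False
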