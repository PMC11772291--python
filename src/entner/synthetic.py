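"""Reproducible synthetic clinical-note corpora in BRAT format.

The generator emulates the statistical structure of Dutch IBD consultation
notes: nine entity types with heavy class imbalance (peri-anal disease the
rarest), section-dependent entity validity (a diagnosis surface form under a
family-history section is *not* an entity), abbreviation ambiguity (CD/UC
reused as lab measurements), multi-token spans occasionally joined by a
conjunction, and Montreal-classification vocabulary (L1-L3, B1-B3, E1-E3).

Text is template-based pseudo-Dutch: a section header line followed by
slot-filled sentences. Realism is not the goal — exact offsets, a controlled
label distribution, and byte-level determinism are.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, EntnerError
from .formats import (
    DEFAULT_ENTITY_TYPES,
    ClinicalNote,
    EntitySpan,
    detect_sections,
    tokenize,
    write_brat,
)

# Conjunctions used to join same-type entities in one sentence; exported for
# the error-taxonomy classifier.
CONJUNCTIONS: tuple[str, ...] = ("en", "of")

# Entity surface lexicon. Montreal codes plus free-text variants.
SURFACES: dict[str, tuple[str, ...]] = {
    "diagnosis": ("ziekte van Crohn", "colitis ulcerosa", "Morbus Crohn", "CD", "UC"),
    "diagnosis_date": ("in 2014", "sinds 2009", "12/03/2015", "in 1998", "sinds 2021"),
    "disease_location": (
        "terminaal ileum", "colitis tot 40 cm", "colon descendens", "rectum",
        "caecum", "sigmoid", "L1", "L2", "L3",
    ),
    "disease_behavior": (
        "B1", "B2", "B3", "stenoserend", "fistel en fisteltraject", "niet stenotisch",
    ),
    "peri_anal_disease": ("peri-anale fistel", "perianaal abces", "peri-anale fissuur"),
    "previous_surgery": (
        "colectomie", "ileocecale resectie", "colectomie met tijdelijk ileostoma",
        "hemicolectomie rechts",
    ),
    "disease_extent": ("E1", "E2", "E3", "pancolitis", "proctitis"),
    "length": ("178 cm", "165 cm", "181 cm", "170 cm"),
    "body_weight": ("72 kg", "80 kg", "64 kg", "95 kg"),
}

# Per-section sentence templates; "{E}" is the entity slot, "{E} en {E}" the
# conjunction variant. Filler sentences carry no entity.
TEMPLATES: dict[str, tuple[str, ...]] = {
    "diagnosis": ("Patient heeft {E} .", "Diagnose : {E} .", "Gekend met {E} ."),
    "diagnosis_date": ("Diagnose gesteld {E} .", "Eerste opstoot {E} ."),
    "disease_location": ("Inflammatie in {E} .", "Letsels ter hoogte van {E} ."),
    "disease_behavior": ("Ziektegedrag : {E} .", "Beeld van {E} ."),
    "peri_anal_disease": ("Voorgeschiedenis van {E} .", "Klachten van {E} ."),
    "previous_surgery": ("Status na {E} .", "Vroegere ingreep : {E} ."),
    "disease_extent": ("Uitgebreidheid : {E} .", "Extensie {E} ."),
    "length": ("Lengte {E} .", "Gestalte {E} ."),
    "body_weight": ("Gewicht {E} .", "Weegt vandaag {E} ."),
}

FILLERS: tuple[str, ...] = (
    "Patient stelt het goed .",
    "Geen nieuwe klachten vandaag .",
    "Controle over drie maanden .",
    "Medicatie wordt verdergezet .",
    "Bloedname werd uitgevoerd .",
)

# Family-history sentences: diagnosis-like surface forms that are NOT entities.
# Half the emissions reuse the diagnosis templates verbatim, so the *sentence
# text alone* cannot decide entityhood — only the section can (the mechanism
# that makes section fusion informative).
FAMILY_SENTENCES: tuple[str, ...] = (
    "Zus en nicht van moeder : ziekte van Crohn .",
    "Broers met Morbus Crohn .",
    "Vader gekend met colitis ulcerosa .",
)

# Lab sentences reusing the CD/UC abbreviations as measurement names.
LAB_SENTENCES: tuple[str, ...] = (
    "CD 4 waarde binnen normale grenzen .",
    "UC ratio licht verhoogd .",
    "CRP 12 mg per liter .",
)


@dataclass(frozen=True)
class SectionSpec:
    """A section title plus the entity types admissible as gold spans in it."""

    title: str
    admissible: tuple[str, ...]


DEFAULT_SECTIONS: tuple[SectionSpec, ...] = (
    SectionSpec("Anamnese", ("diagnosis", "diagnosis_date", "peri_anal_disease")),
    SectionSpec("Voorgeschiedenis", ("previous_surgery", "diagnosis", "diagnosis_date")),
    SectionSpec("Endoscopie", ("disease_location", "disease_behavior", "disease_extent")),
    SectionSpec("Klinisch onderzoek", ("length", "body_weight")),
    SectionSpec("Familiaal", ()),
    SectionSpec("Labo", ()),
)

# Class imbalance: diagnosis dominates, peri-anal disease is the rarest.
DEFAULT_ENTITY_WEIGHTS: dict[str, float] = {
    "diagnosis": 30.0,
    "diagnosis_date": 15.0,
    "disease_location": 12.0,
    "body_weight": 12.0,
    "length": 10.0,
    "disease_extent": 8.0,
    "disease_behavior": 6.0,
    "previous_surgery": 6.0,
    "peri_anal_disease": 1.0,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Full description of a synthetic corpus; a fixed spec (incl. seed) yields
    a byte-identical corpus."""

    n_notes: int = 100
    seed: int = 0
    entity_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_WEIGHTS)
    )
    section_inventory: tuple[SectionSpec, ...] = DEFAULT_SECTIONS
    ambiguity_rate: float = 0.3
    conjunction_rate: float = 0.15
    unlabeled_fraction: float = 0.0
    entities_per_note: tuple[int, int] = (4, 9)  # inclusive range

    def validate(self) -> None:
        if self.n_notes <= 0:
            raise ConfigurationError("n_notes must be positive")
        if not self.section_inventory:
            raise ConfigurationError("empty section inventory")
        if not self.entity_weights:
            raise ConfigurationError("empty entity weights")
        for etype, w in self.entity_weights.items():
            if etype not in DEFAULT_ENTITY_TYPES:
                raise ConfigurationError(f"unknown entity type {etype!r}")
            if w < 0:
                raise ConfigurationError(f"negative weight for {etype!r}")
        if all(w == 0 for w in self.entity_weights.values()):
            raise ConfigurationError("all entity weights are zero")
        for rate, name in (
            (self.ambiguity_rate, "ambiguity_rate"),
            (self.conjunction_rate, "conjunction_rate"),
            (self.unlabeled_fraction, "unlabeled_fraction"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class GeneratedNote:
    note: ClinicalNote
    gold_spans: list[EntitySpan]
    is_labeled: bool = True

    def __post_init__(self) -> None:
        for sp in self.gold_spans:
            if not (0 <= sp.start < sp.end <= len(self.note.text)):
                raise EntnerError(f"span {sp} outside note text")
            if self.note.text[sp.start : sp.end] != sp.surface:
                raise EntnerError(f"span surface mismatch for {sp}")


def _admitting_sections(spec: CorpusSpec, etype: str) -> list[SectionSpec]:
    return [s for s in spec.section_inventory if etype in s.admissible]


def _render_entity_sentence(
    etype: str,
    rng: np.random.Generator,
    conjunction: bool,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Render one sentence; returns text and (start, end, type) spans local to it."""
    template = str(rng.choice(TEMPLATES[etype]))
    choices = SURFACES[etype]
    if conjunction and len(choices) >= 2:
        idx = rng.choice(len(choices), size=2, replace=False)
        a, b = choices[int(idx[0])], choices[int(idx[1])]
        conj = str(rng.choice(CONJUNCTIONS))
        filled = f"{a} {conj} {b}"
        prefix = template.split("{E}")[0]
        text = template.replace("{E}", filled)
        s0 = len(prefix)
        spans = [
            (s0, s0 + len(a), etype),
            (s0 + len(a) + len(conj) + 2, s0 + len(filled), etype),
        ]
    else:
        surface = str(rng.choice(choices))
        prefix = template.split("{E}")[0]
        text = template.replace("{E}", surface)
        spans = [(len(prefix), len(prefix) + len(surface), etype)]
    return text, spans


def generate_note(
    spec: CorpusSpec, rng: np.random.Generator, doc_id: str, is_labeled: bool
) -> GeneratedNote:
    spec.validate()
    types = [t for t in DEFAULT_ENTITY_TYPES if spec.entity_weights.get(t, 0.0) > 0]
    weights = np.array([spec.entity_weights[t] for t in types], dtype=float)
    probs = weights / weights.sum()

    n_entities = int(rng.integers(spec.entities_per_note[0], spec.entities_per_note[1] + 1))
    drawn = [types[i] for i in rng.choice(len(types), size=n_entities, p=probs)]

    # Group drawn entities under sections that admit them; each mention becomes
    # one sentence (possibly a conjunction sentence with two gold spans).
    per_section: dict[str, list[str]] = {}
    for etype in drawn:
        homes = _admitting_sections(spec, etype)
        if not homes:
            continue
        home = homes[int(rng.integers(len(homes)))]
        per_section.setdefault(home.title, []).append(etype)

    include_family = rng.random() < spec.ambiguity_rate
    include_lab = rng.random() < 0.5

    parts: list[str] = []
    spans: list[EntitySpan] = []
    pos = 0

    def emit(line: str) -> None:
        nonlocal pos
        parts.append(line)
        pos += len(line) + 1  # newline separator

    for sec in spec.section_inventory:
        sentences: list[tuple[str, list[tuple[int, int, str]]]] = []
        if sec.title == "Familiaal":
            if include_family:
                if rng.random() < 0.5:
                    # a diagnosis sentence verbatim, but with no gold span
                    text, _ = _render_entity_sentence("diagnosis", rng, False)
                    sentences.append((text, []))
                else:
                    sentences.append((str(rng.choice(FAMILY_SENTENCES)), []))
        elif sec.title == "Labo":
            if include_lab:
                sentences.append((str(rng.choice(LAB_SENTENCES)), []))
        else:
            for etype in per_section.get(sec.title, []):
                conj = rng.random() < spec.conjunction_rate
                sentences.append(_render_entity_sentence(etype, rng, conj))
            if rng.random() < 0.5:
                sentences.append((str(rng.choice(FILLERS)), []))
        if not sentences:
            continue
        emit(f"{sec.title}:")
        for text, local_spans in sentences:
            line_start = pos
            emit(text)
            for s, e, etype in local_spans:
                spans.append(
                    EntitySpan(line_start + s, line_start + e, etype, text[s:e])
                )

    full_text = "\n".join(parts) + "\n"
    note = ClinicalNote(doc_id=doc_id, text=full_text, sections=detect_sections(full_text))
    return GeneratedNote(note=note, gold_spans=spans, is_labeled=is_labeled)


def generate_corpus(spec: CorpusSpec) -> list[GeneratedNote]:
    """Generate a corpus of notes; the trailing ``unlabeled_fraction`` of notes
    is emitted without annotations (their internally generated gold spans are
    retained on the object for auditing pseudo-labels, but writers skip them).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_unlabeled = int(round(spec.unlabeled_fraction * spec.n_notes))
    notes = []
    for i in range(spec.n_notes):
        is_labeled = i < spec.n_notes - n_unlabeled
        notes.append(generate_note(spec, rng, doc_id=f"note{i:05d}", is_labeled=is_labeled))
    return notes


@dataclass
class CorpusStats:
    entity_counts: dict[str, int]
    section_entity_counts: dict[str, dict[str, int]]
    note_word_counts: list[int]

    @property
    def total_entities(self) -> int:
        return sum(self.entity_counts.values())


def corpus_stats(notes: Sequence[GeneratedNote]) -> CorpusStats:
    """Frequency report: per-entity counts, per-section x per-entity counts,
    and the note word-count histogram. Row sums conserve the totals."""
    if not notes:
        raise EntnerError("empty corpus")
    entity_counts: Counter[str] = Counter()
    section_counts: dict[str, Counter[str]] = {}
    word_counts: list[int] = []
    for gn in notes:
        word_counts.append(len(tokenize(gn.note.text)))
        for sp in gn.gold_spans:
            entity_counts[sp.label] += 1
            sec = gn.note.section_at(sp.start) or ""
            section_counts.setdefault(sec, Counter())[sp.label] += 1
    return CorpusStats(
        entity_counts=dict(entity_counts),
        section_entity_counts={k: dict(v) for k, v in section_counts.items()},
        note_word_counts=word_counts,
    )


def write_corpus(
    notes: Sequence[GeneratedNote], out_dir: str | Path
) -> Path:
    """Write BRAT pairs plus a manifest JSON listing labeled/unlabeled splits."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labeled, unlabeled = [], []
    for gn in notes:
        if gn.is_labeled:
            write_brat(gn.note, gn.gold_spans, out_dir)
            labeled.append(gn.note.doc_id)
        else:
            (out_dir / f"{gn.note.doc_id}.txt").write_text(gn.note.text, encoding="utf-8")
            unlabeled.append(gn.note.doc_id)
    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps({"labeled": labeled, "unlabeled": unlabeled}, indent=2),
        encoding="utf-8",
    )
    return manifest
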