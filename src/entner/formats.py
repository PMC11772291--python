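"""Core data types and I/O for clinical NER corpora.

Reads and writes BRAT standoff (.txt/.ann pairs) and a CoNLL-style TSV, splits
notes into sentences with section attribution, and converts between
character-offset entity spans and token-level BIO tags.

Offsets are 0-based half-open throughout, matching the BRAT convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import AnnotationError, SchemeError

logger = logging.getLogger(__name__)

# Entity inventory of the IBD domain: diagnosis (Crohn's disease / ulcerative
# colitis), date of diagnosis, the Montreal-classification axes (location L1-L3,
# behavior B1-B3, extent E1-E3), peri-anal disease history, previous surgery,
# and the two consultation measurements (height, weight).
DEFAULT_ENTITY_TYPES: tuple[str, ...] = (
    "diagnosis",
    "diagnosis_date",
    "disease_location",
    "disease_behavior",
    "peri_anal_disease",
    "previous_surgery",
    "disease_extent",
    "length",
    "body_weight",
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
# A section header is a short line ending in a colon, e.g. "Familiaal:".
_HEADER_RE = re.compile(r"^([^\s:][^:\n]{0,60}):[ \t]*$", re.MULTILINE)
_SENT_END = ".!?\n"


@dataclass(frozen=True)
class LabelScheme:
    """BIO label space derived from an ordered entity-type inventory."""

    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
    begin_token: str = "[CLS]"
    end_token: str = "[SEP]"
    pad_token: str = "[PAD]"

    @property
    def bio_labels(self) -> tuple[str, ...]:
        labels = ["O"]
        for t in self.entity_types:
            labels.append(f"B-{t}")
            labels.append(f"I-{t}")
        return tuple(labels)

    @property
    def label_token_names(self) -> tuple[str, ...]:
        """Reserved vocabulary block for inserted label tokens, e.g. ``<B-diagnosis>``."""
        return tuple(f"<{lab}>" for lab in self.bio_labels if lab != "O")

    def label_index(self, tag: str) -> int:
        try:
            return self.bio_labels.index(tag)
        except ValueError:
            raise SchemeError(f"tag {tag!r} not in scheme {self.bio_labels}") from None

    def validate_tag(self, tag: str) -> None:
        if tag not in self.bio_labels:
            raise SchemeError(f"tag {tag!r} not in scheme")

    def validate_type(self, entity_type: str) -> None:
        if entity_type not in self.entity_types:
            raise SchemeError(f"entity type {entity_type!r} not in scheme")


@dataclass(frozen=True)
class EntitySpan:
    """A typed character-offset span; ``surface`` must equal ``text[start:end]``."""

    start: int
    end: int
    label: str
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"invalid span offsets ({self.start}, {self.end})")

    def overlap(self, other: "EntitySpan") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise AnnotationError("empty token surface")
        if self.end - self.start != len(self.surface):
            raise AnnotationError(f"token range ({self.start},{self.end}) != len({self.surface!r})")


@dataclass(frozen=True)
class ClinicalNote:
    """Document text plus an ordered, disjoint section segmentation."""

    doc_id: str
    text: str
    sections: tuple[tuple[str, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for title, (s, e) in self.sections:
            if not (0 <= s <= e <= len(self.text)):
                raise AnnotationError(f"section {title!r} range ({s},{e}) outside text")
            if s < prev_end:
                raise AnnotationError(f"section {title!r} overlaps the previous section")
            prev_end = e

    def section_at(self, pos: int) -> Optional[str]:
        for title, (s, e) in self.sections:
            if s <= pos < e:
                return title
        return None


@dataclass
class TaggedSentence:
    """Tokens with parallel BIO tags, the enclosing section title, and an
    optional sentence-level binary flag (e.g. a peri-anal-disease mention)."""

    tokens: list[Token]
    tags: list[str]
    section: Optional[str] = None
    sentence_flag: Optional[int] = None
    doc_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise AnnotationError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Whitespace + punctuation tokenizer that preserves exact character offsets."""
    return [
        Token(m.group(), offset + m.start(), offset + m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def detect_sections(text: str) -> tuple[tuple[str, tuple[int, int]], ...]:
    """Segment a note by header lines of the form ``Title:``.

    Each section runs from its header to the next header (or end of text);
    text before the first header belongs to an untitled leading section.
    """
    headers = [(m.group(1), m.start()) for m in _HEADER_RE.finditer(text)]
    sections: list[tuple[str, tuple[int, int]]] = []
    if headers and headers[0][1] > 0:
        sections.append(("", (0, headers[0][1])))
    for i, (title, start) in enumerate(headers):
        end = headers[i + 1][1] if i + 1 < len(headers) else len(text)
        sections.append((title, (start, end)))
    if not headers:
        sections.append(("", (0, len(text))))
    return tuple(sections)


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------

def read_brat(
    txt_path: str | Path,
    ann_path: str | Path,
    scheme: LabelScheme = LabelScheme(),
) -> tuple[ClinicalNote, list[EntitySpan]]:
    """Read a BRAT ``.txt``/``.ann`` pair, validating spans against the text."""
    txt_path, ann_path = Path(txt_path), Path(ann_path)
    text = txt_path.read_text(encoding="utf-8")
    note = ClinicalNote(doc_id=txt_path.stem, text=text, sections=detect_sections(text))
    spans: list[EntitySpan] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith("T"):  # attribute/event/relation lines are out of scope
            continue
        try:
            _tid, meta, surface = line.split("\t", 2)
            label, start_s, end_s = meta.split(" ")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"{ann_path.name}:{lineno}: malformed line {line!r}") from exc
        scheme.validate_type(label)
        if not (0 <= start < end <= len(text)):
            raise AnnotationError(
                f"{ann_path.name}:{lineno}: offsets ({start},{end}) out of bounds"
            )
        if text[start:end] != surface:
            raise AnnotationError(
                f"{ann_path.name}:{lineno}: surface {surface!r} != text slice "
                f"{text[start:end]!r}"
            )
        spans.append(EntitySpan(start, end, label, surface))
    return note, spans


def write_brat(
    note: ClinicalNote,
    spans: Sequence[EntitySpan],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write a note and its spans as a BRAT pair; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt_path = out_dir / f"{note.doc_id}.txt"
    ann_path = out_dir / f"{note.doc_id}.ann"
    txt_path.write_text(note.text, encoding="utf-8")
    lines = [
        f"T{k}\t{sp.label} {sp.start} {sp.end}\t{sp.surface}"
        for k, sp in enumerate(spans, 1)
    ]
    ann_path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return txt_path, ann_path


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

def split_sentences(note: ClinicalNote) -> list[tuple[tuple[int, int], Optional[str]]]:
    """Split a note into sentence char ranges, each tagged with its section title.

    Sentences end at ``.``, ``!``, ``?`` or a newline; the returned ranges cover
    every non-whitespace character exactly once and never cross a section
    boundary, so each sentence inherits a single section title.
    """
    text = note.text
    boundaries = sorted({e for _, (_, e) in note.sections} | {len(text)})
    out: list[tuple[tuple[int, int], Optional[str]]] = []
    pos = 0
    for stop in boundaries:
        while pos < stop:
            while pos < stop and text[pos].isspace():
                pos += 1
            if pos >= stop:
                break
            start = pos
            while pos < stop and text[pos] not in _SENT_END:
                pos += 1
            if pos < stop and text[pos] in ".!?":
                pos += 1  # keep the terminator inside the sentence
            end = pos
            while end > start and text[end - 1].isspace():
                end -= 1
            if end > start:
                out.append(((start, end), note.section_at(start) or None))
        pos = stop
    return out


def note_to_sentences(
    note: ClinicalNote,
    spans: Sequence[EntitySpan] = (),
    flag_type: Optional[str] = "peri_anal_disease",
) -> list[TaggedSentence]:
    """Tokenize a note sentence-by-sentence and project gold spans to BIO tags.

    ``flag_type`` sets the sentence-level binary flag used by the multi-task
    head (1 if the sentence contains an entity of that type).
    """
    sentences = []
    for (s, e), section in split_sentences(note):
        tokens = tokenize(note.text[s:e], offset=s)
        local = [sp for sp in spans if sp.start >= s and sp.end <= e]
        tags = spans_to_bio(tokens, local)
        flag = None
        if flag_type is not None:
            flag = int(any(sp.label == flag_type for sp in local))
        sentences.append(
            TaggedSentence(tokens=tokens, tags=tags, section=section,
                           sentence_flag=flag, doc_id=note.doc_id)
        )
    return sentences


# ---------------------------------------------------------------------------
# Span <-> BIO conversion
# ---------------------------------------------------------------------------

def spans_to_bio(tokens: Sequence[Token], spans: Sequence[EntitySpan]) -> list[str]:
    """Project character spans onto tokens: first overlapping token gets B-,
    subsequent overlapping tokens I-, everything else O.

    Overlapping gold spans are rejected — the annotation model is flat.
    """
    ordered = sorted(spans, key=lambda sp: (sp.start, sp.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.overlap(b) > 0:
            raise AnnotationError(f"overlapping gold spans {a} / {b}")
    tags = ["O"] * len(tokens)
    for sp in ordered:
        first = True
        for i, tok in enumerate(tokens):
            if max(tok.start, sp.start) < min(tok.end, sp.end):
                tags[i] = ("B-" if first else "I-") + sp.label
                first = False
    return tags


def repair_bio(tags: Sequence[str], scheme: LabelScheme = LabelScheme()) -> tuple[list[str], int]:
    """Repair an invalid BIO sequence: I- with no matching open entity becomes B-.

    Returns the repaired tags and the number of repairs. Model output (e.g.
    pseudo-labels) can be invalid and must stay consumable, so repair is
    preferred over rejection.
    """
    repaired: list[str] = []
    n_fixed = 0
    prev_type: Optional[str] = None
    for tag in tags:
        scheme.validate_tag(tag)
        if tag.startswith("I-") and prev_type != tag[2:]:
            repaired.append("B-" + tag[2:])
            n_fixed += 1
            prev_type = tag[2:]
        else:
            repaired.append(tag)
            prev_type = tag[2:] if tag != "O" else None
    if n_fixed:
        logger.warning("repaired %d invalid I- tags", n_fixed)
    return repaired, n_fixed


def bio_to_spans(
    tokens: Sequence[Token],
    tags: Sequence[str],
    scheme: LabelScheme = LabelScheme(),
    text: Optional[str] = None,
) -> list[EntitySpan]:
    """Inverse of :func:`spans_to_bio` at token-boundary granularity.

    Stray I- tags are repaired to B- first (with a logged warning). When the
    note ``text`` is given, surfaces are exact slices; otherwise they are
    reconstructed by joining token surfaces with single spaces.
    """
    if len(tokens) != len(tags):
        raise AnnotationError("tokens/tags length mismatch")
    fixed, _ = repair_bio(tags, scheme)
    spans: list[EntitySpan] = []
    i = 0
    while i < len(fixed):
        tag = fixed[i]
        if tag.startswith("B-"):
            etype = tag[2:]
            j = i + 1
            while j < len(fixed) and fixed[j] == f"I-{etype}":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            if text is not None:
                surface = text[start:end]
            else:
                surface = " ".join(t.surface for t in tokens[i:j])
            spans.append(EntitySpan(start, end, etype, surface))
            i = j
        else:
            i += 1
    return spans


# ---------------------------------------------------------------------------
# CoNLL-style TSV
# ---------------------------------------------------------------------------

_NONE = "-"


def write_conll(
    sentences: Iterable[TaggedSentence],
    path: str | Path,
    header_comment: Optional[str] = None,
) -> Path:
    """Write sentences as TSV rows ``token<TAB>start<TAB>end<TAB>section<TAB>flag<TAB>tag``
    with a blank line between sentences. Lossless for tokens (incl. offsets),
    tags, section, and the sentence flag."""
    path = Path(path)
    lines: list[str] = []
    if header_comment:
        lines.append(f"# {header_comment}")
    for sent in sentences:
        sec = sent.section if sent.section else _NONE
        flag = _NONE if sent.sentence_flag is None else str(sent.sentence_flag)
        if "\t" in sec:
            raise AnnotationError(f"tab inside section title {sec!r}")
        for tok, tag in zip(sent.tokens, sent.tags):
            if "\t" in tok.surface:
                raise AnnotationError(f"tab inside token {tok.surface!r}")
            lines.append(f"{tok.surface}\t{tok.start}\t{tok.end}\t{sec}\t{flag}\t{tag}")
        lines.append("")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_conll(path: str | Path, scheme: LabelScheme = LabelScheme()) -> list[TaggedSentence]:
    """Read the TSV written by :func:`write_conll`."""
    path = Path(path)
    sentences: list[TaggedSentence] = []
    tokens: list[Token] = []
    tags: list[str] = []
    section: Optional[str] = None
    flag: Optional[int] = None

    def flush() -> None:
        nonlocal tokens, tags, section, flag
        if tokens:
            sentences.append(TaggedSentence(tokens, tags, section, flag))
        tokens, tags, section, flag = [], [], None, None

    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if line.startswith("#"):
            continue
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise AnnotationError(f"{path.name}:{lineno}: expected 6 columns, got {len(parts)}")
        surface, start_s, end_s, sec, flag_s, tag = parts
        scheme.validate_tag(tag)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"{path.name}:{lineno}: bad offsets") from exc
        tokens.append(Token(surface, start, end))
        tags.append(tag)
        section = None if sec == _NONE else sec
        flag = None if flag_s == _NONE else int(flag_s)
    flush()
    return sentences
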