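"""Entity semantic levels and entity-marked sentence construction.

Biomedical relation-classification inputs are sentences in which the two
entity mentions are wrapped in marker tokens, optionally prefixed by a
semantic label drawn from a UMLS-style semantic-type table.  Each concept
(CUI) maps to a fine semantic type (127 types in the UMLS metathesaurus)
and a coarse semantic group (15 groups), each available as a full name or a
short code — four "entity levels", plus a fifth level with no entity
information at all.

The marker convention follows R-BERT: the head mention is wrapped in
``$ ... $`` and the tail mention in ``# ... #``; when an entity level is
active the resolved label is inserted after the opening marker as
``LABEL : mention``.  The transformation is reversible: stripping markers
and labels recovers the original sentence byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import IntegrityError, ParseError, SpanError

__all__ = [
    "EntityLevel",
    "SemanticTypeRecord",
    "EntityMention",
    "AnnotatedSentence",
    "load_semantic_table",
    "write_semantic_table",
    "resolve_entity_level",
    "annotate_sentence",
    "strip_markers",
    "write_annotated_jsonl",
]

SEMANTIC_TABLE_COLUMNS = ("cui", "type_name", "type_code", "group_name", "group_abbr")

#: Fallback label used for CUIs absent from the semantic table.
DEFAULT_FALLBACK_LABEL = "UNK"

HEAD_MARKER = "$"
TAIL_MARKER = "#"
LABEL_SEPARATOR = " : "


class EntityLevel(Enum):
    """The five entity-information levels for model input construction."""

    TYPE_NAME = "type_name"
    TYPE_CODE = "type_code"
    GROUP_NAME = "group_name"
    GROUP_ABBR = "group_abbr"
    NONE = "none"


@dataclass(frozen=True)
class SemanticTypeRecord:
    """One CUI-keyed row of the semantic-type table."""

    cui: str
    type_name: str
    type_code: str
    group_name: str
    group_abbr: str

    def __post_init__(self) -> None:
        for field in SEMANTIC_TABLE_COLUMNS:
            if not getattr(self, field):
                raise IntegrityError(f"SemanticTypeRecord field {field!r} is empty")


@dataclass(frozen=True)
class EntityMention:
    """A head or tail entity occurrence inside a sentence.

    Spans are 0-based, half-open character offsets (PubTator convention).
    """

    entity_id: str
    surface: str
    start: int
    end: int
    role: str  # "head" | "tail"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SpanError(f"invalid span [{self.start}, {self.end}) for {self.entity_id}")
        if self.role not in ("head", "tail"):
            raise SpanError(f"role must be 'head' or 'tail', got {self.role!r}")


@dataclass(frozen=True)
class AnnotatedSentence:
    """A marked model-input sentence together with the labels inserted."""

    text: str
    level: EntityLevel
    head_label: str
    tail_label: str


def load_semantic_table(path: str | Path) -> dict[str, SemanticTypeRecord]:
    """Read a 5-column TSV into a CUI-keyed mapping.

    The file must carry a header row matching :data:`SEMANTIC_TABLE_COLUMNS`.
    Duplicate CUIs raise :class:`IntegrityError` naming both line numbers;
    malformed rows raise :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    table: dict[str, SemanticTypeRecord] = {}
    first_line: dict[str, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row") from None
        if tuple(header) != SEMANTIC_TABLE_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {list(SEMANTIC_TABLE_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns, got {len(row)}")
            cui = row[0]
            if cui in table:
                raise IntegrityError(
                    f"{path}: duplicate CUI {cui!r} on lines {first_line[cui]} and {lineno}"
                )
            try:
                record = SemanticTypeRecord(*row)
            except IntegrityError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            table[cui] = record
            first_line[cui] = lineno
    return table


def write_semantic_table(records: Iterable[SemanticTypeRecord], path: str | Path) -> None:
    """Write records as the 5-column TSV dialect read by :func:`load_semantic_table`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SEMANTIC_TABLE_COLUMNS)
        for rec in records:
            writer.writerow([rec.cui, rec.type_name, rec.type_code, rec.group_name, rec.group_abbr])


def resolve_entity_level(
    cui: str,
    level: EntityLevel,
    table: Mapping[str, SemanticTypeRecord],
    fallback: str = DEFAULT_FALLBACK_LABEL,
) -> str:
    """Return the semantic label for ``cui`` at the requested entity level.

    ``EntityLevel.NONE`` always returns the empty string; a CUI absent from
    the table returns ``fallback`` (large corpora always contain unmapped
    entities, so a miss is not an error).
    """
    if level is EntityLevel.NONE:
        return ""
    record = table.get(cui)
    if record is None:
        return fallback
    return getattr(record, level.value)


def _wrap(marker: str, label: str, surface: str) -> str:
    inner = f"{label}{LABEL_SEPARATOR}{surface}" if label else surface
    return f"{marker} {inner} {marker}"


def annotate_sentence(
    sentence: str,
    head: EntityMention,
    tail: EntityMention,
    level: EntityLevel,
    table: Mapping[str, SemanticTypeRecord],
    fallback: str = DEFAULT_FALLBACK_LABEL,
) -> AnnotatedSentence:
    """Wrap head/tail mentions in marker tokens with optional semantic labels.

    Insertions are applied right-to-left so that character offsets stay
    valid; all non-entity text is preserved verbatim.
    """
    n = len(sentence)
    for mention in (head, tail):
        if mention.end > n:
            raise SpanError(f"span [{mention.start}, {mention.end}) exceeds sentence length {n}")
    if head.start < tail.end and tail.start < head.end:
        raise SpanError(
            f"head span [{head.start}, {head.end}) overlaps tail span [{tail.start}, {tail.end})"
        )

    head_label = resolve_entity_level(head.entity_id, level, table, fallback)
    tail_label = resolve_entity_level(tail.entity_id, level, table, fallback)

    pieces = [
        (head.start, head.end, HEAD_MARKER, head_label),
        (tail.start, tail.end, TAIL_MARKER, tail_label),
    ]
    text = sentence
    for start, end, marker, label in sorted(pieces, key=lambda p: p[0], reverse=True):
        text = text[:start] + _wrap(marker, label, text[start:end]) + text[end:]
    return AnnotatedSentence(text=text, level=level, head_label=head_label, tail_label=tail_label)


def strip_markers(annotated: AnnotatedSentence) -> str:
    """Invert :func:`annotate_sentence`, recovering the original sentence."""
    text = annotated.text
    for marker, label in ((HEAD_MARKER, annotated.head_label), (TAIL_MARKER, annotated.tail_label)):
        prefix = re.escape(marker) + " "
        if label:
            prefix += re.escape(label) + re.escape(LABEL_SEPARATOR)
        pattern = prefix + r"(.*?) " + re.escape(marker)
        text, n_subs = re.subn(pattern, r"\1", text, count=1, flags=re.DOTALL)
        if n_subs != 1:
            raise ParseError(f"no {marker!r} marker pair found in {annotated.text!r}")
    return text


def write_annotated_jsonl(
    annotated: Iterable[AnnotatedSentence],
    path: str | Path,
    provenance: str | None = None,
) -> None:
    """Emit annotated sentences as JSON lines (text, level, labels, provenance)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for ann in annotated:
            row = {
                "text": ann.text,
                "level": ann.level.value,
                "head_label": ann.head_label,
                "tail_label": ann.tail_label,
                "provenance": provenance,
            }
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")
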