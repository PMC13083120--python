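"""Standoff annotation I/O for medication-incident narratives.

Annotations live in a ``.ann`` file separate from the narrative ``.txt`` and
reference it by character offset (the BRAT dialect): ``T`` lines are
text-bound mentions (entities and event triggers), ``E`` lines events,
``R`` lines binary relations, ``A`` lines event attributes and ``#`` lines
free-form notes.

Coordinate convention
---------------------
Offsets are 0-based, half-open character (Unicode code point) positions into
the ``.txt`` content, *not* bytes.  Discontinuous spans are written as
semicolon-separated fragment pairs (``0 4;10 14``) and the stored surface is
the fragment texts joined by a single space.

Because the scheme's canonical labels contain spaces ('Drug name') while the
on-disk dialect forbids them, the writer maps ``' ' -> '_'`` in labels and
the reader maps ``'_' -> ' '`` back; this is bijective for every label of
the bundled scheme (none contains an underscore).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, MriraError, OffsetError, StandoffParseError

__all__ = [
    "TextSpan",
    "EntityMention",
    "EventMention",
    "RelationMention",
    "AttributeMention",
    "AnnotatedDocument",
    "parse_document",
    "serialize_document",
    "read_corpus",
    "write_corpus",
]


# --------------------------------------------------------------------------
# label <-> disk token mapping

def label_to_token(label: str) -> str:
    return label.replace(" ", "_")


def token_to_label(token: str) -> str:
    return token.replace("_", " ")


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class TextSpan:
    """An ordered, non-overlapping sequence of (start, end) character fragments."""

    fragments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise OffsetError("a span needs at least one fragment")
        prev_end = -1
        for start, end in self.fragments:
            if start >= end:
                raise OffsetError(f"fragment ({start}, {end}) must have start < end")
            if start < prev_end:
                raise OffsetError(
                    f"fragments must be sorted and non-overlapping, got {self.fragments}"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def check_within(self, text_length: int) -> None:
        if self.end > text_length or self.start < 0:
            raise OffsetError(
                f"span {self.fragments} outside document of length {text_length}"
            )

    def extract(self, text: str) -> str:
        """Surface form: fragment texts joined by a single space."""
        return " ".join(text[s:e] for s, e in self.fragments)

    def overlap(self, other: "TextSpan") -> int:
        """Character overlap, any fragment of self vs any fragment of other."""
        total = 0
        for s1, e1 in self.fragments:
            for s2, e2 in other.fragments:
                total += max(0, min(e1, e2) - max(s1, s2))
        return total


@dataclass(frozen=True)
class EntityMention:
    """A typed text-bound mention (entity or event trigger): a T record."""

    id: str
    type: str
    span: TextSpan
    surface: str


@dataclass(frozen=True)
class EventMention:
    """An event anchored on a trigger mention with role-labelled arguments."""

    id: str
    type: str
    trigger: str  # id of the trigger EntityMention
    arguments: tuple[tuple[str, str], ...] = ()  # (role, filler id); roles may repeat


@dataclass(frozen=True)
class RelationMention:
    """A directed binary relation between two text-bound mentions."""

    id: str
    type: str
    source: str
    target: str


@dataclass(frozen=True)
class AttributeMention:
    """A modifier on an annotation (for this scheme: on an event).

    ``value is None`` means a binary flag that is present.
    """

    id: str
    name: str
    host: str
    value: str | None = None


@dataclass
class AnnotatedDocument:
    """One narrative's text plus all standoff annotations.

    Collections are insertion-ordered mappings keyed by annotation id; ids are
    unique across all collections.  ``notes`` holds ``#`` lines verbatim.
    """

    doc_id: str
    text: str
    entities: dict[str, EntityMention] = field(default_factory=dict)
    events: dict[str, EventMention] = field(default_factory=dict)
    relations: dict[str, RelationMention] = field(default_factory=dict)
    attributes: dict[str, AttributeMention] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    # -- structural helpers -------------------------------------------------

    def all_ids(self) -> set[str]:
        return (
            set(self.entities) | set(self.events)
            | set(self.relations) | set(self.attributes)
        )

    def trigger_ids(self) -> set[str]:
        return {ev.trigger for ev in self.events.values()}

    def non_trigger_entities(self) -> list[EntityMention]:
        """Entity mentions excluding event triggers (the 'entities' scoring layer)."""
        triggers = self.trigger_ids()
        return [e for e in self.entities.values() if e.id not in triggers]

    def n_annotations(self) -> int:
        return (
            len(self.entities) + len(self.events)
            + len(self.relations) + len(self.attributes)
        )

    def check_integrity(self) -> None:
        """Raise on any structural invariant violation.

        Checks: span bounds, surface/offset consistency, reference resolution
        (trigger, arguments, relation endpoints, attribute hosts) and the
        event-trigger typing rule that the trigger mention carries the event's
        type label.
        """
        n = len(self.text)
        for ent in self.entities.values():
            ent.span.check_within(n)
            actual = ent.span.extract(self.text)
            if actual != ent.surface:
                raise IntegrityError(
                    f"{self.doc_id}/{ent.id}: stored surface {ent.surface!r} differs "
                    f"from text at offsets {ent.span.fragments} ({actual!r})"
                )
        resolvable = set(self.entities) | set(self.events)
        for ev in self.events.values():
            if ev.trigger not in self.entities:
                raise IntegrityError(f"{self.doc_id}/{ev.id}: dangling trigger {ev.trigger}")
            if self.entities[ev.trigger].type != ev.type:
                raise IntegrityError(
                    f"{self.doc_id}/{ev.id}: trigger {ev.trigger} has type "
                    f"{self.entities[ev.trigger].type!r}, event is {ev.type!r}"
                )
            for role, filler in ev.arguments:
                if filler not in resolvable:
                    raise IntegrityError(
                        f"{self.doc_id}/{ev.id}: dangling {role} filler {filler}"
                    )
        for rel in self.relations.values():
            for end in (rel.source, rel.target):
                if end not in resolvable:
                    raise IntegrityError(f"{self.doc_id}/{rel.id}: dangling endpoint {end}")
        for attr in self.attributes.values():
            if attr.host not in resolvable:
                raise IntegrityError(f"{self.doc_id}/{attr.id}: dangling host {attr.host}")


# --------------------------------------------------------------------------
# parsing

_OFFSET_RE = re.compile(r"^\d+ \d+(?:;\d+ \d+)*$")
# brat numbers repeated roles Receiver2, Receiver3, ...
_ROLE_INDEX_RE = re.compile(r"^(.*?)(\d+)$")


def _parse_span(offsets: str, line_no: int, text_length: int) -> TextSpan:
    if not _OFFSET_RE.match(offsets):
        raise StandoffParseError(f"malformed offsets {offsets!r}", line_no)
    fragments = tuple(
        (int(s), int(e))
        for s, e in (frag.split(" ") for frag in offsets.split(";"))
    )
    try:
        span = TextSpan(fragments)
        span.check_within(text_length)
    except OffsetError as exc:
        raise OffsetError(f"line {line_no}: {exc}") from None
    return span


def _strip_role_index(role: str) -> str:
    m = _ROLE_INDEX_RE.match(role)
    return m.group(1) if m and m.group(1) else role


def parse_document(text_content: str, ann_content: str, doc_id: str) -> AnnotatedDocument:
    """Parse a (.txt content, .ann content) pair into an :class:`AnnotatedDocument`.

    Every line of ``ann_content`` is represented in the result; unknown line
    prefixes raise :class:`StandoffParseError` rather than being dropped.
    Raises :class:`IntegrityError` on duplicate ids, dangling references or a
    surface text disagreeing with the offsets, and :class:`OffsetError` when
    offsets fall outside the text.
    """
    doc = AnnotatedDocument(doc_id=doc_id, text=text_content)
    seen: set[str] = set()
    for line_no, raw in enumerate(ann_content.splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            doc.notes.append(raw)
            continue
        fields = raw.split("\t")
        aid = fields[0]
        kind = aid[0] if aid else ""
        if kind not in "TERA":
            raise StandoffParseError(f"unknown annotation prefix in {aid!r}", line_no)
        if aid in seen:
            raise IntegrityError(f"line {line_no}: duplicate annotation id {aid}")
        seen.add(aid)

        if kind == "T":
            if len(fields) != 3:
                raise StandoffParseError(
                    f"T line needs 3 tab-separated fields, got {len(fields)}", line_no
                )
            head = fields[1]
            type_token, _, offsets = head.partition(" ")
            if not offsets:
                raise StandoffParseError(f"T line missing offsets: {head!r}", line_no)
            span = _parse_span(offsets, line_no, len(text_content))
            surface = fields[2]
            expected = span.extract(text_content)
            if surface != expected:
                raise IntegrityError(
                    f"line {line_no}: surface {surface!r} does not match text "
                    f"{expected!r} at {span.fragments}"
                )
            doc.entities[aid] = EntityMention(
                id=aid, type=token_to_label(type_token), span=span, surface=surface
            )
        elif kind == "E":
            if len(fields) != 2:
                raise StandoffParseError(
                    f"E line needs 2 tab-separated fields, got {len(fields)}", line_no
                )
            tokens = fields[1].split()
            if not tokens or ":" not in tokens[0]:
                raise StandoffParseError(f"E line missing Type:Trigger: {fields[1]!r}", line_no)
            type_token, trigger = tokens[0].split(":", 1)
            args = []
            for tok in tokens[1:]:
                if ":" not in tok:
                    raise StandoffParseError(f"malformed argument {tok!r}", line_no)
                role, filler = tok.split(":", 1)
                args.append((token_to_label(_strip_role_index(role)), filler))
            doc.events[aid] = EventMention(
                id=aid, type=token_to_label(type_token),
                trigger=trigger, arguments=tuple(args),
            )
        elif kind == "R":
            if len(fields) != 2:
                raise StandoffParseError(
                    f"R line needs 2 tab-separated fields, got {len(fields)}", line_no
                )
            tokens = fields[1].split()
            if len(tokens) != 3:
                raise StandoffParseError(
                    f"R line needs 'Type Arg1:x Arg2:y', got {fields[1]!r}", line_no
                )
            endpoints = {}
            for tok in tokens[1:]:
                key, _, ref = tok.partition(":")
                if key not in ("Arg1", "Arg2") or not ref:
                    raise StandoffParseError(f"malformed relation argument {tok!r}", line_no)
                endpoints[key] = ref
            if set(endpoints) != {"Arg1", "Arg2"}:
                raise StandoffParseError("relation needs both Arg1 and Arg2", line_no)
            doc.relations[aid] = RelationMention(
                id=aid, type=token_to_label(tokens[0]),
                source=endpoints["Arg1"], target=endpoints["Arg2"],
            )
        else:  # A
            if len(fields) != 2:
                raise StandoffParseError(
                    f"A line needs 2 tab-separated fields, got {len(fields)}", line_no
                )
            tokens = fields[1].split()
            if len(tokens) not in (2, 3):
                raise StandoffParseError(
                    f"A line needs 'Name Host [Value]', got {fields[1]!r}", line_no
                )
            value = token_to_label(tokens[2]) if len(tokens) == 3 else None
            doc.attributes[aid] = AttributeMention(
                id=aid, name=token_to_label(tokens[0]), host=tokens[1], value=value
            )

    doc.check_integrity()
    return doc


# --------------------------------------------------------------------------
# serialization

def serialize_document(doc: AnnotatedDocument) -> str:
    """Emit the annotation payload so that ``parse_document`` round-trips it.

    Refuses (raising the failing invariant's error) when the document's
    structural invariants do not hold.
    """
    doc.check_integrity()
    lines: list[str] = []
    for ent in doc.entities.values():
        offsets = ";".join(f"{s} {e}" for s, e in ent.span.fragments)
        lines.append(f"{ent.id}\t{label_to_token(ent.type)} {offsets}\t{ent.surface}")
    for ev in doc.events.values():
        parts = [f"{label_to_token(ev.type)}:{ev.trigger}"]
        role_counts: dict[str, int] = {}
        for role, filler in ev.arguments:
            n = role_counts.get(role, 0) + 1
            role_counts[role] = n
            suffix = "" if n == 1 else str(n)
            parts.append(f"{label_to_token(role)}{suffix}:{filler}")
        lines.append(f"{ev.id}\t{' '.join(parts)}")
    for attr in doc.attributes.values():
        tail = f" {label_to_token(attr.value)}" if attr.value is not None else ""
        lines.append(f"{attr.id}\t{label_to_token(attr.name)} {attr.host}{tail}")
    for rel in doc.relations.values():
        lines.append(
            f"{rel.id}\t{label_to_token(rel.type)} Arg1:{rel.source} Arg2:{rel.target}"
        )
    lines.extend(doc.notes)
    return "\n".join(lines) + ("\n" if lines else "")


# --------------------------------------------------------------------------
# corpus I/O

def _iter_pairs(source) -> Iterator[tuple[Path, Path]]:
    if isinstance(source, (str, Path)):
        directory = Path(source)
        txts = {p.stem: p for p in sorted(directory.glob("*.txt"))}
        anns = {p.stem: p for p in sorted(directory.glob("*.ann"))}
        orphans = sorted(
            [str(anns[s]) for s in anns.keys() - txts.keys()]
            + [str(txts[s]) for s in txts.keys() - anns.keys()]
        )
        if orphans:
            raise MriraError(
                "unpaired standoff files (each .txt needs a .ann and vice versa): "
                + ", ".join(orphans)
            )
        for stem in sorted(txts):
            yield txts[stem], anns[stem]
    else:
        for txt, ann in source:
            txt, ann = Path(txt), Path(ann)
            if txt.stem != ann.stem:
                raise MriraError(f"pair basenames differ: {txt} vs {ann}")
            yield txt, ann


def read_corpus(source) -> dict[str, AnnotatedDocument]:
    """Read a directory (or explicit (.txt, .ann) path pairs) into documents.

    Documents are keyed by basename.  An empty directory yields an empty
    mapping; an orphaned file (missing partner) is an error.
    """
    docs: dict[str, AnnotatedDocument] = {}
    for txt_path, ann_path in _iter_pairs(source):
        try:
            text = txt_path.read_text(encoding="utf-8")
            ann = ann_path.read_text(encoding="utf-8")
        except (OSError, UnicodeError) as exc:
            raise MriraError(f"cannot read {txt_path.stem}: {exc}") from exc
        docs[txt_path.stem] = parse_document(text, ann, doc_id=txt_path.stem)
    return docs


def write_corpus(docs: Mapping[str, AnnotatedDocument] | Iterable[AnnotatedDocument],
                 directory) -> list[Path]:
    """Write each document as a `<doc_id>.txt` / `<doc_id>.ann` pair."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(docs, Mapping):
        docs = docs.values()
    written = []
    for doc in docs:
        txt = directory / f"{doc.doc_id}.txt"
        ann = directory / f"{doc.doc_id}.ann"
        txt.write_text(doc.text, encoding="utf-8")
        ann.write_text(serialize_document(doc), encoding="utf-8")
        written.extend([txt, ann])
    return written
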