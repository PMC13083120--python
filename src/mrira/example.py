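"""A small bundled demonstration document.

A synthetic incident narrative, written in the style of the scheme's worked
annotation example, carrying every annotation layer: entities, event
triggers and arguments, relations, and intent/actuality plus negation
attributes.  Used by the documentation, the test suite and the acceptance
script as a fully schema-conformant reference document.
"""

from __future__ import annotations

from .standoff import (
    AnnotatedDocument,
    AttributeMention,
    EntityMention,
    EventMention,
    RelationMention,
    TextSpan,
    serialize_document,
)

__all__ = ["worked_example", "worked_example_files"]

_TEXT = (
    "Summary:\n"
    "An elderly patient with severe pain was prescribed 10 mg of morphine "
    "subcutaneously. The nurse covering multiple patients on the busy ward "
    "administered the drug intravenously.\n"
    "\n"
    "Underlying factors:\n"
    "The error was identified immediately.\n"
    "\n"
    "Actions taken:\n"
    "The patient was monitored closely.\n"
    "\n"
    "Outcome:\n"
    "No harm occurred.\n"
)

# (id, type, surface); surfaces are unique in the text except 'patient',
# whose first occurrence is the intended one
_MENTIONS = [
    ("T1", "Age group", "elderly"),
    ("T2", "People", "patient"),
    ("T3", "Medical condition", "severe pain"),
    ("T4", "Prescribing", "prescribed"),
    ("T5", "Drug dose", "10 mg"),
    ("T6", "Drug name", "morphine"),
    ("T7", "Dose route", "subcutaneously"),
    ("T8", "People", "nurse"),
    ("T9", "Underlying and contributing factors", "covering"),
    ("T10", "People", "multiple patients"),
    ("T11", "Location", "busy ward"),
    ("T12", "Administration", "administered"),
    ("T13", "Dose route", "intravenously"),
    ("T14", "Artefact", "error"),
    ("T15", "Other action", "identified"),
    ("T16", "Date/Time", "immediately"),
    ("T17", "Action taken", "monitored"),
    ("T18", "Medical condition", "harm"),
    ("T19", "Error outcome", "occurred"),
]

_EVENTS = [
    ("E1", "Prescribing", "T4", (("Subject", "T6"), ("Receiver", "T2"))),
    ("E2", "Administration", "T12",
     (("Subject", "T6"), ("Agent", "T8"), ("Receiver", "T2"))),
    ("E3", "Underlying and contributing factors", "T9",
     (("Agent", "T8"), ("Receiver", "T10"), ("Where", "T11"))),
    ("E4", "Other action", "T15", (("Subject", "T14"), ("When", "T16"))),
    ("E5", "Action taken", "T17", (("Receiver", "T2"),)),
    ("E6", "Error outcome", "T19", (("Subject", "T18"),)),
]

_RELATIONS = [
    ("R1", "has", "T2", "T3"),
    ("R2", "has dose", "T6", "T5"),
    ("R3", "has route", "T6", "T7"),
    ("R4", "has route", "T6", "T13"),
]

_ATTRIBUTES = [
    ("A1", "Action intended but not actual", "E1"),
    ("A2", "Action not intended but actual", "E2"),
    ("A3", "Negated", "E6"),
]


def worked_example() -> AnnotatedDocument:
    """Build the demonstration document (synthetic narrative)."""
    doc = AnnotatedDocument(doc_id="worked-example", text=_TEXT)
    for tid, type_name, surface in _MENTIONS:
        start = _TEXT.find(surface)
        assert start >= 0, surface
        doc.entities[tid] = EntityMention(
            id=tid, type=type_name,
            span=TextSpan(((start, start + len(surface)),)), surface=surface,
        )
    for eid, type_name, trigger, args in _EVENTS:
        doc.events[eid] = EventMention(
            id=eid, type=type_name, trigger=trigger, arguments=args
        )
    for rid, type_name, src, tgt in _RELATIONS:
        doc.relations[rid] = RelationMention(id=rid, type=type_name, source=src, target=tgt)
    for aid, name, host in _ATTRIBUTES:
        doc.attributes[aid] = AttributeMention(id=aid, name=name, host=host)
    doc.check_integrity()
    return doc


def worked_example_files() -> tuple[str, str]:
    """The same document as (.txt content, .ann content) strings."""
    doc = worked_example()
    return doc.text, serialize_document(doc)
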