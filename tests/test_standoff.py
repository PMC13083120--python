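"""Standoff parsing, serialization and corpus I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrira import (
    AnnotatedDocument,
    AttributeMention,
    EntityMention,
    EventMention,
    IntegrityError,
    MriraError,
    OffsetError,
    RelationMention,
    StandoffParseError,
    TextSpan,
    parse_document,
    read_corpus,
    serialize_document,
    worked_example,
    write_corpus,
)


class TestTextSpan:
    def test_rejects_empty_and_inverted_fragments(self):
        with pytest.raises(OffsetError):
            TextSpan(())
        with pytest.raises(OffsetError):
            TextSpan(((5, 5),))
        with pytest.raises(OffsetError):
            TextSpan(((4, 8), (2, 3)))

    def test_discontinuous_extract_joins_with_space(self):
        span = TextSpan(((0, 4), (10, 14)))
        assert span.extract("abcdXXXXXXefghYY") == "abcd efgh"

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((((0, 8),)), (((0, 8),)), 8),
            ((((0, 8),)), (((8, 16),)), 0),
            ((((0, 4), (10, 14))), (((3, 11),)), 2),
        ],
    )
    def test_overlap_counts_characters_across_fragments(self, a, b, expected):
        assert TextSpan(a).overlap(TextSpan(b)) == expected


class TestParsing:
    def test_single_entity_line(self):
        doc = parse_document("morphine 10 mg", "T1\tDrug_name 0 8\tmorphine", "d")
        ent = doc.entities["T1"]
        assert ent.type == "Drug name"
        assert ent.span.fragments == ((0, 8),)
        assert ent.surface == "morphine"

    def test_event_with_binary_attribute(self):
        text = "morphine was not administered"
        ann = (
            "T1\tDrug_name 0 8\tmorphine\n"
            "T2\tAdministration 17 29\tadministered\n"
            "E1\tAdministration:T2 Subject:T1\n"
            "A1\tNegated E1\n"
        )
        doc = parse_document(text, ann, "d")
        ev = doc.events["E1"]
        assert ev.trigger == "T2"
        assert ev.arguments == (("Subject", "T1"),)
        attr = doc.attributes["A1"]
        assert (attr.name, attr.host, attr.value) == ("Negated", "E1", None)

    def test_empty_annotation_content(self):
        doc = parse_document("some text", "", "d")
        assert doc.text == "some text"
        assert doc.n_annotations() == 0

    def test_repeated_roles_lose_brat_numbering(self):
        text = "gave it to them and them"
        ann = (
            "T1\tAdministration 0 4\tgave\n"
            "T2\tPeople 11 15\tthem\n"
            "T3\tPeople 20 24\tthem\n"
            "E1\tAdministration:T1 Receiver:T2 Receiver2:T3\n"
        )
        doc = parse_document(text, ann, "d")
        assert doc.events["E1"].arguments == (("Receiver", "T2"), ("Receiver", "T3"))

    def test_notes_lines_are_preserved_verbatim(self):
        ann = "T1\tDrug_name 0 8\tmorphine\n#1\tAnnotatorNotes T1\tcheck spelling\n"
        doc = parse_document("morphine", ann, "d")
        assert doc.notes == ["#1\tAnnotatorNotes T1\tcheck spelling"]
        assert "#1\tAnnotatorNotes T1\tcheck spelling" in serialize_document(doc)

    @pytest.mark.parametrize(
        "ann, error",
        [
            ("T1\tDrug_name 0 8", StandoffParseError),          # missing surface field
            ("X1\tweird 0 3\tfoo", StandoffParseError),          # unknown prefix
            ("T1\tDrug_name 0 99\tmorphine", OffsetError),       # offset out of range
            ("E1\tAdministration:T9", IntegrityError),           # dangling trigger
            ("R1\thas Arg1:T1 Arg2:T9", IntegrityError),         # dangling endpoint
            ("T1\tDrug_name 0 8\tmorphXXX", IntegrityError),     # surface mismatch
            ("T1\tDrug_name 0 8\tmorphine\nT1\tPeople 0 8\tmorphine", IntegrityError),
        ],
    )
    def test_malformed_input_is_rejected(self, ann, error):
        with pytest.raises(error):
            parse_document("morphine sulfate", ann, "d")

    def test_parse_error_names_the_line(self):
        with pytest.raises(StandoffParseError, match="line 2"):
            parse_document("morphine", "T1\tDrug_name 0 8\tmorphine\nZ9\tbad", "d")

    def test_line_order_does_not_matter_for_references(self):
        text = "morphine given"
        lines = [
            "A1\tNegated E1",
            "E1\tAdministration:T2 Subject:T1",
            "T2\tAdministration 9 14\tgiven",
            "T1\tDrug_name 0 8\tmorphine",
        ]
        doc = parse_document(text, "\n".join(lines), "d")
        assert set(doc.all_ids()) == {"T1", "T2", "E1", "A1"}


class TestSerialization:
    def test_round_trip_of_worked_example(self):
        doc = worked_example()
        again = parse_document(doc.text, serialize_document(doc), doc.doc_id)
        assert again == doc

    def test_empty_document_serializes_to_empty_payload(self):
        assert serialize_document(AnnotatedDocument("d", "text")) == ""

    def test_discontinuous_span_uses_semicolon_offsets(self):
        text = "abcdXXXXXXefgh"
        span = TextSpan(((0, 4), (10, 14)))
        doc = AnnotatedDocument("d", text)
        doc.entities["T1"] = EntityMention("T1", "Function", span, span.extract(text))
        payload = serialize_document(doc)
        assert "0 4;10 14" in payload
        assert parse_document(text, payload, "d").entities["T1"].span == span

    def test_serialization_refuses_invalid_documents(self):
        doc = AnnotatedDocument("d", "morphine")
        doc.events["E1"] = EventMention("E1", "Administration", trigger="T9")
        with pytest.raises(IntegrityError, match="dangling trigger"):
            serialize_document(doc)


# ---------------------------------------------------------------------------
# property: parse ∘ serialize is the identity on valid documents

_LABELS = ("Drug name", "People", "Date/Time", "Medical condition")
_EVENT_LABELS = ("Administration", "Prescribing")
_ROLES = ("Agent", "Subject", "Receiver")


@st.composite
def documents(draw):
    words = draw(st.lists(st.text("abcdef", min_size=1, max_size=5),
                          min_size=4, max_size=15))
    text = " ".join(words)
    n = len(text)
    entities = {}
    for i in range(draw(st.integers(min_value=1, max_value=5))):
        start = draw(st.integers(min_value=0, max_value=n - 1))
        end = draw(st.integers(min_value=start + 1, max_value=n))
        fragments = [(start, end)]
        if end + 2 < n and draw(st.booleans()):
            s2 = draw(st.integers(min_value=end + 1, max_value=n - 1))
            e2 = draw(st.integers(min_value=s2 + 1, max_value=n))
            fragments.append((s2, e2))
        span = TextSpan(tuple(fragments))
        tid = f"T{i + 1}"
        entities[tid] = EntityMention(
            tid, draw(st.sampled_from(_LABELS)), span, span.extract(text)
        )
    doc = AnnotatedDocument("prop", text, entities=entities)
    ids = list(entities)
    if draw(st.booleans()):
        trig_id = ids[0]
        ev_type = draw(st.sampled_from(_EVENT_LABELS))
        entities[trig_id] = EntityMention(
            trig_id, ev_type, entities[trig_id].span, entities[trig_id].surface
        )
        args = tuple(
            (draw(st.sampled_from(_ROLES)), draw(st.sampled_from(ids)))
            for _ in range(draw(st.integers(min_value=0, max_value=3)))
        )
        doc.events["E1"] = EventMention("E1", ev_type, trig_id, args)
        doc.attributes["A1"] = AttributeMention(
            "A1", "Negated", "E1",
            value=draw(st.sampled_from([None, "Action intent not clear"])),
        )
    if len(ids) >= 2 and draw(st.booleans()):
        doc.relations["R1"] = RelationMention("R1", "has dose", ids[0], ids[1])
    doc.check_integrity()
    return doc


@settings(max_examples=60, derandomize=True, deadline=None)
@given(documents())
def test_parse_serialize_identity(doc):
    assert parse_document(doc.text, serialize_document(doc), doc.doc_id) == doc


# ---------------------------------------------------------------------------
# corpus I/O

class TestCorpusIO:
    def test_write_then_read_corpus(self, tmp_path):
        docs = {"a": worked_example()}
        docs["a"].doc_id = "a"
        write_corpus(docs, tmp_path)
        loaded = read_corpus(tmp_path)
        assert list(loaded) == ["a"]
        assert loaded["a"].entities == docs["a"].entities

    def test_orphan_file_raises(self, tmp_path):
        (tmp_path / "a.ann").write_text("", encoding="utf-8")
        with pytest.raises(MriraError, match="a.ann"):
            read_corpus(tmp_path)

    def test_empty_directory_is_empty_corpus(self, tmp_path):
        assert read_corpus(tmp_path) == {}
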