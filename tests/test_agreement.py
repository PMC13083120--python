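"""Layer scores, corpus averaging, interpretation bands and their invariants."""

import dataclasses
import math

import pytest

from mrira import (
    AnnotatedDocument,
    AttributeMention,
    EntityMention,
    EventMention,
    PerturbationConfig,
    RelationMention,
    ScoringError,
    TextSpan,
    classify_band,
    compute_prf,
    score_corpus,
    score_document_pair,
    score_event_arguments,
    score_layer,
)
from conftest import make_pairs

TEXT = "the nurse gave morphine 10 mg and noted severe pain and harm today ok"


def ent(tid, type_, surface, occurrence=0):
    start = -1
    for _ in range(occurrence + 1):
        start = TEXT.find(surface, start + 1)
    return EntityMention(tid, type_, TextSpan(((start, start + len(surface)),)), surface)


def base_reference():
    """4 entities, 1 event (+1 argument), 1 relation, 1 attribute."""
    doc = AnnotatedDocument("pair", TEXT)
    doc.entities = {
        "T1": ent("T1", "People", "nurse"),
        "T2": ent("T2", "Drug name", "morphine"),
        "T3": ent("T3", "Drug dose", "10 mg"),
        "T4": ent("T4", "Medical condition", "severe pain"),
        "T5": ent("T5", "Administration", "gave"),
    }
    doc.events = {
        "E1": EventMention("E1", "Administration", "T5", (("Agent", "T1"), ("Subject", "T2"))),
    }
    doc.relations = {"R1": RelationMention("R1", "has dose", "T2", "T3")}
    doc.attributes = {"A1": AttributeMention("A1", "Negated", "E1")}
    doc.check_integrity()
    return doc


class TestComputePrf:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((3, 4, 4), (0.75, 0.75, 0.75)),
            ((1, 1, 2), (0.5, 1.0, 2 / 3)),
            ((0, 0, 0), (1.0, 1.0, 1.0)),  # empty-layer convention
            ((0, 2, 2), (0.0, 0.0, 0.0)),
        ],
    )
    def test_formulas(self, counts, expected):
        assert compute_prf(*counts) == pytest.approx(expected)

    def test_matched_may_not_exceed_either_denominator(self):
        with pytest.raises(ScoringError):
            compute_prf(3, 2, 5)


class TestDocumentPairScoring:
    def test_self_agreement_is_perfect_everywhere(self, worked_doc_normalized):
        doc = worked_doc_normalized
        for criterion in ("strict", "relaxed"):
            for layer in ("entities", "relations", "events", "attributes"):
                score = score_layer(doc, doc, layer, criterion)
                assert score.precision == score.recall == score.f1 == 1.0
            args = score_event_arguments(doc, doc, criterion)
            assert args.f1 == 1.0

    def test_three_of_four_entities_with_one_spurious(self):
        ref = base_reference()
        resp = base_reference()
        del resp.entities["T4"]                      # one reference entity missed
        resp.entities["T9"] = ent("T9", "People", "today")  # one spurious
        resp.relations.clear()
        resp.attributes.clear()
        resp.events.clear()
        del resp.entities["T5"]  # drop the now-orphaned trigger too
        score = score_layer(ref, resp, "entities", "strict")
        assert (score.matched, score.n_reference, score.n_response) == (3, 4, 4)
        assert score.f1 == pytest.approx(0.75)

    def test_dropped_negation_hits_recall_not_precision(self):
        # one annotator left 'Negated' unset on an otherwise matched event
        ref = base_reference()
        resp = base_reference()
        resp.attributes.clear()
        score = score_layer(ref, resp, "attributes", "strict")
        assert score.matched == 0
        assert score.recall == 0.0
        assert score.precision == 1.0  # nothing spurious on the response side

    def test_relation_needs_both_endpoints_matched(self):
        ref = base_reference()
        resp = base_reference()
        # response moves the dose span entirely: entity unmatched under strict
        resp.entities["T3"] = ent("T3", "Drug dose", "today")
        strict = score_layer(ref, resp, "relations", "strict")
        assert strict.matched == 0
        # under relaxed the spans still don't overlap, so it stays unmatched
        relaxed = score_layer(ref, resp, "relations", "relaxed")
        assert relaxed.matched == 0

    def test_attribute_needs_its_host_event_matched(self):
        ref = base_reference()
        resp = base_reference()
        # response trigger moved to a disjoint span: event unmatched
        resp.entities["T5"] = EntityMention(
            "T5", "Administration",
            TextSpan(((TEXT.find("noted"), TEXT.find("noted") + 5),)), "noted",
        )
        score = score_layer(ref, resp, "attributes", "strict")
        assert score.matched == 0
        assert score_layer(ref, resp, "events", "strict").matched == 0

    def test_differing_texts_are_not_comparable(self):
        ref = base_reference()
        resp = AnnotatedDocument("pair", "completely different narrative")
        with pytest.raises(ScoringError):
            score_document_pair(ref, resp, "strict")

    def test_triggers_do_not_count_in_the_entity_layer(self):
        ref = base_reference()
        score = score_layer(ref, ref, "entities", "strict")
        assert score.n_reference == 4  # T5 is a trigger, excluded


class TestCorpusScoring:
    def test_identical_pairs_score_one_everywhere(self, worked_doc_normalized):
        doc = worked_doc_normalized
        report = score_corpus([(doc, doc), (doc, doc)])
        for criterion in ("strict", "relaxed"):
            for layer in ("entities", "relations", "events", "attributes"):
                assert report.micro[criterion][layer].f1 == 1.0
                assert report.macro[criterion][layer] == 1.0

    def test_micro_pools_counts_and_macro_averages_f1(self):
        # doc 1: matched 3 / 4 / 4  -> F1 0.75 ; doc 2: matched 1 / 2 / 2 -> F1 0.5
        ref1, resp1 = base_reference(), base_reference()
        del resp1.entities["T4"]
        resp1.entities["T9"] = ent("T9", "People", "today")
        resp1.relations.clear(); resp1.attributes.clear(); resp1.events.clear()
        del resp1.entities["T5"]

        ref2 = AnnotatedDocument("doc2", TEXT)
        ref2.entities = {"T1": ent("T1", "People", "nurse"),
                         "T2": ent("T2", "Drug name", "morphine")}
        resp2 = AnnotatedDocument("doc2", TEXT)
        resp2.entities = {"T1": ent("T1", "People", "nurse"),
                          "T2": ent("T2", "Drug name", "today")}

        report = score_corpus([(ref1, resp1), (ref2, resp2)], criteria=("strict",))
        micro = report.micro["strict"]["entities"]
        assert (micro.matched, micro.n_reference, micro.n_response) == (4, 6, 6)
        assert micro.precision == pytest.approx(4 / 6)
        assert report.macro["strict"]["entities"] == pytest.approx((0.75 + 0.5) / 2)

    def test_layer_absent_everywhere_reports_undefined(self):
        ref = AnnotatedDocument("d", TEXT)
        ref.entities = {"T1": ent("T1", "People", "nurse")}
        report = score_corpus([(ref, ref)], criteria=("strict",))
        assert math.isnan(report.micro["strict"]["relations"].f1)
        assert math.isnan(report.macro["strict"]["relations"])
        assert report.bands["strict"]["relations"] is None

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ScoringError):
            score_corpus([])

    def test_report_serializes_undefined_as_null(self):
        ref = AnnotatedDocument("d", TEXT)
        ref.entities = {"T1": ent("T1", "People", "nurse")}
        payload = score_corpus([(ref, ref)], criteria=("strict",)).to_dict()
        assert payload["micro"]["strict"]["relations"]["f1"] is None
        assert payload["micro"]["strict"]["entities"]["f1"] == 1.0


class TestRoleSymmetry:
    def test_swapping_annotators_swaps_p_and_r_and_keeps_f1(self, small_corpus):
        noise = PerturbationConfig(
            p_delete=0.15, p_insert=0.1, p_boundary=0.3, p_attr_drop=0.3
        )
        for ref, resp in make_pairs(small_corpus[:8], noise):
            for criterion in ("strict", "relaxed"):
                fwd = score_document_pair(ref, resp, criterion)
                rev = score_document_pair(resp, ref, criterion)
                for layer in ("entities", "relations", "events", "attributes"):
                    assert fwd[layer].precision == pytest.approx(rev[layer].recall)
                    assert fwd[layer].recall == pytest.approx(rev[layer].precision)
                    assert fwd[layer].f1 == pytest.approx(rev[layer].f1)

    def test_swapped_scores_in_the_report(self, worked_doc_normalized):
        doc = worked_doc_normalized
        report = score_corpus([(doc, doc)], criteria=("strict",))
        swapped = report.swapped_micro["strict"]["entities"]
        micro = report.micro["strict"]["entities"]
        assert swapped.precision == micro.recall
        assert swapped.recall == micro.precision


class TestBands:
    @pytest.mark.parametrize(
        "f1, layer, label, acceptable",
        [
            (0.85, "entities", "high", False),
            (0.62, "events", "moderate", False),
            (0.51, "attributes", "low", True),
            (0.51, "entities", "low", False),
            (0.55, "events", "low", True),
            (0.60, "events", "moderate", True),
        ],
    )
    def test_interpretation_bands(self, f1, layer, label, acceptable):
        band = classify_band(f1, layer)
        assert band.label == label
        assert band.potentially_acceptable is acceptable

    def test_out_of_range_f1_is_rejected(self):
        with pytest.raises(ScoringError):
            classify_band(1.2)
        with pytest.raises(ScoringError):
            classify_band(float("nan"))
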