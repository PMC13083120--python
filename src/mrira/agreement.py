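"""Inter-annotator agreement across the four annotation layers.

One annotator is designated the reference (ground truth) and the other the
response.  For each layer — entities, relations, events, attributes —
precision is the proportion of response annotations matching the reference,
recall the proportion of reference annotations found by the response, and
F1 their harmonic mean, under strict and relaxed span-matching criteria.

Layer match definitions
-----------------------
* entities    — typed-span match over non-trigger entity mentions;
* events      — equal event type and a span match between the triggers;
* relations   — equal relation type and *both* endpoints paired in the
  entity correspondence computed under the same criterion;
* attributes  — equal name (and value, if valued) and host events paired in
  the event correspondence.

The entity correspondence is computed once per (document pair, criterion)
and reused by the relation layer; likewise the event correspondence by the
attribute layer, so layer dependence holds by construction.

Averaging: corpus *micro* scores pool matched/reference/response counts over
documents (the headline default); *macro* scores average per-document F1,
excluding documents where the layer is empty on both sides.  F1 values are
banded for interpretation: > 0.80 high, 0.60-0.80 moderate, < 0.60 low,
with 0.50-0.60 flagged "potentially acceptable" for the event-like layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

from .alignment import Correspondence, align_annotations, span_match
from .errors import ScoringError
from .standoff import AnnotatedDocument

__all__ = [
    "LAYERS",
    "AgreementScore",
    "AgreementReport",
    "Band",
    "compute_prf",
    "classify_band",
    "score_document_pair",
    "score_layer",
    "score_event_arguments",
    "score_corpus",
]

Layer = Literal["entities", "relations", "events", "attributes"]
LAYERS: tuple[Layer, ...] = ("entities", "relations", "events", "attributes")
_EVENT_LIKE_LAYERS = {"events", "attributes", "event_arguments"}


def compute_prf(matched: int, n_reference: int, n_response: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts.

    Empty-denominator convention: an empty side with nothing matched scores
    1.0 (nothing to find, nothing found); F1 of (0, 0) is 0.
    """
    if min(matched, n_reference, n_response) < 0:
        raise ScoringError("counts must be non-negative")
    if matched > min(n_reference, n_response):
        raise ScoringError(
            f"matched ({matched}) exceeds a denominator "
            f"(reference {n_reference}, response {n_response})"
        )
    precision = matched / n_response if n_response else 1.0
    recall = matched / n_reference if n_reference else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


@dataclass(frozen=True)
class AgreementScore:
    """Counts and derived metrics for one layer under one criterion."""

    layer: str
    criterion: str
    matched: int
    n_reference: int
    n_response: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, layer: str, criterion: str, matched: int,
                    n_reference: int, n_response: int) -> "AgreementScore":
        p, r, f1 = compute_prf(matched, n_reference, n_response)
        return cls(layer, criterion, matched, n_reference, n_response, p, r, f1)

    @property
    def defined(self) -> bool:
        """False when the layer is absent on both sides (0/0)."""
        return (self.n_reference + self.n_response) > 0

    def swapped(self) -> "AgreementScore":
        """The same pair scored with reference and response roles exchanged."""
        return AgreementScore(
            self.layer, self.criterion, self.matched,
            self.n_response, self.n_reference,
            self.recall, self.precision, self.f1,
        )


class Band(NamedTuple):
    label: str  # 'high' | 'moderate' | 'low'
    potentially_acceptable: bool


def classify_band(f1: float, layer: str = "entities") -> Band:
    """Interpretation band for an F1 value.

    Above 0.80 is high, 0.60-0.80 moderate and below 0.60 low; for the
    event-like layers (events, attributes) values in [0.50, 0.60] carry an
    additional "potentially acceptable" flag.
    """
    if not (0.0 <= f1 <= 1.0) or math.isnan(f1):
        raise ScoringError(f"F1 must lie in [0, 1], got {f1}")
    if f1 > 0.80:
        label = "high"
    elif f1 >= 0.60:
        label = "moderate"
    else:
        label = "low"
    acceptable = layer in _EVENT_LIKE_LAYERS and 0.50 <= f1 <= 0.60
    return Band(label, acceptable)


# --------------------------------------------------------------------------
# document-pair scoring

def _by_start(mentions):
    return sorted(mentions, key=lambda e: (e.span.start, e.span.end, e.id))


def score_document_pair(
    reference: AnnotatedDocument,
    response: AnnotatedDocument,
    criterion: str,
) -> dict[str, AgreementScore]:
    """Score all four layers of one document pair under one criterion.

    Both documents must carry the same text and already-canonical labels
    (see :func:`mrira.schema.normalize_document`).
    """
    if reference.text != response.text:
        raise ScoringError(
            f"documents {reference.doc_id!r} and {response.doc_id!r} have different "
            "texts; their annotations are not comparable"
        )

    scores: dict[str, AgreementScore] = {}

    # entities: non-trigger mentions, typed-span match
    ref_entities = _by_start(reference.non_trigger_entities())
    resp_entities = _by_start(response.non_trigger_entities())
    entity_corr = align_annotations(ref_entities, resp_entities, criterion)
    scores["entities"] = AgreementScore.from_counts(
        "entities", criterion, len(entity_corr), len(ref_entities), len(resp_entities)
    )

    # events: equal event type + trigger span match
    def event_predicate(ev_r, ev_s):
        if ev_r.type != ev_s.type:
            return False
        return span_match(
            reference.entities[ev_r.trigger], response.entities[ev_s.trigger], criterion
        )

    def event_overlap(ev_r, ev_s):
        return reference.entities[ev_r.trigger].span.overlap(
            response.entities[ev_s.trigger].span
        )

    ref_events = sorted(
        reference.events.values(),
        key=lambda ev: (reference.entities[ev.trigger].span.start, ev.id),
    )
    resp_events = sorted(
        response.events.values(),
        key=lambda ev: (response.entities[ev.trigger].span.start, ev.id),
    )
    event_corr = align_annotations(
        ref_events, resp_events, predicate=event_predicate, overlap=event_overlap
    )
    scores["events"] = AgreementScore.from_counts(
        "events", criterion, len(event_corr), len(ref_events), len(resp_events)
    )

    # relations: type equal + both endpoints paired in the entity correspondence
    entity_map = entity_corr.mapping

    def relation_predicate(rel_r, rel_s):
        return (
            rel_r.type == rel_s.type
            and entity_map.get(rel_r.source) == rel_s.source
            and entity_map.get(rel_r.target) == rel_s.target
        )

    rel_corr = align_annotations(
        list(reference.relations.values()),
        list(response.relations.values()),
        predicate=relation_predicate,
    )
    scores["relations"] = AgreementScore.from_counts(
        "relations", criterion, len(rel_corr),
        len(reference.relations), len(response.relations),
    )

    # attributes: name (+ value) equal + hosts paired in the event correspondence
    host_map = event_corr.mapping | entity_map  # entity hosts tolerated at parse time

    def attribute_predicate(a_r, a_s):
        return (
            a_r.name == a_s.name
            and a_r.value == a_s.value
            and host_map.get(a_r.host) == a_s.host
        )

    attr_corr = align_annotations(
        list(reference.attributes.values()),
        list(response.attributes.values()),
        predicate=attribute_predicate,
    )
    scores["attributes"] = AgreementScore.from_counts(
        "attributes", criterion, len(attr_corr),
        len(reference.attributes), len(response.attributes),
    )

    # stash the correspondences for diagnostics
    scores["_correspondences"] = {  # type: ignore[assignment]
        "entities": entity_corr, "events": event_corr,
        "relations": rel_corr, "attributes": attr_corr,
    }
    return scores


def score_layer(
    reference: AnnotatedDocument,
    response: AnnotatedDocument,
    layer: Layer,
    criterion: str,
) -> AgreementScore:
    """Agreement on one layer of one document pair."""
    if layer not in LAYERS:
        raise ScoringError(f"layer must be one of {LAYERS}, got {layer!r}")
    return score_document_pair(reference, response, criterion)[layer]


def score_event_arguments(
    reference: AnnotatedDocument,
    response: AnnotatedDocument,
    criterion: str,
) -> AgreementScore:
    """Diagnostic sub-score: role-labelled arguments of matched events.

    An argument matches when the roles are equal and the fillers correspond
    (via the entity or event correspondence under the same criterion).  Only
    arguments of matched events enter the denominators, so this isolates
    argument disagreement from trigger disagreement.
    """
    pair = score_document_pair(reference, response, criterion)
    corrs = pair["_correspondences"]  # type: ignore[index]
    filler_map = dict(corrs["entities"].pairs) | dict(corrs["events"].pairs)
    # triggers of matched events also correspond
    for ev_r_id, ev_s_id in corrs["events"].pairs:
        filler_map[reference.events[ev_r_id].trigger] = response.events[ev_s_id].trigger

    matched = n_ref = n_resp = 0
    for ev_r_id, ev_s_id in corrs["events"].pairs:
        args_r = list(reference.events[ev_r_id].arguments)
        args_s = list(response.events[ev_s_id].arguments)
        n_ref += len(args_r)
        n_resp += len(args_s)
        used: set[int] = set()
        for role_r, filler_r in args_r:
            for j, (role_s, filler_s) in enumerate(args_s):
                if j in used:
                    continue
                if role_r == role_s and filler_map.get(filler_r) == filler_s:
                    used.add(j)
                    matched += 1
                    break
    return AgreementScore.from_counts("event_arguments", criterion, matched, n_ref, n_resp)


# --------------------------------------------------------------------------
# corpus scoring

@dataclass
class AgreementReport:
    """Per-document, pooled (micro) and averaged (macro) agreement scores."""

    per_document: dict[str, dict[str, dict[str, AgreementScore]]]
    # criterion -> layer -> score
    micro: dict[str, dict[str, AgreementScore]]
    macro: dict[str, dict[str, float]]
    bands: dict[str, dict[str, Band | None]] = field(default_factory=dict)
    swapped_micro: dict[str, dict[str, AgreementScore]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def score_dict(s: AgreementScore) -> dict:
            return {
                "matched": s.matched,
                "n_reference": s.n_reference,
                "n_response": s.n_response,
                "precision": None if math.isnan(s.precision) else round(s.precision, 6),
                "recall": None if math.isnan(s.recall) else round(s.recall, 6),
                "f1": None if math.isnan(s.f1) else round(s.f1, 6),
            }

        return {
            "micro": {
                crit: {layer: score_dict(s) for layer, s in layers.items()}
                for crit, layers in self.micro.items()
            },
            "macro": {
                crit: {
                    layer: (None if math.isnan(v) else round(v, 6))
                    for layer, v in layers.items()
                }
                for crit, layers in self.macro.items()
            },
            "bands": {
                crit: {
                    layer: (
                        None if band is None
                        else {"label": band.label,
                              "potentially_acceptable": band.potentially_acceptable}
                    )
                    for layer, band in layers.items()
                }
                for crit, layers in self.bands.items()
            },
            "swapped_micro": {
                crit: {layer: score_dict(s) for layer, s in layers.items()}
                for crit, layers in self.swapped_micro.items()
            },
            "per_document": {
                doc_id: {
                    crit: {layer: score_dict(s) for layer, s in layers.items()}
                    for crit, layers in crits.items()
                }
                for doc_id, crits in self.per_document.items()
            },
        }

    def to_markdown(self) -> str:
        """Per-layer table in the familiar 'Averaged F1 by layer' shape."""
        lines = ["| Annotation layer | Strict F1 | Relaxed F1 |",
                 "| --- | --- | --- |"]
        for layer in LAYERS:
            cells = []
            for crit in ("strict", "relaxed"):
                score = self.micro.get(crit, {}).get(layer)
                if score is None or math.isnan(score.f1):
                    cells.append("NA")
                else:
                    cells.append(f"{score.f1:.2f}")
            lines.append(f"| {layer.capitalize()} | {cells[0]} | {cells[1]} |")
        lines.append("")
        lines.append("Micro-averaged (pooled counts); macro averages and per-document "
                     "scores are in the JSON report.")
        return "\n".join(lines)


def score_corpus(
    pairs: Sequence[tuple[AnnotatedDocument, AnnotatedDocument]],
    criteria: Iterable[str] = ("strict", "relaxed"),
) -> AgreementReport:
    """Agreement over a corpus of (reference, response) document pairs.

    Micro scores pool raw counts over documents; macro scores average
    per-document F1 over documents where the layer occurs on at least one
    side.  A layer absent from every document reports NaN (undefined), not 0.
    """
    pairs = list(pairs)
    if not pairs:
        raise ScoringError("score_corpus needs at least one document pair")

    per_document: dict[str, dict[str, dict[str, AgreementScore]]] = {}
    micro: dict[str, dict[str, AgreementScore]] = {}
    macro: dict[str, dict[str, float]] = {}
    bands: dict[str, dict[str, Band | None]] = {}
    swapped: dict[str, dict[str, AgreementScore]] = {}

    for criterion in criteria:
        pooled = {layer: [0, 0, 0] for layer in LAYERS}
        per_doc_f1 = {layer: [] for layer in LAYERS}
        for ref, resp in pairs:
            doc_scores = score_document_pair(ref, resp, criterion)
            doc_entry = per_document.setdefault(ref.doc_id, {})
            doc_entry[criterion] = {layer: doc_scores[layer] for layer in LAYERS}
            for layer in LAYERS:
                s = doc_scores[layer]
                pooled[layer][0] += s.matched
                pooled[layer][1] += s.n_reference
                pooled[layer][2] += s.n_response
                if s.defined:
                    per_doc_f1[layer].append(s.f1)

        micro[criterion] = {}
        macro[criterion] = {}
        bands[criterion] = {}
        swapped[criterion] = {}
        for layer in LAYERS:
            matched, n_ref, n_resp = pooled[layer]
            if n_ref + n_resp == 0:
                score = AgreementScore(
                    layer, criterion, 0, 0, 0,
                    math.nan, math.nan, math.nan,
                )
            else:
                score = AgreementScore.from_counts(
                    layer, criterion, matched, n_ref, n_resp
                )
            micro[criterion][layer] = score
            swapped[criterion][layer] = score.swapped()
            macro[criterion][layer] = (
                sum(per_doc_f1[layer]) / len(per_doc_f1[layer])
                if per_doc_f1[layer]
                else math.nan
            )
            bands[criterion][layer] = (
                classify_band(score.f1, layer) if not math.isnan(score.f1) else None
            )

    return AgreementReport(
        per_document=per_document,
        micro=micro,
        macro=macro,
        bands=bands,
        swapped_micro=swapped,
    )
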