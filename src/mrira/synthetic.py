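"""Synthetic medication-incident narratives with gold annotations, plus a
parameterised annotator-disagreement model.

The real corpora this package targets are access-restricted, so the
generator emulates their observable structure instead: each report carries
the free-text subsections of an incident record (summary, underlying
factors, actions taken, actions planned, outcome), slot-filled template
sentences in the style of a worked incident narrative ("An elderly patient
... was prescribed 10 mg of morphine ... administered intravenously"), and
annotation-type frequencies drawn from the published development-corpus
profile (weights proportional to its per-type counts, with a small floor so
zero-count types are still exercised).  Text is assembled with exact offset
tracking, so every emitted annotation is schema-valid by construction and a
fixed seed reproduces the corpus byte for byte.

The disagreement model derives a simulated second annotator from gold by
independent per-annotation perturbation operators mirroring the observed
disagreement taxonomy: span-boundary jitter (span granularity), attribute
dropping (attribute assignment), relation retargeting (relation scope),
plus deletion/insertion operators for recall/precision control.  For
deletion/insertion-only configurations the expected layer scores have a
closed form (:func:`expected_scores`), which the tests use for parameter
recovery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .schema import MRIRASchema, build_default_schema, validate_document
from .standoff import (
    AnnotatedDocument,
    AttributeMention,
    EntityMention,
    EventMention,
    RelationMention,
    TextSpan,
)

__all__ = [
    "GeneratorConfig",
    "PerturbationConfig",
    "generate_corpus",
    "perturb_document",
    "expected_scores",
    "stratified_sample",
    "DEFAULT_ENTITY_WEIGHTS",
    "DEFAULT_EVENT_WEIGHTS",
    "DEFAULT_VOCABULARY",
]

SECTIONS = ("summary", "underlying factors", "actions taken", "actions planned", "outcome")

_HEADINGS = {
    "summary": "Summary:",
    "underlying factors": "Underlying factors:",
    "actions taken": "Actions taken:",
    "actions planned": "Actions planned:",
    "outcome": "Outcome:",
}

HARM_LEVELS = ("low", "moderate", "high", "unspecified")

#: development-corpus per-type counts, with a floor of 2 for zero-count types
#: so rare-type code paths are exercised
DEFAULT_ENTITY_WEIGHTS: dict[str, float] = {
    "Drug name": 194, "Drug strength or amount": 52, "Drug form": 55,
    "Drug dose": 66, "Drug frequency": 26, "Dose route": 5, "Dose duration": 2,
    "People": 335, "Location": 58, "Artefact": 110, "Knowledge": 84,
    "Function": 50, "Date/Time": 129, "Medical condition": 26,
    "Age group": 1, "Gender": 9,
}

DEFAULT_EVENT_WEIGHTS: dict[str, float] = {
    "Prescribing": 42, "Transcription": 2, "Dispensing": 10, "Administration": 50,
    "Monitoring": 2, "Corrective action": 144, "Preventive action": 67,
    "Underlying and contributing factors": 16, "Error outcome": 11, "Other action": 8,
    "Action taken": 2,
}

DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "People": ("patient", "nurse", "pharmacist", "doctor", "carer", "paramedic"),
    "Location": ("busy ward", "pharmacy", "care home", "treatment room",
                 "emergency department"),
    "Date/Time": ("immediately", "overnight", "yesterday evening", "at 08:00",
                  "this morning", "on admission"),
    "Artefact": ("error", "CD register", "prescription chart", "syringe driver",
                 "medication trolley"),
    "Knowledge": ("discrepancy", "omission", "miscalculation", "wrong entry"),
    "Function": ("stock check", "double signature", "second check", "audit"),
    "Age group": ("elderly", "middle-aged", "young"),
    "Gender": ("female", "male"),
    "Drug name": ("morphine", "oxycodone", "fentanyl", "methadone", "diazepam",
                  "midazolam", "codeine", "tramadol"),
    "Drug form": ("tablet", "patch", "injection", "solution", "capsule"),
    "Drug strength or amount": ("10 mg/ml", "50 micrograms", "30 mg", "two boxes"),
    "Drug dose": ("10 mg", "5 ml", "2.5 mg", "one tablet", "20 mg"),
    "Drug frequency": ("twice daily", "once daily", "every four hours", "as required"),
    "Dose route": ("orally", "intravenously", "subcutaneously", "intramuscularly"),
    "Dose duration": ("for five days", "for one week", "for 48 hours"),
    "Medical condition": ("severe pain", "agitation", "palliative care needs",
                          "breakthrough pain", "anxiety"),
    # trigger words per event type
    "Prescribing": ("prescribed",),
    "Transcription": ("transcribed",),
    "Dispensing": ("dispensed", "supplied"),
    "Administration": ("administered", "given"),
    "Monitoring": ("monitored",),
    "Corrective action": ("corrected", "amended", "rectified"),
    "Preventive action": ("briefed", "retrained"),
    "Underlying and contributing factors": ("covering", "short-staffed"),
    "Error outcome": ("occurred", "resulted"),
    "Action taken": ("escalated", "reported"),
    "Other action": ("identified", "noticed"),
}

# descriptive phrasing around a mention: (prefix, suffix)
_DESC_TEMPLATES: dict[str, tuple[str, str]] = {
    "People": ("the ", ""),
    "Location": ("the ", ""),
    "Artefact": ("the ", ""),
    "Knowledge": ("the ", ""),
    "Function": ("the ", ""),
    "Age group": ("an ", " patient"),
    "Gender": ("a ", " patient"),
    "Drug dose": ("a dose of ", ""),
    "Dose route": ("given ", ""),
    "Drug form": ("the ", " form"),
    "Drug frequency": ("dosing ", ""),
    "Dose duration": ("treatment ", ""),
}

_DESC_OPENERS = ("The report noted ", "Staff recorded ", "The review described ",
                 "Documentation mentioned ")

_SECTION_FOR_EVENT = {
    "Prescribing": "summary", "Transcription": "summary", "Dispensing": "summary",
    "Administration": "summary", "Monitoring": "summary",
    "Underlying and contributing factors": "underlying factors",
    "Corrective action": "actions taken", "Action taken": "actions taken",
    "Other action": "actions taken",
    "Preventive action": "actions planned",
    "Error outcome": "outcome",
}

_INTENT_ATTRIBUTES = (
    "Action intended and actual",
    "Action not intended but actual",
    "Action intended but not actual",
    "Action intent not clear",
)

_DEFAULT_CONFUSABILITY: tuple[tuple[str, ...], ...] = (
    ("Drug dose", "Drug strength or amount"),
    ("Artefact", "Knowledge"),
    ("Corrective action", "Preventive action"),
    ("Action taken", "Other action"),
)


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults reproduce the development-corpus profile: ~21.8 entity and
    ~6.4 event annotations per report (1200 entities and 350 events over
    55 reports), type weights proportional to the per-type counts, and
    attribute rates of 20/350 (intent/actuality) and 5/350 (Negated) per
    event.  Harm-stratum weights are a realistic skew chosen once (most
    incidents reported as low or unspecified harm).
    """

    seed: int = 0
    n_reports: int = 10
    mean_entities: float = 1200 / 55
    mean_events: float = 350 / 55
    section_profile: tuple[str, ...] = SECTIONS
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_WEIGHTS))
    event_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_WEIGHTS))
    vocabulary: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_VOCABULARY.items()})
    harm_weights: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.45, "moderate": 0.25,
                                 "high": 0.05, "unspecified": 0.25})
    intent_attr_rate: float = 20 / 350
    negated_attr_rate: float = 5 / 350
    relation_rate: float = 0.9
    doc_id_prefix: str = "report"

    def validate(self) -> None:
        for name, weights in (("type_weights", self.type_weights),
                              ("event_weights", self.event_weights),
                              ("harm_weights", self.harm_weights)):
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{name} must be non-negative")
            if not any(w > 0 for w in weights.values()):
                raise ConfigError(f"{name} needs at least one positive weight")
        enabled = [t for w in (self.type_weights, self.event_weights)
                   for t, weight in w.items() if weight > 0]
        for t in enabled:
            if not self.vocabulary.get(t):
                raise ConfigError(f"enabled type {t!r} has an empty vocabulary")
        if self.n_reports < 0:
            raise ConfigError("n_reports must be >= 0")
        unknown = set(self.section_profile) - set(SECTIONS)
        if unknown or not self.section_profile:
            raise ConfigError(f"section_profile must be a non-empty subset of {SECTIONS}")


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-operator disagreement rates for the simulated second annotator.

    ``p_boundary`` jitters a span while always preserving >=1 character of
    overlap and the label; ``p_attr_drop`` omits an attribute;
    ``p_rel_retarget`` moves a relation endpoint to another schema-compatible
    entity — mirroring the span-granularity, attribute-assignment and
    relation-scope disagreement themes.  ``p_delete`` / ``p_insert`` control
    recall and precision directly.
    """

    p_delete: float = 0.0
    p_insert: float = 0.0
    p_boundary: float = 0.0
    p_relabel: float = 0.0
    p_attr_drop: float = 0.0
    p_rel_retarget: float = 0.0
    seed: int = 0
    confusability: tuple[tuple[str, ...], ...] = _DEFAULT_CONFUSABILITY

    def validate(self) -> None:
        for name in ("p_delete", "p_boundary", "p_relabel",
                     "p_attr_drop", "p_rel_retarget"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.p_insert < 0:
            raise ConfigError("p_insert must be >= 0")


# --------------------------------------------------------------------------
# generation internals

class _Pool:
    """Multiset of annotation types to be consumed while rendering."""

    def __init__(self, types: Iterable[str]):
        self.items: list[str] = list(types)

    def take(self, type_name: str) -> bool:
        try:
            self.items.remove(type_name)
            return True
        except ValueError:
            return False

    def take_front(self, k: int) -> list[str]:
        taken, self.items = self.items[:k], self.items[k:]
        return taken

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class _SentencePlan:
    # pieces: (literal text, annotation key or None); a keyed piece is a mention
    pieces: list[tuple[str, tuple[int, str] | None]] = field(default_factory=list)
    # (event type, trigger key, [(role, filler key)], [attribute names])
    events: list[tuple[str, int, list[tuple[str, int]], list[str]]] = field(
        default_factory=list)
    relations: list[tuple[str, int, int]] = field(default_factory=list)


def _choice(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _plan_event_sentence(
    etype: str, pool: _Pool, cfg: GeneratorConfig, rng: np.random.Generator,
    next_key,
) -> _SentencePlan:
    vocab = cfg.vocabulary
    plan = _SentencePlan()
    pieces = plan.pieces
    args: list[tuple[str, int]] = []

    subj_key = None
    if pool.take("People"):
        subj_key = next_key()
        pieces.append(("The ", None))
        pieces.append((_choice(rng, vocab["People"]), (subj_key, "People")))
        args.append(("Agent", subj_key))
    else:
        pieces.append(("Staff", None))

    negated = rng.random() < cfg.negated_attr_rate
    if negated:
        pieces.append((" had not", None))
    trig_key = next_key()
    pieces.append((" ", None))
    pieces.append((_choice(rng, vocab[etype]), (trig_key, etype)))

    obj_key = obj_type = None
    for candidate in ("Drug name", "Artefact", "Knowledge"):
        if pool.take(candidate):
            obj_key, obj_type = next_key(), candidate
            det = " " if candidate == "Drug name" else " the "
            pieces.append((det, None))
            pieces.append((_choice(rng, vocab[candidate]), (obj_key, candidate)))
            break
    if obj_key is None:
        pieces.append((" the medication", None))
    else:
        args.append(("Subject", obj_key))

    def rel(rtype: str, src: int | None, tgt: int | None) -> None:
        if src is not None and tgt is not None and rng.random() < cfg.relation_rate:
            plan.relations.append((rtype, src, tgt))

    drug = obj_key if obj_type == "Drug name" else None
    dose_key = None
    extras = 0
    for etype2, prefix, role, max_extras in (
        ("Drug dose", " ", None, 5),
        ("Drug strength or amount", " ", None, 5),
        ("Drug form", " as a ", None, 5),
        ("Drug frequency", " ", None, 5),
        ("Dose route", " ", None, 5),
        ("Dose duration", " ", None, 5),
    ):
        if extras >= max_extras or not pool.take(etype2):
            continue
        extras += 1
        key = next_key()
        pieces.append((prefix, None))
        pieces.append((_choice(rng, vocab[etype2]), (key, etype2)))
        if etype2 == "Drug dose":
            dose_key = key
            rel("has dose", drug, key)
        elif etype2 == "Drug strength or amount":
            rel("has strength or amount", drug, key)
        elif etype2 == "Drug form":
            rel("has form", drug, key)
        elif etype2 == "Drug frequency":
            rel("has frequency", drug, key)
        elif etype2 == "Dose route":
            rel("has route", drug, key)
        elif etype2 == "Dose duration":
            rel("has duration", drug, key)

    recv_key = None
    if pool.take("People"):
        recv_key = next_key()
        pieces.append((" to the ", None))
        pieces.append((_choice(rng, vocab["People"]), (recv_key, "People")))
        args.append(("Receiver", recv_key))

    person = recv_key if recv_key is not None else subj_key
    if pool.take("Medical condition"):
        key = next_key()
        pieces.append((" for ", None))
        pieces.append((_choice(rng, vocab["Medical condition"]), (key, "Medical condition")))
        args.append(("For", key))
        rel("has", person, key)
    if pool.take("Date/Time"):
        key = next_key()
        pieces.append((" ", None))
        pieces.append((_choice(rng, vocab["Date/Time"]), (key, "Date/Time")))
        args.append(("When", key))
        rel("has time", dose_key, key)
    if pool.take("Location"):
        key = next_key()
        pieces.append((" on the ", None))
        pieces.append((_choice(rng, vocab["Location"]), (key, "Location")))
        args.append(("Where", key))
        rel("at", person, key)

    pieces.append((".", None))

    attrs: list[str] = []
    if rng.random() < cfg.intent_attr_rate:
        attrs.append(_choice(rng, _INTENT_ATTRIBUTES))
    if negated:
        attrs.append("Negated")
    plan.events.append((etype, trig_key, args, attrs))
    return plan


def _plan_descriptive_sentence(
    types: list[str], cfg: GeneratorConfig, rng: np.random.Generator,
    schema: MRIRASchema, next_key,
) -> _SentencePlan:
    vocab = cfg.vocabulary
    plan = _SentencePlan()
    plan.pieces.append((_choice(rng, _DESC_OPENERS), None))
    keys: list[tuple[int, str]] = []
    for i, t in enumerate(types):
        if i:
            sep = " and " if i == len(types) - 1 else ", "
            plan.pieces.append((sep, None))
        prefix, suffix = _DESC_TEMPLATES.get(t, ("", ""))
        key = next_key()
        keys.append((key, t))
        if prefix:
            plan.pieces.append((prefix, None))
        plan.pieces.append((_choice(rng, vocab[t]), (key, t)))
        if suffix:
            plan.pieces.append((suffix, None))
    plan.pieces.append((".", None))

    allowed = {(s, t): name
               for name, pairs in schema.relation_types.items() for s, t in pairs}
    for i, (key_a, type_a) in enumerate(keys):
        for key_b, type_b in keys[i + 1:]:
            if (type_a, type_b) in allowed and rng.random() < cfg.relation_rate:
                plan.relations.append((allowed[(type_a, type_b)], key_a, key_b))
            elif (type_b, type_a) in allowed and rng.random() < cfg.relation_rate:
                plan.relations.append((allowed[(type_b, type_a)], key_b, key_a))
    return plan


def _layout_report(
    doc_id: str, plans_by_section: dict[str, list[_SentencePlan]],
    section_profile: Sequence[str],
) -> AnnotatedDocument:
    """Write the text and materialise annotations with exact offsets."""
    doc = AnnotatedDocument(doc_id=doc_id, text="")
    parts: list[str] = []
    pos = 0
    key_to_tid: dict[int, str] = {}
    counters = {"T": 0, "E": 0, "R": 0, "A": 0}

    def raw(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    pending_events: list[tuple[str, int, list[tuple[str, int]], list[str]]] = []
    pending_relations: list[tuple[str, int, int]] = []

    for s_idx, section in enumerate(section_profile):
        raw(_HEADINGS[section] + "\n")
        plans = plans_by_section.get(section, [])
        if not plans:
            raw("No further details were recorded.")
        for p_idx, plan in enumerate(plans):
            if p_idx:
                raw(" ")
            for text, ann in plan.pieces:
                if ann is None:
                    raw(text)
                else:
                    key, type_name = ann
                    start = pos
                    raw(text)
                    counters["T"] += 1
                    tid = f"T{counters['T']}"
                    key_to_tid[key] = tid
                    doc.entities[tid] = EntityMention(
                        id=tid, type=type_name,
                        span=TextSpan(((start, pos),)), surface=text,
                    )
            pending_events.extend(plan.events)
            pending_relations.extend(plan.relations)
        raw("\n" if s_idx == len(section_profile) - 1 else "\n\n")

    doc.text = "".join(parts)

    for etype, trig_key, args, attrs in pending_events:
        counters["E"] += 1
        eid = f"E{counters['E']}"
        doc.events[eid] = EventMention(
            id=eid, type=etype, trigger=key_to_tid[trig_key],
            arguments=tuple((role, key_to_tid[k]) for role, k in args),
        )
        for attr_name in attrs:
            counters["A"] += 1
            aid = f"A{counters['A']}"
            doc.attributes[aid] = AttributeMention(id=aid, name=attr_name, host=eid)
    for rtype, src_key, tgt_key in pending_relations:
        counters["R"] += 1
        rid = f"R{counters['R']}"
        doc.relations[rid] = RelationMention(
            id=rid, type=rtype, source=key_to_tid[src_key], target=key_to_tid[tgt_key],
        )
    return doc


def generate_document(
    doc_id: str, cfg: GeneratorConfig, rng: np.random.Generator,
    schema: MRIRASchema,
) -> AnnotatedDocument:
    """Generate one report (all sections, annotations schema-valid)."""
    ent_names = [t for t, w in cfg.type_weights.items() if w > 0]
    ent_w = np.array([cfg.type_weights[t] for t in ent_names], dtype=float)
    ent_w /= ent_w.sum()
    ev_names = [t for t, w in cfg.event_weights.items() if w > 0]
    ev_w = np.array([cfg.event_weights[t] for t in ev_names], dtype=float)
    ev_w /= ev_w.sum()

    n_ent = max(3, int(rng.poisson(cfg.mean_entities)))
    n_evt = max(1, int(rng.poisson(cfg.mean_events)))
    pool = _Pool(rng.choice(ent_names, size=n_ent, p=ent_w).tolist())
    event_types = rng.choice(ev_names, size=n_evt, p=ev_w).tolist()

    key_counter = iter(range(10 ** 6))

    def next_key() -> int:
        return next(key_counter)

    enabled = list(cfg.section_profile)
    plans_by_section: dict[str, list[_SentencePlan]] = {s: [] for s in enabled}
    for etype in event_types:
        section = _SECTION_FOR_EVENT.get(etype, enabled[0])
        if section not in plans_by_section:
            section = enabled[0]
        plans_by_section[section].append(
            _plan_event_sentence(etype, pool, cfg, rng, next_key)
        )
    # weave remaining entity mentions into descriptive sentences, spread
    # round-robin over the enabled sections
    s_idx = 0
    while len(pool):
        group = pool.take_front(int(rng.integers(1, 4)))
        plans_by_section[enabled[s_idx % len(enabled)]].append(
            _plan_descriptive_sentence(group, cfg, rng, schema, next_key)
        )
        s_idx += 1

    doc = _layout_report(doc_id, plans_by_section, enabled)
    doc.check_integrity()
    return doc


def generate_corpus(
    config: GeneratorConfig, schema: MRIRASchema | None = None,
) -> list[tuple[AnnotatedDocument, str]]:
    """Generate ``config.n_reports`` annotated reports with harm levels.

    Deterministic under ``config.seed``; every document validates with zero
    violations against the schema.
    """
    config.validate()
    if schema is None:
        schema = build_default_schema()
    rng = np.random.default_rng(config.seed)
    harm_names = list(config.harm_weights)
    harm_w = np.array([config.harm_weights[h] for h in harm_names], dtype=float)
    harm_w /= harm_w.sum()

    width = max(3, len(str(max(config.n_reports, 1))))
    out: list[tuple[AnnotatedDocument, str]] = []
    for i in range(config.n_reports):
        doc_id = f"{config.doc_id_prefix}-{i + 1:0{width}d}"
        doc = generate_document(doc_id, config, rng, schema)
        violations = validate_document(schema, doc)
        if violations:  # pragma: no cover - generator contract
            raise AssertionError(
                f"generator produced an invalid document: {violations[:3]}"
            )
        harm = harm_names[int(rng.choice(len(harm_names), p=harm_w))]
        out.append((doc, harm))
    return out


# --------------------------------------------------------------------------
# perturbation

_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z\-]{2,}")


def _jitter_span(span: TextSpan, text: str, rng: np.random.Generator) -> TextSpan:
    """Move one boundary of the first fragment, keeping >=1 char of overlap
    and never pulling a newline or tab into the span.  Returns the original
    span when no admissible move exists (single-character span at both text
    boundaries)."""
    s, e = span.fragments[0]
    n = len(text)
    options: list[tuple[int, int]] = []
    for k in (1, 2, 3):
        if e + k <= n and not any(c in "\n\t" for c in text[e:e + k]):
            options.append((s, e + k))
        if s - k >= 0 and not any(c in "\n\t" for c in text[s - k:s]):
            options.append((s - k, e))
        if e - s > k:
            options.append((s, e - k))
            options.append((s + k, e))
    if not options:
        return span
    s2, e2 = options[int(rng.integers(len(options)))]
    return TextSpan(((s2, e2),) + span.fragments[1:])


def _max_id_index(ids: Iterable[str]) -> int:
    best = 0
    for i in ids:
        m = re.match(r"^[A-Z](\d+)$", i)
        if m:
            best = max(best, int(m.group(1)))
    return best


def perturb_document(
    gold: AnnotatedDocument,
    p: PerturbationConfig,
    schema: MRIRASchema | None = None,
) -> AnnotatedDocument:
    """Derive a plausible second annotator's document from gold.

    Operators are applied independently per annotation at the configured
    rates; deletions cascade (no dangling references) and the result is
    always schema-valid.  Deterministic under ``p.seed``.
    """
    p.validate()
    if schema is None:
        schema = build_default_schema()
    rng = np.random.default_rng(p.seed)

    entities = dict(gold.entities)
    events = dict(gold.events)
    relations = dict(gold.relations)
    attributes = dict(gold.attributes)
    trigger_ids = {ev.trigger for ev in events.values()}

    # deletion: non-trigger entities, then whole events (trigger goes too)
    if p.p_delete > 0:
        for eid in list(entities):
            if eid in trigger_ids:
                continue
            if rng.random() < p.p_delete:
                del entities[eid]
        for evid in list(events):
            if rng.random() < p.p_delete:
                trig = events.pop(evid).trigger
                if not any(ev.trigger == trig for ev in events.values()):
                    del entities[trig]

    surviving = set(entities) | set(events)
    relations = {
        rid: r for rid, r in relations.items()
        if r.source in surviving and r.target in surviving
    }
    events = {
        evid: replace(ev, arguments=tuple(
            (role, f) for role, f in ev.arguments if f in surviving))
        for evid, ev in events.items()
    }
    attributes = {
        aid: a for aid, a in attributes.items() if a.host in surviving
    }
    trigger_ids = {ev.trigger for ev in events.values()}

    # relabel within confusability sets (entity or event types)
    if p.p_relabel > 0:
        confusions: dict[str, list[str]] = {}
        for group in p.confusability:
            for t in group:
                confusions[t] = [o for o in group if o != t]
        for eid, ent in list(entities.items()):
            if eid in trigger_ids or ent.type not in confusions:
                continue
            if rng.random() < p.p_relabel:
                entities[eid] = replace(
                    ent, type=_choice(rng, confusions[ent.type]))
        for evid, ev in list(events.items()):
            if ev.type not in confusions:
                continue
            if rng.random() < p.p_relabel:
                new_type = _choice(rng, confusions[ev.type])
                events[evid] = replace(ev, type=new_type)
                entities[ev.trigger] = replace(entities[ev.trigger], type=new_type)
        # relabelling can break endpoint constraints; drop offending relations
        def endpoint_type(ann_id: str) -> str | None:
            if ann_id in entities:
                return schema.resolve(entities[ann_id].type).label
            if ann_id in events:
                return schema.resolve(events[ann_id].type).label
            return None

        for rid, r in list(relations.items()):
            name = schema.resolve(r.type).label
            if name in schema.relation_types:
                pair = (endpoint_type(r.source), endpoint_type(r.target))
                if pair not in schema.relation_types[name]:
                    del relations[rid]

    # span-boundary jitter (preserves label and >=1 character of overlap)
    if p.p_boundary > 0:
        for eid, ent in list(entities.items()):
            if rng.random() < p.p_boundary:
                new_span = _jitter_span(ent.span, gold.text, rng)
                entities[eid] = replace(
                    ent, span=new_span, surface=new_span.extract(gold.text))

    # spurious entity insertion over unannotated tokens
    if p.p_insert > 0:
        n_gold = len(gold.non_trigger_entities())
        n_insert = int(rng.poisson(p.p_insert * n_gold))
        if n_insert:
            occupied = [ent.span for ent in gold.entities.values()]
            occupied += [ent.span for ent in entities.values()]

            def free(start: int, end: int) -> bool:
                probe = TextSpan(((start, end),))
                return all(probe.overlap(sp) == 0 for sp in occupied)

            candidates = [
                m.span() for m in _TOKEN_RE.finditer(gold.text)
                if free(*m.span())
            ]
            n_insert = min(n_insert, len(candidates))
            if n_insert:
                picks = rng.choice(len(candidates), size=n_insert, replace=False)
                next_t = _max_id_index(gold.entities) + 1
                etype_pool = schema.entity_types
                for idx in sorted(int(i) for i in picks):
                    start, end = candidates[idx]
                    tid = f"T{next_t}"
                    next_t += 1
                    entities[tid] = EntityMention(
                        id=tid, type=_choice(rng, etype_pool),
                        span=TextSpan(((start, end),)),
                        surface=gold.text[start:end],
                    )

    # attribute omission
    if p.p_attr_drop > 0:
        for aid in list(attributes):
            if rng.random() < p.p_attr_drop:
                del attributes[aid]

    # relation retargeting to another schema-compatible entity
    if p.p_rel_retarget > 0:
        for rid, r in list(relations.items()):
            if rng.random() >= p.p_rel_retarget:
                continue
            name = schema.resolve(r.type).label
            if name not in schema.relation_types or r.source not in entities:
                continue
            src_type = schema.resolve(entities[r.source].type).label
            allowed_targets = {
                tgt for src, tgt in schema.relation_types[name] if src == src_type
            }
            candidates = sorted(
                eid for eid, ent in entities.items()
                if eid != r.target and eid not in trigger_ids
                and schema.resolve(ent.type).label in allowed_targets
            )
            if candidates:
                relations[rid] = replace(r, target=_choice(rng, candidates))

    out = AnnotatedDocument(
        doc_id=gold.doc_id, text=gold.text,
        entities=entities, events=events,
        relations=relations, attributes=attributes,
        notes=list(gold.notes),
    )
    out.check_integrity()
    return out


def expected_scores(p: PerturbationConfig) -> dict[str, tuple[float, float, float]]:
    """Closed-form expected (precision, recall, F1) per layer.

    Valid only for the deletion/insertion model (``p_boundary``,
    ``p_relabel`` and ``p_rel_retarget`` all zero); refuses otherwise, since
    no closed form is claimed for the span-editing operators.  Entity
    recall is the survival rate ``1 - p_delete``; entity precision divides
    survivors by survivors plus expected insertions.  Events survive whole;
    a relation needs both endpoints to survive; an attribute needs its host
    event to survive and itself to be kept.
    """
    p.validate()
    if p.p_boundary or p.p_relabel or p.p_rel_retarget:
        raise ConfigError(
            "expected_scores has a closed form only when p_boundary, "
            "p_relabel and p_rel_retarget are all zero"
        )
    survive = 1.0 - p.p_delete

    def prf(precision: float, recall: float) -> tuple[float, float, float]:
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        return precision, recall, f1

    denom = survive + p.p_insert
    ent_precision = survive / denom if denom else 1.0
    return {
        "entities": prf(ent_precision, survive),
        "events": prf(1.0, survive),
        "relations": prf(1.0, survive ** 2),
        "attributes": prf(1.0, survive * (1.0 - p.p_attr_drop)),
    }


# --------------------------------------------------------------------------
# stratified systematic sampling

def stratified_sample(reports: Sequence, interval: int, seed: int = 0) -> list:
    """Systematic sampling within harm strata: one report per ``interval``.

    ``reports`` is a sequence of ``(item, harm_level)`` pairs (as returned
    by :func:`generate_corpus`) or of objects with a ``harm_level``
    attribute.  Items are partitioned by harm level (strata ordered by first
    appearance), shuffled once under ``seed`` to randomise the listing, and
    every ``interval``-th report of each stratum is selected — so a stratum
    of size ``n`` contributes ``floor(n / interval)`` reports.
    """
    if interval < 1:
        raise ConfigError("interval must be >= 1")
    strata: dict[str, list] = {}
    for item in reports:
        harm = item[1] if isinstance(item, tuple) else item.harm_level
        strata.setdefault(harm, []).append(item)
    rng = np.random.default_rng(seed)
    selected: list = []
    for items in strata.values():
        order = rng.permutation(len(items))
        shuffled = [items[int(i)] for i in order]
        selected.extend(shuffled[interval - 1::interval])
    return selected
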