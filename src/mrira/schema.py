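"""The annotation type system and document validator.

The scheme is a declarative registry of entity types (general,
patient-specific and domain-specific), main and supplementary event types,
event attributes, argument roles and typed directional relations with
endpoint constraints (e.g. 'has dose' may only link a 'Drug name' to a
'Drug dose').  The bundled default — 16 entity types, 11 event types,
5 attributes, 6 roles, 9 relation types — ships as a YAML file so other
schemes can be plugged in.

Label variants that occur in practice ('Dosage form' vs 'Drug form') are
resolved through an alias table before any validation or scoring decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import yaml

from .errors import ConfigError
from .standoff import AnnotatedDocument, AttributeMention, EntityMention

__all__ = [
    "MRIRASchema",
    "Violation",
    "ResolvedLabel",
    "build_default_schema",
    "resolve_type_alias",
    "validate_document",
    "normalize_document",
]

#: the four mutually exclusive intent/actuality attributes
INTENT_ATTRIBUTES = (
    "Action intended and actual",
    "Action not intended but actual",
    "Action intended but not actual",
    "Action intent not clear",
)

#: attribute names under which a *valued* intent/actuality record may arrive,
#: to be folded into the binary form by :func:`normalize_document`
_VALUED_INTENT_NAMES = {"intent", "intent and actuality", "actuality"}


class ResolvedLabel(NamedTuple):
    label: str
    known: bool


@dataclass(frozen=True)
class Violation:
    """One breach of the scheme, reported (never raised) by the validator."""

    doc_id: str
    annotation_id: str
    code: str  # one of VIOLATION_CODES
    message: str


#: closed set of rule codes the validator can emit
VIOLATION_CODES = frozenset({
    "unknown-entity-type",
    "unknown-event-type",
    "unknown-attribute",
    "unknown-role",
    "unknown-relation",
    "relation-endpoint",
    "attribute-host",
    "trigger-type-mismatch",
    "intent-conflict",
})


@dataclass(frozen=True)
class MRIRASchema:
    """Immutable registry of annotation types with endpoint constraints."""

    name: str
    entity_groups: dict[str, tuple[str, ...]]   # group tag -> entity type names
    event_groups: dict[str, tuple[str, ...]]    # 'main'/'supplementary' -> names
    attribute_names: tuple[str, ...]
    argument_roles: tuple[str, ...]
    relation_types: dict[str, tuple[tuple[str, str], ...]]  # name -> allowed (src, tgt)
    aliases: dict[str, str] = field(default_factory=dict)
    optional_link_types: tuple[str, ...] = ()   # enabled event-to-event links

    # -- derived views ------------------------------------------------------

    @property
    def entity_types(self) -> tuple[str, ...]:
        return tuple(t for group in self.entity_groups.values() for t in group)

    @property
    def event_types(self) -> tuple[str, ...]:
        return tuple(t for group in self.event_groups.values() for t in group)

    @property
    def main_event_types(self) -> tuple[str, ...]:
        return self.event_groups.get("main", ())

    @property
    def supplementary_event_types(self) -> tuple[str, ...]:
        return self.event_groups.get("supplementary", ())

    def entity_group(self, entity_type: str) -> str | None:
        for group, members in self.entity_groups.items():
            if entity_type in members:
                return group
        return None

    # -- alias resolution ---------------------------------------------------

    def resolve(self, label: str) -> ResolvedLabel:
        """Resolve a label to its canonical spelling.

        Resolution order: exact canonical, exact alias, then a normalised
        comparison (case-folded, underscores treated as spaces) against both.
        Unknown labels come back unchanged with ``known=False``.
        """
        known = (
            set(self.entity_types) | set(self.event_types)
            | set(self.attribute_names) | set(self.argument_roles)
            | set(self.relation_types) | set(self.optional_link_types)
        )
        if label in known:
            return ResolvedLabel(label, True)
        if label in self.aliases:
            return ResolvedLabel(self.aliases[label], True)
        folded = label.replace("_", " ").casefold().strip()
        for canonical in known:
            if canonical.casefold() == folded:
                return ResolvedLabel(canonical, True)
        for variant, canonical in self.aliases.items():
            if variant.casefold() == folded:
                return ResolvedLabel(canonical, True)
        return ResolvedLabel(label, False)

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def from_config(cls, config: dict) -> "MRIRASchema":
        try:
            entity_groups = {
                group: tuple(names) for group, names in config["entity_types"].items()
            }
            event_groups = {
                group: tuple(names) for group, names in config["event_types"].items()
            }
            relations = {
                name: tuple((src, tgt) for src, tgt in pairs)
                for name, pairs in config["relation_types"].items()
            }
            schema = cls(
                name=config.get("name", "custom"),
                entity_groups=entity_groups,
                event_groups=event_groups,
                attribute_names=tuple(config["attribute_names"]),
                argument_roles=tuple(config["argument_roles"]),
                relation_types=relations,
                aliases=dict(config.get("aliases", {})),
                optional_link_types=tuple(
                    name
                    for name, spec in config.get("optional_link_types", {}).items()
                    if spec.get("enabled", False)
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed schema configuration: {exc}") from exc
        for name, pairs in schema.relation_types.items():
            if not pairs:
                raise ConfigError(f"relation {name!r} needs >=1 endpoint pair")
        return schema

    @classmethod
    def from_yaml(cls, path) -> "MRIRASchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_config(yaml.safe_load(fh))

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "entity_types": {g: list(m) for g, m in self.entity_groups.items()},
            "event_types": {g: list(m) for g, m in self.event_groups.items()},
            "attribute_names": list(self.attribute_names),
            "argument_roles": list(self.argument_roles),
            "relation_types": {
                name: [list(pair) for pair in pairs]
                for name, pairs in self.relation_types.items()
            },
            "optional_link_types": {
                name: {"enabled": True} for name in self.optional_link_types
            },
            "aliases": dict(self.aliases),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_config(), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )


def build_default_schema(enable_mismatch: bool = False) -> MRIRASchema:
    """Load the bundled default registry.

    ``enable_mismatch=True`` additionally allows an event-to-event 'Mismatch'
    link; this does not change any of the headline inventory counts.
    """
    with resources.files("mrira.data").joinpath("mrira_schema.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        config = yaml.safe_load(fh)
    if enable_mismatch:
        config.setdefault("optional_link_types", {}).setdefault("Mismatch", {})[
            "enabled"
        ] = True
    return MRIRASchema.from_config(config)


def resolve_type_alias(schema: MRIRASchema, label: str) -> ResolvedLabel:
    """Functional form of :meth:`MRIRASchema.resolve`."""
    return schema.resolve(label)


# --------------------------------------------------------------------------
# validation

def validate_document(schema: MRIRASchema, doc: AnnotatedDocument) -> list[Violation]:
    """Check a structurally sound document against the scheme.

    Returns one :class:`Violation` per breach; an empty list means the
    document conforms.  Never raises on structurally sound input.
    """
    out: list[Violation] = []

    def add(annotation_id: str, code: str, message: str) -> None:
        assert code in VIOLATION_CODES
        out.append(Violation(doc.doc_id, annotation_id, code, message))

    triggers = doc.trigger_ids()
    entity_like = set(schema.entity_types)
    event_like = set(schema.event_types)

    def mention_type(ann_id: str) -> str | None:
        """Resolved type of a T or E annotation, None if it cannot resolve."""
        if ann_id in doc.entities:
            return schema.resolve(doc.entities[ann_id].type).label
        if ann_id in doc.events:
            return schema.resolve(doc.events[ann_id].type).label
        return None

    for ent in doc.entities.values():
        label, known = schema.resolve(ent.type)
        if not known:
            add(ent.id, "unknown-entity-type", f"unknown type {ent.type!r}")
        elif label not in entity_like and label not in event_like:
            # attribute/role/relation name used as a mention type
            add(ent.id, "unknown-entity-type",
                f"{label!r} is not an entity or event-trigger type")
        elif label in event_like and ent.id not in triggers:
            # a trigger-typed mention must actually anchor an event
            add(ent.id, "unknown-entity-type",
                f"event type {label!r} used on a mention that triggers no event")

    for ev in doc.events.values():
        label, known = schema.resolve(ev.type)
        if not known or label not in event_like:
            add(ev.id, "unknown-event-type", f"unknown event type {ev.type!r}")
        trig_label = schema.resolve(doc.entities[ev.trigger].type).label
        if known and label in event_like and trig_label != label:
            add(ev.id, "trigger-type-mismatch",
                f"trigger {ev.trigger} is {trig_label!r}, event is {label!r}")
        for role, _filler in ev.arguments:
            rlabel, rknown = schema.resolve(role)
            if not rknown or rlabel not in schema.argument_roles:
                add(ev.id, "unknown-role", f"unknown argument role {role!r}")

    for rel in doc.relations.values():
        label, known = schema.resolve(rel.type)
        if label in schema.optional_link_types:
            continue  # event-to-event link outside the entity-relation registry
        if not known or label not in schema.relation_types:
            add(rel.id, "unknown-relation", f"unknown relation type {rel.type!r}")
            continue
        src_type = mention_type(rel.source)
        tgt_type = mention_type(rel.target)
        if (src_type, tgt_type) not in schema.relation_types[label]:
            allowed = ", ".join(
                f"{s} -> {t}" for s, t in schema.relation_types[label]
            )
            add(rel.id, "relation-endpoint",
                f"{label!r} does not allow {src_type!r} -> {tgt_type!r} "
                f"(allowed: {allowed})")

    intent_set = set(INTENT_ATTRIBUTES)
    intents_per_event: dict[str, list[str]] = {}
    for attr in doc.attributes.values():
        name, known = schema.resolve(attr.name)
        valued_intent = (
            attr.value is not None
            and attr.name.replace("_", " ").casefold() in _VALUED_INTENT_NAMES
            and schema.resolve(attr.value).label in intent_set
        )
        if not known and not valued_intent:
            add(attr.id, "unknown-attribute", f"unknown attribute {attr.name!r}")
        if attr.host not in doc.events:
            add(attr.id, "attribute-host",
                f"attribute hosted on {attr.host}, which is not an event")
        effective = schema.resolve(attr.value).label if valued_intent else name
        if effective in intent_set:
            intents_per_event.setdefault(attr.host, []).append(attr.id)
    for host, attr_ids in intents_per_event.items():
        if len(attr_ids) > 1:
            for aid in attr_ids[1:]:
                add(aid, "intent-conflict",
                    f"event {host} carries more than one intent/actuality attribute")

    return out


# --------------------------------------------------------------------------
# normalization

def normalize_document(schema: MRIRASchema, doc: AnnotatedDocument) -> AnnotatedDocument:
    """Return a copy with every label rewritten to its canonical spelling.

    Also folds valued intent/actuality attributes (``Intent E1 <label>``)
    into the binary form the scheme prescribes (name = the label, no value).
    Unknown labels pass through unchanged.
    """
    entities = {
        e.id: replace(e, type=schema.resolve(e.type).label)
        for e in doc.entities.values()
    }
    events = {
        ev.id: replace(
            ev,
            type=schema.resolve(ev.type).label,
            arguments=tuple(
                (schema.resolve(role).label, filler) for role, filler in ev.arguments
            ),
        )
        for ev in doc.events.values()
    }
    relations = {
        r.id: replace(r, type=schema.resolve(r.type).label)
        for r in doc.relations.values()
    }
    attributes: dict[str, AttributeMention] = {}
    for attr in doc.attributes.values():
        name = schema.resolve(attr.name).label
        value = schema.resolve(attr.value).label if attr.value is not None else None
        if (
            value is not None
            and attr.name.replace("_", " ").casefold() in _VALUED_INTENT_NAMES
            and value in INTENT_ATTRIBUTES
        ):
            name, value = value, None
        attributes[attr.id] = replace(attr, name=name, value=value)
    return AnnotatedDocument(
        doc_id=doc.doc_id,
        text=doc.text,
        entities=entities,
        events=events,
        relations=relations,
        attributes=attributes,
        notes=list(doc.notes),
    )
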