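"""Corpus summary statistics.

Summarises an annotated corpus per annotation type: number of annotations,
average words per annotation (exact, and rounded as printed summaries
usually are) and total words across annotations of that type, grouped by
the schema's category headings.  Argument roles and attributes are counted
only (they are not text-bound).  Words are whitespace-delimited tokens of
the covered surface text, so hyphenated tokens count as one word.

Interpretation note: the "total words" column is the summed word count over
annotations of the type; this assumption is stated in the rendered output
footer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .schema import MRIRASchema, build_default_schema
from .standoff import AnnotatedDocument

__all__ = ["CorpusStatistics", "summarize_corpus"]

_FOOTER = (
    "Words are whitespace-delimited tokens of the covered text; 'total_words' "
    "is the summed word count over annotations of the type."
)


def _word_count(surface: str) -> int:
    return len(surface.split())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CorpusStatistics:
    """Per-type counts and word statistics for an annotated corpus."""

    entity_table: pd.DataFrame   # group, type, n_annotations, avg_words, avg_words_rounded, total_words
    event_table: pd.DataFrame
    role_counts: dict[str, int]
    attribute_counts: dict[str, int]
    n_documents: int

    @property
    def total_entity_annotations(self) -> int:
        return int(self.entity_table["n_annotations"].sum())

    @property
    def total_event_annotations(self) -> int:
        return int(self.event_table["n_annotations"].sum())

    def to_frame(self) -> pd.DataFrame:
        """One long table over all annotation levels (counts-only rows get
        empty word columns)."""
        ent = self.entity_table.assign(level="Entities")
        ev = self.event_table.assign(level="Events")
        roles = pd.DataFrame(
            {"group": "", "type": list(self.role_counts),
             "n_annotations": list(self.role_counts.values()),
             "avg_words": float("nan"), "avg_words_rounded": pd.NA,
             "total_words": pd.NA, "level": "Event arguments"}
        )
        attrs = pd.DataFrame(
            {"group": "", "type": list(self.attribute_counts),
             "n_annotations": list(self.attribute_counts.values()),
             "avg_words": float("nan"), "avg_words_rounded": pd.NA,
             "total_words": pd.NA, "level": "Event attributes"}
        )
        cols = ["level", "group", "type", "n_annotations",
                "avg_words", "avg_words_rounded", "total_words"]
        return pd.concat([ent, ev, roles, attrs], ignore_index=True)[cols]

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, index=False)
            fh.write(f"# {_FOOTER}\n")

    def to_markdown(self) -> str:
        frame = self.to_frame()
        lines = ["| Level | Group | Type | Annotations | Avg words | Total words |",
                 "| --- | --- | --- | --- | --- | --- |"]
        for _, row in frame.iterrows():
            if pd.isna(row["avg_words"]):
                avg = total = ""
            else:
                avg = f"{row['avg_words']:.2f} ({row['avg_words_rounded']})"
                total = str(row["total_words"])
            lines.append(
                f"| {row['level']} | {row['group']} | {row['type']} "
                f"| {row['n_annotations']} | {avg} | {total} |"
            )
        lines += ["", _FOOTER]
        return "\n".join(lines)


def summarize_corpus(
    docs: Iterable[AnnotatedDocument] | Mapping[str, AnnotatedDocument],
    schema: MRIRASchema | None = None,
) -> CorpusStatistics:
    """Summarise a corpus per annotation type.

    Types are alias-resolved against the schema; every schema type appears
    in the output even with zero instances.  Unknown types encountered in
    the corpus are appended under the group ``"(unknown)"``.
    """
    if schema is None:
        schema = build_default_schema()
    if isinstance(docs, Mapping):
        docs = list(docs.values())
    else:
        docs = list(docs)

    ent_counts: dict[str, int] = {t: 0 for t in schema.entity_types}
    ent_words: dict[str, int] = {t: 0 for t in schema.entity_types}
    ev_counts: dict[str, int] = {t: 0 for t in schema.event_types}
    ev_words: dict[str, int] = {t: 0 for t in schema.event_types}
    role_counts: dict[str, int] = {r: 0 for r in schema.argument_roles}
    attr_counts: dict[str, int] = {a: 0 for a in schema.attribute_names}

    for doc in docs:
        for ent in doc.non_trigger_entities():
            label = schema.resolve(ent.type).label
            ent_counts[label] = ent_counts.get(label, 0) + 1
            ent_words[label] = ent_words.get(label, 0) + _word_count(ent.surface)
        for ev in doc.events.values():
            label = schema.resolve(ev.type).label
            surface = doc.entities[ev.trigger].surface
            ev_counts[label] = ev_counts.get(label, 0) + 1
            ev_words[label] = ev_words.get(label, 0) + _word_count(surface)
            for role, _filler in ev.arguments:
                rlabel = schema.resolve(role).label
                role_counts[rlabel] = role_counts.get(rlabel, 0) + 1
        for attr in doc.attributes.values():
            alabel = schema.resolve(attr.name).label
            attr_counts[alabel] = attr_counts.get(alabel, 0) + 1

    def build_table(counts, words, group_of) -> pd.DataFrame:
        rows = []
        for type_name, n in counts.items():
            total = words.get(type_name, 0)
            avg = total / n if n else 0.0
            rows.append({
                "group": group_of(type_name),
                "type": type_name,
                "n_annotations": n,
                "avg_words": avg,
                "avg_words_rounded": _round_half_up(avg),
                "total_words": total,
            })
        return pd.DataFrame(rows)

    def entity_group(t: str) -> str:
        return schema.entity_group(t) or "(unknown)"

    def event_group(t: str) -> str:
        if t in schema.main_event_types:
            return "main"
        if t in schema.supplementary_event_types:
            return "supplementary"
        return "(unknown)"

    return CorpusStatistics(
        entity_table=build_table(ent_counts, ent_words, entity_group),
        event_table=build_table(ev_counts, ev_words, event_group),
        role_counts=role_counts,
        attribute_counts=attr_counts,
        n_documents=len(docs),
    )
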