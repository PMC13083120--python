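"""One-to-one correspondence between two annotators' annotations.

Two matching criteria are supported: *strict* (identical fragment list and
identical label) and *relaxed* (identical label, spans overlapping by at
least one character).  Given the admissible pairs under a criterion, the
aligner solves an assignment problem for a maximum-cardinality one-to-one
matching; among maximum matchings it prefers the largest total character
overlap, with a deterministic tie-break toward earlier reference items.
Maximum (rather than greedy first-come) matching is used because greedy
pairing undercounts agreement on crossing overlaps.

A brute-force enumerator over all one-to-one matchings is provided as an
independent oracle for small instances (used by the test suite only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import MriraError
from .standoff import EntityMention, TextSpan

__all__ = [
    "MatchCriterion",
    "Correspondence",
    "span_match",
    "align_annotations",
    "brute_force_align",
]

MatchCriterion = Literal["strict", "relaxed"]
_CRITERIA = ("strict", "relaxed")


def _check_criterion(criterion: str) -> None:
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")


def span_match(a: EntityMention, b: EntityMention, criterion: MatchCriterion) -> bool:
    """Do two typed spans agree under the given criterion?

    Strict: identical fragment lists and equal types.  Relaxed: equal types
    and any fragment of ``a`` overlapping any fragment of ``b`` by >=1
    character.  Types are compared as given (alias-resolve first).
    """
    _check_criterion(criterion)
    if a.type != b.type:
        return False
    if criterion == "strict":
        return a.span.fragments == b.span.fragments
    return a.span.overlap(b.span) > 0


@dataclass(frozen=True)
class Correspondence:
    """A one-to-one pairing: matched (reference id, response id) pairs plus
    the ids left unmatched on each side."""

    pairs: tuple[tuple[str, str], ...]
    unmatched_reference: tuple[str, ...]
    unmatched_response: tuple[str, ...]

    @property
    def mapping(self) -> dict[str, str]:
        """reference id -> response id over the matched pairs."""
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _default_predicate(criterion: MatchCriterion) -> Callable:
    return lambda a, b: span_match(a, b, criterion)


def _default_overlap(a, b) -> int:
    span_a = getattr(a, "span", None)
    span_b = getattr(b, "span", None)
    if isinstance(span_a, TextSpan) and isinstance(span_b, TextSpan):
        return span_a.overlap(span_b)
    return 0


def _admissibility(reference, response, predicate, overlap):
    n, m = len(reference), len(response)
    adm = np.zeros((n, m), dtype=bool)
    ov = np.zeros((n, m), dtype=float)
    for i, r in enumerate(reference):
        for j, s in enumerate(response):
            if predicate(r, s):
                adm[i, j] = True
                ov[i, j] = overlap(r, s)
    return adm, ov


def _finish(reference, response, chosen: list[tuple[int, int]]) -> Correspondence:
    ref_ids = [a.id for a in reference]
    resp_ids = [a.id for a in response]
    matched_i = {i for i, _ in chosen}
    matched_j = {j for _, j in chosen}
    return Correspondence(
        pairs=tuple((ref_ids[i], resp_ids[j]) for i, j in sorted(chosen)),
        unmatched_reference=tuple(
            rid for i, rid in enumerate(ref_ids) if i not in matched_i
        ),
        unmatched_response=tuple(
            sid for j, sid in enumerate(resp_ids) if j not in matched_j
        ),
    )


def align_annotations(
    reference: Sequence,
    response: Sequence,
    criterion: MatchCriterion | None = None,
    *,
    predicate: Callable | None = None,
    overlap: Callable | None = None,
) -> Correspondence:
    """Maximum-cardinality one-to-one matching over the admissible pairs.

    Items need an ``.id``.  With ``criterion`` given and no explicit
    ``predicate``, items are treated as typed spans and matched with
    :func:`span_match`; composite layers (relations, attributes) pass their
    own ``predicate``.  The secondary objective maximises total character
    overlap; remaining ties break deterministically toward earlier
    reference/response list positions, so sort span layers by start offset
    for the earliest-start preference.
    """
    if predicate is None:
        if criterion is None:
            raise ValueError("either a criterion or an explicit predicate is required")
        predicate = _default_predicate(criterion)
    if overlap is None:
        overlap = _default_overlap

    if not reference or not response:
        return _finish(reference, response, [])

    adm, ov = _admissibility(reference, response, predicate, overlap)
    if not adm.any():
        return _finish(reference, response, [])

    n, m = adm.shape
    # cardinality dominates total overlap, which dominates the positional tie-break
    card_weight = ov.sum() + 1.0
    pos = np.add.outer(np.arange(n), np.arange(m)).astype(float)
    tie = (pos.max() + 1.0 - pos) / ((pos.max() + 1.0) * (min(n, m) + 1.0))  # < 1 total
    weights = np.where(adm, card_weight + ov + tie, 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    chosen = [(i, j) for i, j in zip(rows, cols) if adm[i, j]]
    return _finish(reference, response, chosen)


def brute_force_align(
    reference: Sequence,
    response: Sequence,
    criterion: MatchCriterion | None = None,
    *,
    predicate: Callable | None = None,
    overlap: Callable | None = None,
) -> Correspondence:
    """Exhaustive optimum over all one-to-one matchings (test oracle).

    Same objective as :func:`align_annotations`; refuses instances with more
    than 12 annotations in total.
    """
    if len(reference) + len(response) > 12:
        raise MriraError("brute-force aligner refuses instances with > 12 annotations")
    if predicate is None:
        if criterion is None:
            raise ValueError("either a criterion or an explicit predicate is required")
        predicate = _default_predicate(criterion)
    if overlap is None:
        overlap = _default_overlap

    adm, ov = _admissibility(reference, response, predicate, overlap)
    n, m = (len(reference), len(response))

    best: tuple[int, float, list[tuple[int, int]]] = (0, 0.0, [])

    def recurse(i: int, used: set[int], chosen: list[tuple[int, int]], total: float):
        nonlocal best
        if i == n:
            key = (len(chosen), total)
            if key > (best[0], best[1]):
                best = (len(chosen), total, list(chosen))
            return
        recurse(i + 1, used, chosen, total)  # leave reference item i unmatched
        for j in range(m):
            if j not in used and adm[i, j]:
                chosen.append((i, j))
                used.add(j)
                recurse(i + 1, used, chosen, total + ov[i, j])
                used.discard(j)
                chosen.pop()

    recurse(0, set(), [], 0.0)
    return _finish(reference, response, best[2])
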