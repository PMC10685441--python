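"""Supervised curation of training phrases.

Training enumerates every candidate relation a sentence supports (one
tagged entity per required slot, spans pairwise disjoint) and asks the
annotator to confirm the correct ones.  Sentences in the natural-science
literature usually admit only a handful of candidates, so this is a single
multiple-choice question (*relationship-based* mode); when the candidate
count exceeds a threshold the session switches to *entity-based* mode,
where relations are assembled slot by slot as a series of single-choice
questions instead.  Confirmed relations become phrases with confidence 1.0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from .errors import AnnotationError
from .schema import (
    COMPOUND,
    EntityTag,
    Phrase,
    PropertySchema,
    Relation,
    TaggedSentence,
    WeightConfig,
    decompose,
)

__all__ = [
    "AnnotationSession",
    "active_slots",
    "enumerate_candidates",
    "annotate_relationship",
    "annotate_entitywise",
]

RELATIONSHIP_BASED = "relationship_based"
ENTITY_BASED = "entity_based"

#: Candidate count above which annotation switches to entity-based mode.
DEFAULT_ENTITY_MODE_THRESHOLD = 100


def _slot_pool(
    sentence: TaggedSentence, path: tuple[str, ...], kind: str
) -> list[EntityTag]:
    if kind == COMPOUND:
        pool = [e for e in sentence.entities if e.category == COMPOUND]
    else:
        pool = [
            e
            for e in sentence.entities
            if e.category == kind and e.property_path == path
        ]
    return sorted(pool, key=lambda e: e.span)


def active_slots(
    sentence: TaggedSentence, schema: PropertySchema
) -> list[tuple[tuple[str, ...], str]]:
    """Required slots of the property models a sentence can instantiate.

    The root model is always required; a nested model participates only
    when the sentence carries at least one tagged entity for each of its
    required slots (and its parent participates).  Entities of excluded
    models are left untouched.
    """
    included: set[tuple[str, ...]] = set()
    for model, path in schema.walk():
        parent_ok = len(path) == 1 or path[:-1] in included
        has_all = all(
            _slot_pool(sentence, path, kind) for kind in model.required_slots
        )
        if len(path) == 1 or (parent_ok and has_all):
            included.add(path)
    slots: list[tuple[tuple[str, ...], str]] = [((), COMPOUND)]
    for model, path in schema.walk():
        if path in included:
            slots.extend((path, kind) for kind in model.required_slots)
    return slots


def enumerate_candidates(
    sentence: TaggedSentence, schema: PropertySchema
) -> list[Relation]:
    """All relations assigning one tagged entity to each required slot.

    Candidates are the cross product of the per-slot entity pools with
    relations containing overlapping entities discarded, ordered
    lexicographically by the span starts of their slot entities.  A
    required slot with no tagged entity yields an empty list.
    """
    slots = active_slots(sentence, schema)
    pools = [_slot_pool(sentence, path, kind) for path, kind in slots]
    if any(not pool for pool in pools):
        return []
    candidates: list[Relation] = []
    for combo in itertools.product(*pools):
        ok = True
        for i, a in enumerate(combo):
            for b in combo[i + 1:]:
                if a.overlaps(b):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            candidates.append(
                Relation(dict(zip(slots, combo)), confidence=1.0)
            )
    candidates.sort(key=lambda r: r.span_signature())
    return candidates


@dataclass
class AnnotationSession:
    """One sentence's annotation state.

    The mode is entity-based exactly when the candidate count exceeds the
    threshold; the threshold is user-adjustable.
    """

    sentence: TaggedSentence
    schema: PropertySchema
    threshold: int = DEFAULT_ENTITY_MODE_THRESHOLD
    candidates: list[Relation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.candidates:
            self.candidates = enumerate_candidates(self.sentence, self.schema)

    @property
    def mode(self) -> str:
        if len(self.candidates) > self.threshold:
            return ENTITY_BASED
        return RELATIONSHIP_BASED


def _to_phrases(
    session: AnnotationSession,
    relations: Sequence[Relation],
    max_prefix_len: int,
    max_suffix_len: int,
    weights: WeightConfig | None,
    pooled_middles: bool,
) -> list[Phrase]:
    compounds = [r.compound for r in relations]
    if len({c.span for c in compounds}) != len(compounds):
        raise AnnotationError(
            "each compound can carry only one relation per sentence"
        )
    return [
        decompose(
            session.sentence,
            rel,
            max_prefix_len=max_prefix_len,
            max_suffix_len=max_suffix_len,
            weights=weights,
            confidence=1.0,
            pooled_middles=pooled_middles,
        )
        for rel in relations
    ]


def annotate_relationship(
    session: AnnotationSession,
    chosen: Sequence[int],
    *,
    max_prefix_len: int = 3,
    max_suffix_len: int = 3,
    weights: WeightConfig | None = None,
    pooled_middles: bool = False,
) -> list[Phrase]:
    """Confirm candidate relations by index; returns confidence-1.0 phrases.

    An empty selection marks the sentence as a labeled negative and yields
    no phrases.
    """
    if session.mode != RELATIONSHIP_BASED:
        raise AnnotationError(
            f"session with {len(session.candidates)} candidates is in "
            "entity-based mode; use annotate_entitywise"
        )
    relations = []
    for idx in chosen:
        if not (0 <= idx < len(session.candidates)):
            raise AnnotationError(
                f"candidate index {idx} out of range "
                f"(0..{len(session.candidates) - 1})"
            )
        relations.append(session.candidates[idx])
    return _to_phrases(
        session, relations, max_prefix_len, max_suffix_len, weights,
        pooled_middles,
    )


def annotate_entitywise(
    session: AnnotationSession,
    picks: Sequence[tuple[tuple[tuple[str, ...], str], EntityTag]],
    *,
    max_prefix_len: int = 3,
    max_suffix_len: int = 3,
    weights: WeightConfig | None = None,
    pooled_middles: bool = False,
) -> list[Phrase]:
    """Assemble relations one slot at a time from ``(slot, entity)`` picks.

    Slots are asked in schema order — compound first, then each property
    model's required slots — and the cycle repeats until the pick sequence
    is exhausted, one relation per cycle.  Every picked entity must be
    tagged in the sentence under the picked slot.
    """
    if session.mode != ENTITY_BASED:
        raise AnnotationError(
            f"session with {len(session.candidates)} candidates is in "
            "relationship-based mode; use annotate_relationship"
        )
    slots = active_slots(session.sentence, session.schema)
    if len(picks) % len(slots) != 0:
        raise AnnotationError(
            f"pick count {len(picks)} is not a multiple of the "
            f"{len(slots)} slots per relation"
        )
    relations: list[Relation] = []
    for start in range(0, len(picks), len(slots)):
        assignment: dict[tuple[tuple[str, ...], str], EntityTag] = {}
        for expected, (slot, entity) in zip(slots, picks[start:start + len(slots)]):
            if slot != expected:
                raise AnnotationError(
                    f"expected a pick for slot {expected}, got {slot}"
                )
            path, kind = slot
            if entity not in _slot_pool(session.sentence, path, kind):
                raise AnnotationError(
                    f"entity {entity.surface} is not tagged for slot {slot}"
                )
            assignment[slot] = entity
        relations.append(Relation(assignment, confidence=1.0))
    return _to_phrases(
        session, relations, max_prefix_len, max_suffix_len, weights,
        pooled_middles,
    )
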