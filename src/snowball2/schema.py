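"""Domain types for property-annotated sentences and their phrase form.

A *property model* (:class:`PropertySchema`) names a physical property and
the slot kinds a complete record of it requires (specifier, value, unit),
optionally with nested sub-models.  A complete chemical record over ``n``
property models therefore carries ``3n + 1`` entities: one
specifier/value/unit triple per model plus a single shared compound.

A tagged sentence is a token list with labeled candidate entities.  Choosing
one entity per slot yields a :class:`Relation`; decomposing the sentence
around the relation's span-ordered entities yields a :class:`Phrase` — the
unit of both training and extraction — whose non-entity token runs form the
*elements*: a prefix, one middle per gap between consecutive entities, and a
suffix, each carrying an importance weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

from .errors import InvalidInputError, InvalidRelationError

__all__ = [
    "SLOT_KINDS",
    "COMPOUND",
    "PropertySchema",
    "EntityTag",
    "TaggedSentence",
    "Relation",
    "Phrase",
    "WeightConfig",
    "decompose",
    "entity_count",
]

#: Slot kinds a property model may require, in canonical order.
SLOT_KINDS = ("specifier", "value", "unit")

#: Category label of the single compound entity shared at the record root.
COMPOUND = "compound_name"


@dataclass(frozen=True)
class PropertySchema:
    """A property model: required slot kinds plus nested sub-models.

    Parameters
    ----------
    name:
        Property name, e.g. ``"band_gap"``.  Used in output records and in
        entity ``property_path`` values, never in cluster comparison.
    required_slots:
        Ordered subset of :data:`SLOT_KINDS` a complete record must fill.
    nested:
        Child property models, each contributing its own slots.
    """

    name: str
    required_slots: tuple[str, ...] = SLOT_KINDS
    nested: tuple["PropertySchema", ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("property model needs a non-empty name")
        bad = [s for s in self.required_slots if s not in SLOT_KINDS]
        if bad:
            raise InvalidInputError(f"unknown slot kinds: {bad}")
        if len(set(self.required_slots)) != len(self.required_slots):
            raise InvalidInputError("duplicate slot kind in required_slots")
        # reject sharing of a model object between branches: the tree must
        # be a tree (acyclic by construction, but duplicates break paths)
        seen: set[int] = set()
        for model, _ in self.walk():
            if id(model) in seen:
                raise InvalidInputError("property-model tree reuses a node")
            seen.add(id(model))

    def walk(self) -> Iterator[tuple["PropertySchema", tuple[str, ...]]]:
        """Yield ``(model, property_path)`` in preorder, root first."""

        def _walk(model: PropertySchema, path: tuple[str, ...]):
            path = path + (model.name,)
            yield model, path
            for child in model.nested:
                yield from _walk(child, path)

        yield from _walk(self, ())

    def slot_list(self) -> list[tuple[tuple[str, ...], str]]:
        """All required ``(property_path, kind)`` slots, compound first."""
        slots: list[tuple[tuple[str, ...], str]] = [((), COMPOUND)]
        for model, path in self.walk():
            slots.extend((path, kind) for kind in model.required_slots)
        return slots

    @property
    def n_models(self) -> int:
        return sum(1 for _ in self.walk())


def entity_count(schema: PropertySchema) -> int:
    """Number of entities in one complete record under ``schema``.

    Equals ``3n + 1`` for ``n`` property models when every model requires
    the full specifier/value/unit triple; models declaring fewer required
    slots contribute correspondingly fewer entities.
    """
    return 1 + sum(len(m.required_slots) for m, _ in schema.walk())


@dataclass(frozen=True)
class EntityTag:
    """A labeled token span filling one relation slot.

    ``span`` is a 0-based half-open token interval.  ``property_path``
    locates the owning property model in the schema tree and is empty for
    the compound entity.
    """

    category: str
    span: tuple[int, int]
    surface: tuple[str, ...]
    property_path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in SLOT_KINDS + (COMPOUND,):
            raise InvalidInputError(f"unknown entity category {self.category!r}")
        if not (0 <= self.span[0] < self.span[1]):
            raise InvalidInputError(f"invalid span {self.span}")
        if self.category != COMPOUND and not self.property_path:
            raise InvalidInputError(
                f"{self.category} entity must carry a property_path"
            )

    def overlaps(self, other: "EntityTag") -> bool:
        return self.span[0] < other.span[1] and other.span[0] < self.span[1]


@dataclass(frozen=True)
class Relation:
    """One entity per required slot: a candidate or gold chemical record.

    ``slots`` maps ``(property_path, kind)`` to the chosen entity; the
    compound is keyed ``((), COMPOUND)``.  Slot entities must be pairwise
    disjoint in span.
    """

    slots: Mapping[tuple[tuple[str, ...], str], EntityTag]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        slots = dict(self.slots)
        object.__setattr__(self, "slots", slots)
        if ((), COMPOUND) not in slots:
            raise InvalidRelationError("relation lacks a compound slot")
        ents = list(slots.values())
        for i, a in enumerate(ents):
            for b in ents[i + 1:]:
                if a.overlaps(b):
                    raise InvalidRelationError(
                        f"slot entities overlap: {a.surface} / {b.surface}"
                    )
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidRelationError("confidence outside [0, 1]")

    @property
    def compound(self) -> EntityTag:
        return self.slots[((), COMPOUND)]

    def entities_in_order(self) -> tuple[EntityTag, ...]:
        return tuple(sorted(self.slots.values(), key=lambda e: e.span))

    def span_signature(self) -> tuple[int, ...]:
        """Span starts in canonical slot-key order; deterministic sorting."""
        return tuple(
            self.slots[k].span[0] for k in sorted(self.slots.keys())
        )

    def __hash__(self) -> int:
        return hash(frozenset(self.slots.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Relation):
            return NotImplemented
        return dict(self.slots) == dict(other.slots)


@dataclass(frozen=True)
class TaggedSentence:
    """A pre-tokenized sentence with labeled candidate entities.

    ``relations`` optionally carries gold-standard relations (used by the
    training and evaluation code); entities in the candidate pool may
    overlap one another, entities chosen into a single relation may not.
    """

    sentence_id: str
    tokens: tuple[str, ...]
    entities: tuple[EntityTag, ...] = ()
    relations: tuple[Relation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "entities", tuple(self.entities))
        object.__setattr__(self, "relations", tuple(self.relations))
        n = len(self.tokens)
        for e in self.entities:
            if e.span[1] > n:
                raise InvalidInputError(
                    f"entity span {e.span} exceeds sentence length {n} "
                    f"(sentence {self.sentence_id!r})"
                )
            if tuple(self.tokens[e.span[0]:e.span[1]]) != e.surface:
                raise InvalidInputError(
                    f"entity surface {e.surface} does not match tokens at "
                    f"{e.span} (sentence {self.sentence_id!r})"
                )


@dataclass(frozen=True)
class WeightConfig:
    """Importance mass for the prefix, the middles jointly, and the suffix.

    The three masses are normalized to sum one; the middle mass is split
    equally among the per-gap middle elements (or kept whole when middles
    are pooled into a single element).
    """

    prefix: float = 0.1
    middles: float = 0.8
    suffix: float = 0.1

    def __post_init__(self) -> None:
        if min(self.prefix, self.middles, self.suffix) < 0:
            raise InvalidInputError("element weights must be non-negative")
        if self.prefix + self.middles + self.suffix <= 0:
            raise InvalidInputError("element weights must not all be zero")

    def element_weights(self, n_middles: int) -> tuple[float, ...]:
        total = self.prefix + self.middles + self.suffix
        p, m, s = (self.prefix / total, self.middles / total, self.suffix / total)
        if n_middles == 0:
            # no gap between entities cannot occur (>=2 entities per
            # relation); guard for synthesized degenerate phrases
            rescale = p + s
            return (p / rescale, s / rescale) if rescale else (0.5, 0.5)
        return (p, *([m / n_middles] * n_middles), s)


@dataclass(frozen=True)
class Phrase:
    """A labeled sentence: span-ordered entities interleaved with elements.

    ``elements`` holds the prefix, the middles (one per gap, or one pooled)
    and the suffix as token tuples in original case; lowercasing happens in
    the vector space.  ``confidence`` is the probability the labeling is
    correct; phrases curated during supervised training carry 1.0.
    """

    sentence_id: str
    tokens: tuple[str, ...]
    relations: tuple[Relation, ...]
    entities_in_order: tuple[EntityTag, ...]
    elements: tuple[tuple[str, ...], ...]
    element_weights: tuple[float, ...]
    confidence: float = 1.0
    pooled_middles: bool = False

    def __post_init__(self) -> None:
        if not self.relations:
            raise InvalidRelationError("phrase needs at least one relation")
        if len(self.elements) != len(self.element_weights):
            raise InvalidInputError("one weight per element required")
        if abs(sum(self.element_weights) - 1.0) > 1e-9:
            raise InvalidInputError("element weights must sum to 1")
        if any(w < 0 for w in self.element_weights):
            raise InvalidInputError("element weights must be non-negative")
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidInputError("phrase confidence outside [0, 1]")

    @property
    def prefix(self) -> tuple[str, ...]:
        return self.elements[0]

    @property
    def middles(self) -> tuple[tuple[str, ...], ...]:
        return self.elements[1:-1]

    @property
    def suffix(self) -> tuple[str, ...]:
        return self.elements[-1]

    def with_confidence(self, confidence: float) -> "Phrase":
        return replace(self, confidence=confidence)

    def element_key(self) -> tuple[tuple[str, ...], ...]:
        """Lowercased elements; the identity used for modal selection and
        canonical ordering."""
        return tuple(tuple(t.lower() for t in el) for el in self.elements)

    def sort_key(self):
        """Content-based canonical ordering key (order-invariance anchor)."""
        return (
            self.element_key(),
            tuple(e.span for e in self.entities_in_order),
            tuple(e.surface for e in self.entities_in_order),
            self.sentence_id,
        )


def decompose(
    sentence: TaggedSentence,
    relation: Relation,
    max_prefix_len: int = 3,
    max_suffix_len: int = 3,
    weights: WeightConfig | None = None,
    confidence: float = 1.0,
    pooled_middles: bool = False,
) -> Phrase:
    """Split a sentence into a phrase around a relation's ordered entities.

    The prefix keeps at most ``max_prefix_len`` tokens adjacent to the first
    entity and the suffix at most ``max_suffix_len`` after the last; one
    middle element covers each gap between consecutive entities (or all
    gaps pooled into one element when ``pooled_middles``).

    Raises
    ------
    InvalidInputError
        Empty sentence.
    InvalidRelationError
        Overlapping slot entities or entities outside the sentence.
    """
    if not sentence.tokens:
        raise InvalidInputError("cannot decompose an empty sentence")
    weights = weights or WeightConfig()
    ents = relation.entities_in_order()
    if ents[-1].span[1] > len(sentence.tokens):
        raise InvalidRelationError("relation entities exceed sentence bounds")

    toks = sentence.tokens
    prefix = toks[max(0, ents[0].span[0] - max_prefix_len):ents[0].span[0]]
    middles = [
        toks[a.span[1]:b.span[0]] for a, b in zip(ents, ents[1:])
    ]
    last = ents[-1].span[1]
    suffix = toks[last:last + max_suffix_len]

    if pooled_middles:
        pooled = tuple(t for run in middles for t in run)
        middles = [pooled]
    element_weights = weights.element_weights(len(middles))
    elements = (tuple(prefix), *map(tuple, middles), tuple(suffix))
    return Phrase(
        sentence_id=sentence.sentence_id,
        tokens=sentence.tokens,
        relations=(relation,),
        entities_in_order=ents,
        elements=elements,
        element_weights=element_weights,
        confidence=confidence,
        pooled_middles=pooled_middles,
    )
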