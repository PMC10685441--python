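"""Shared fixtures: hand-built sentences and the three-phrase toy."""

from __future__ import annotations

import pytest

from snowball2.schema import (
    COMPOUND,
    EntityTag,
    PropertySchema,
    Relation,
    TaggedSentence,
    WeightConfig,
    decompose,
)


def make_sentence(sentence_id, tokens, tags):
    """Build a TaggedSentence from (category, span, property_path) tags."""
    tokens = tuple(tokens)
    entities = tuple(
        EntityTag(
            category=cat,
            span=(start, end),
            surface=tokens[start:end],
            property_path=tuple(path),
        )
        for cat, (start, end), path in tags
    )
    return TaggedSentence(sentence_id, tokens, entities)


def relation_from_entities(entities):
    """One slot per entity, keyed by its own (path, category)."""
    slots = {}
    for e in entities:
        kind = COMPOUND if e.category == COMPOUND else e.category
        slots[(e.property_path, kind)] = e
    return Relation(slots)


@pytest.fixture
def band_gap_schema():
    return PropertySchema("band_gap", ("specifier", "value", "unit"))


@pytest.fixture
def band_gap_sentence():
    """'The bulk TiO2 has a direct band gap of 3.2 eV at tau point .'"""
    tokens = "The bulk TiO2 has a direct band gap of 3.2 eV at tau point .".split()
    return make_sentence(
        "tbl1",
        tokens,
        [
            (COMPOUND, (2, 3), ()),
            ("specifier", (6, 8), ("band_gap",)),
            ("value", (9, 10), ("band_gap",)),
            ("unit", (10, 11), ("band_gap",)),
        ],
    )


@pytest.fixture
def band_gap_relation(band_gap_sentence):
    return relation_from_entities(band_gap_sentence.entities)


# --- the three-phrase similarity toy --------------------------------------
#
# Single-middle phrases over 100-token bags engineered so the pairwise
# weighted similarities are exactly 0.91 (A,B), 0.89 (B,C) and 0.80 (A,C):
# 80 tokens common to all three, 11 shared by A,B only, 9 shared by B,C
# only, and private remainders filling each bag to 100 tokens.

TOY_SCHEMA = PropertySchema("prop", ("value",))


def _toy_phrase(name: str, middle: list[str]):
    tokens = ["M" + name] + middle + ["7.7"]
    sent = TaggedSentence(name, tuple(tokens), ())
    comp = EntityTag(COMPOUND, (0, 1), (tokens[0],))
    val = EntityTag("value", (len(tokens) - 1, len(tokens)), ("7.7",), ("prop",))
    rel = Relation({((), COMPOUND): comp, (("prop",), "value"): val})
    return decompose(
        sent,
        rel,
        max_prefix_len=0,
        max_suffix_len=0,
        weights=WeightConfig(0.0, 1.0, 0.0),
    )


@pytest.fixture(scope="session")
def toy_phrases():
    common = [f"w{i}" for i in range(80)]
    ab = [f"x{i}" for i in range(11)]
    bc = [f"y{i}" for i in range(9)]
    return {
        "A": _toy_phrase("A", common + ab + [f"z{i}" for i in range(9)]),
        "B": _toy_phrase("B", common + ab + bc),
        "C": _toy_phrase("C", common + bc + [f"u{i}" for i in range(11)]),
    }
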