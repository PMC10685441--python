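"""Synthetic annotated corpus of property sentences.

The generator emulates the statistical structure of sentences reporting a
scalar material property (band-gap-like): weighted sentence skeletons with
slot placeholders in varying entity orders (so several pseudoclusters are
exercised), closed vocabulary pools for compounds, multi-token specifier
variants, values and units, optional nested-model sentences (a second
specifier/value/unit triple, temperature-like), optional two-compound
sentences, and untagged numeric distractor insertions.  Every sentence
carries gold relations consistent with its entities, and generation is
bit-reproducible for a fixed seed.

Values mimic structure only: root values are drawn uniformly from a
band-gap-like 0.1-10 range with one decimal, nested values are integer
temperatures; no physical claim is attached to either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .schema import (
    COMPOUND,
    EntityTag,
    PropertySchema,
    Relation,
    TaggedSentence,
)

__all__ = [
    "SynthConfig",
    "default_schema",
    "generate",
    "train_test_split",
    "DEFAULT_TEMPLATES",
    "PARAPHRASE_TEMPLATES",
    "NESTED_TEMPLATES",
    "MULTI_TEMPLATES",
]

Template = tuple[str, ...]

DEFAULT_TEMPLATES: tuple[Template, ...] = (
    ("The", "{compound}", "has", "a", "{specifier}", "of", "{value}", "{unit}", "."),
    ("The", "{specifier}", "of", "{compound}", "is", "{value}", "{unit}", "."),
    ("A", "{specifier}", "of", "{value}", "{unit}", "was", "measured", "for",
     "{compound}", "."),
    ("{compound}", "exhibits", "a", "direct", "{specifier}", "of", "{value}",
     "{unit}", "."),
    ("The", "measured", "{specifier}", "for", "{compound}", "was", "{value}",
     "{unit}", "."),
    ("{compound}", "films", "show", "a", "{specifier}", "near", "{value}",
     "{unit}", "."),
)

#: Reworded variants of the default skeletons, intended as held-out test
#: templates when studying generalization to unseen phrasings.
PARAPHRASE_TEMPLATES: tuple[Template, ...] = (
    ("The", "bulk", "{compound}", "has", "an", "indirect", "{specifier}",
     "of", "{value}", "{unit}", "."),
    ("The", "{specifier}", "of", "crystalline", "{compound}", "equals",
     "{value}", "{unit}", "."),
    ("A", "{specifier}", "around", "{value}", "{unit}", "was", "reported",
     "for", "{compound}", "."),
    ("{compound}", "samples", "exhibit", "a", "{specifier}", "close", "to",
     "{value}", "{unit}", "."),
)

NESTED_TEMPLATES: tuple[Template, ...] = (
    ("At", "a", "{nspecifier}", "of", "{nvalue}", "{nunit}", ",",
     "{compound}", "has", "a", "{specifier}", "of", "{value}", "{unit}", "."),
    ("{compound}", "shows", "a", "{specifier}", "of", "{value}", "{unit}",
     "at", "a", "{nspecifier}", "of", "{nvalue}", "{nunit}", "."),
)

MULTI_TEMPLATES: tuple[Template, ...] = (
    ("{compound}", "and", "{compound2}", "show", "{specifier}", "values",
     "of", "{value}", "{unit}", "and", "{value2}", "{unit2}", ",",
     "respectively", "."),
)

_COMPOUNDS = (
    "TiO2", "ZnO", "GaN", "GaAs", "CdSe", "Si", "Ge", "InP", "SnO2", "CuO",
    "ZnS", "MoS2", "WSe2", "AlN", "SiC", "Cu2O",
)
_SPECIFIERS = (("band", "gap"), ("bandgap",), ("energy", "gap"),
               ("optical", "gap"))
_UNITS = (("eV",), ("meV",))
_NSPECIFIERS = (("temperature",),)
_NUNITS = (("K",),)


def default_schema() -> PropertySchema:
    """Band-gap-like root model with a nested temperature model."""
    return PropertySchema(
        "band_gap",
        ("specifier", "value", "unit"),
        nested=(PropertySchema("temperature", ("specifier", "value", "unit")),),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of a synthetic corpus.

    ``distractor_rate`` inserts extra *untagged* numeric value/unit tokens;
    ``multi_relation_rate`` and ``nested_rate`` are the fractions of
    sentences drawn from two-compound and nested-model skeletons.
    """

    n_sentences: int = 1500
    seed: int = 0
    templates: tuple[Template, ...] = DEFAULT_TEMPLATES
    nested_templates: tuple[Template, ...] = NESTED_TEMPLATES
    multi_templates: tuple[Template, ...] = MULTI_TEMPLATES
    template_weights: tuple[float, ...] | None = None
    compounds: tuple[str, ...] = _COMPOUNDS
    specifiers: tuple[tuple[str, ...], ...] = _SPECIFIERS
    units: tuple[tuple[str, ...], ...] = _UNITS
    nested_specifiers: tuple[tuple[str, ...], ...] = _NSPECIFIERS
    nested_units: tuple[tuple[str, ...], ...] = _NUNITS
    value_range: tuple[float, float] = (0.1, 10.0)
    nested_value_range: tuple[int, int] = (4, 1000)
    distractor_rate: float = 0.0
    multi_relation_rate: float = 0.0
    nested_rate: float = 0.0
    id_prefix: str = "s"

    def __post_init__(self) -> None:
        for name in ("templates", "compounds", "specifiers", "units"):
            if not getattr(self, name):
                raise ConfigError(f"empty vocabulary pool: {name}")
        if self.nested_rate > 0 and not self.nested_templates:
            raise ConfigError("nested_rate > 0 requires nested templates")
        if self.multi_relation_rate > 0 and not self.multi_templates:
            raise ConfigError("multi_relation_rate > 0 requires multi templates")
        for rate in (self.distractor_rate, self.multi_relation_rate,
                     self.nested_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError("rates must lie in [0, 1]")
        if self.multi_relation_rate > 0 and len(self.compounds) < 2:
            raise ConfigError("two-compound sentences need >= 2 compounds")
        if self.template_weights is not None and len(
            self.template_weights
        ) != len(self.templates):
            raise ConfigError("one weight per template required")


def _sample_value(rng: np.random.Generator, lo: float, hi: float) -> str:
    return f"{round(rng.uniform(lo, hi), 1):.1f}"


def _fill(
    template: Template,
    surfaces: dict[str, tuple[str, ...]],
) -> tuple[tuple[str, ...], dict[str, tuple[int, int]]]:
    tokens: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for item in template:
        if item.startswith("{") and item.endswith("}"):
            name = item[1:-1]
            surf = surfaces[name]
            spans[name] = (len(tokens), len(tokens) + len(surf))
            tokens.extend(surf)
        else:
            tokens.append(item)
    return tuple(tokens), spans


def _distract(
    rng: np.random.Generator, tokens: tuple[str, ...]
) -> tuple[str, ...]:
    """Insert an untagged numeric aside before the final token."""
    choices = (
        ("at", str(int(rng.integers(100, 900))), "K"),
        ("(", str(int(rng.integers(200, 800))), "nm", ")"),
        ("under", str(int(rng.integers(1, 10))), "GPa"),
    )
    extra = choices[int(rng.integers(len(choices)))]
    cut = len(tokens) - 1 if tokens and tokens[-1] == "." else len(tokens)
    return tokens[:cut] + extra + tokens[cut:]


def generate(config: SynthConfig) -> list[TaggedSentence]:
    """Generate a labeled corpus under ``config`` (seeded, reproducible)."""
    rng = np.random.default_rng(config.seed)
    root_path = ("band_gap",)
    nested_path = ("band_gap", "temperature")
    sentences: list[TaggedSentence] = []

    if config.template_weights is not None:
        w = np.asarray(config.template_weights, dtype=float)
        plain_p = w / w.sum()
    else:
        plain_p = None

    for i in range(config.n_sentences):
        u = rng.uniform()
        if u < config.multi_relation_rate:
            kind = "multi"
            template = config.multi_templates[
                int(rng.integers(len(config.multi_templates)))
            ]
        elif u < config.multi_relation_rate + config.nested_rate:
            kind = "nested"
            template = config.nested_templates[
                int(rng.integers(len(config.nested_templates)))
            ]
        else:
            kind = "plain"
            idx = (
                int(rng.choice(len(config.templates), p=plain_p))
                if plain_p is not None
                else int(rng.integers(len(config.templates)))
            )
            template = config.templates[idx]

        surfaces: dict[str, tuple[str, ...]] = {
            "compound": (str(rng.choice(config.compounds)),),
            "specifier": tuple(
                config.specifiers[int(rng.integers(len(config.specifiers)))]
            ),
            "value": (
                _sample_value(rng, *config.value_range),
            ),
            "unit": tuple(config.units[int(rng.integers(len(config.units)))]),
        }
        if kind == "multi":
            others = [c for c in config.compounds if (c,) != surfaces["compound"]]
            surfaces["compound2"] = (str(rng.choice(others)),)
            surfaces["value2"] = (_sample_value(rng, *config.value_range),)
            surfaces["unit2"] = tuple(
                config.units[int(rng.integers(len(config.units)))]
            )
        if kind == "nested":
            lo, hi = config.nested_value_range
            surfaces["nspecifier"] = tuple(
                config.nested_specifiers[
                    int(rng.integers(len(config.nested_specifiers)))
                ]
            )
            surfaces["nvalue"] = (str(int(rng.integers(lo, hi + 1))),)
            surfaces["nunit"] = tuple(
                config.nested_units[int(rng.integers(len(config.nested_units)))]
            )

        tokens, spans = _fill(template, surfaces)
        if rng.uniform() < config.distractor_rate:
            tokens = _distract(rng, tokens)
            # spans precede the insertion point only when the template ends
            # with the sentence-final token; recompute defensively
            _, spans2 = _fill(template, surfaces)
            spans = spans2

        def tag(name: str, category: str, path: tuple[str, ...]) -> EntityTag:
            s = spans[name]
            return EntityTag(
                category=category,
                span=s,
                surface=tuple(tokens[s[0]:s[1]]),
                property_path=path,
            )

        entities = [
            tag("compound", COMPOUND, ()),
            tag("specifier", "specifier", root_path),
            tag("value", "value", root_path),
            tag("unit", "unit", root_path),
        ]
        rel1_slots = {
            ((), COMPOUND): entities[0],
            (root_path, "specifier"): entities[1],
            (root_path, "value"): entities[2],
            (root_path, "unit"): entities[3],
        }
        relations = []
        if kind == "nested":
            extra = [
                tag("nspecifier", "specifier", nested_path),
                tag("nvalue", "value", nested_path),
                tag("nunit", "unit", nested_path),
            ]
            entities.extend(extra)
            rel1_slots.update(
                {
                    (nested_path, "specifier"): extra[0],
                    (nested_path, "value"): extra[1],
                    (nested_path, "unit"): extra[2],
                }
            )
        relations.append(Relation(rel1_slots, confidence=1.0))
        if kind == "multi":
            extra = [
                tag("compound2", COMPOUND, ()),
                tag("value2", "value", root_path),
                tag("unit2", "unit", root_path),
            ]
            entities.extend(extra)
            relations.append(
                Relation(
                    {
                        ((), COMPOUND): extra[0],
                        (root_path, "specifier"): entities[1],
                        (root_path, "value"): extra[1],
                        (root_path, "unit"): extra[2],
                    },
                    confidence=1.0,
                )
            )

        sentences.append(
            TaggedSentence(
                sentence_id=f"{config.id_prefix}{i:05d}",
                tokens=tokens,
                entities=tuple(sorted(entities, key=lambda e: e.span)),
                relations=tuple(relations),
            )
        )
    return sentences


def train_test_split(
    corpus: Sequence[TaggedSentence], ratio: int = 5
) -> tuple[list[TaggedSentence], list[TaggedSentence]]:
    """Deterministic interleaved split; every (ratio+1)-th sentence is test."""
    if ratio < 1:
        raise ConfigError("ratio must be >= 1")
    train, test = [], []
    for i, s in enumerate(corpus):
        (test if i % (ratio + 1) == ratio else train).append(s)
    return train, test
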