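"""Serialization: sentence JSONL, model archives, phrase exchange, records.

Everything is UTF-8 JSON (JSON Lines for sentence corpora); floats survive
round trips at full precision via their decimal repr.  The model archive
stores every cluster's member phrases verbatim, so labeled phrases can be
exported from one model and imported into another — patterns and keys are
recomputed deterministically on load.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .clustering import Cluster, pseudocluster_key
from .errors import ModelFormatError, SentenceValidationError
from .extraction import DataRecord, Hyperparams, SnowballModel
from .schema import (
    COMPOUND,
    EntityTag,
    Phrase,
    PropertySchema,
    Relation,
    TaggedSentence,
    WeightConfig,
)

__all__ = [
    "FORMAT_VERSION",
    "read_sentences",
    "write_sentences",
    "save_model",
    "load_model",
    "export_phrases",
    "import_phrases",
    "write_records",
    "records_to_dataframe",
    "load_hyperparams",
]

FORMAT_VERSION = "1"


# -- schema ------------------------------------------------------------


def schema_to_dict(schema: PropertySchema) -> dict:
    return {
        "name": schema.name,
        "required_slots": list(schema.required_slots),
        "nested": [schema_to_dict(c) for c in schema.nested],
    }


def schema_from_dict(obj: dict) -> PropertySchema:
    return PropertySchema(
        name=obj["name"],
        required_slots=tuple(obj["required_slots"]),
        nested=tuple(schema_from_dict(c) for c in obj.get("nested", [])),
    )


# -- sentences ---------------------------------------------------------


def _entity_to_dict(e: EntityTag) -> dict:
    return {
        "category": e.category,
        "property_path": list(e.property_path),
        "span": list(e.span),
    }


def _sentence_to_dict(s: TaggedSentence) -> dict:
    ent_index = {e: i for i, e in enumerate(s.entities)}
    obj: dict[str, Any] = {
        "sentence_id": s.sentence_id,
        "tokens": list(s.tokens),
        "entities": [_entity_to_dict(e) for e in s.entities],
    }
    if s.relations:
        obj["relations"] = [
            {
                "confidence": rel.confidence,
                "slots": [
                    {"path": list(path), "kind": kind, "entity": ent_index[e]}
                    for (path, kind), e in rel.slots.items()
                ],
            }
            for rel in s.relations
        ]
    return obj


def _sentence_from_dict(obj: dict, line: int | None = None) -> TaggedSentence:
    try:
        tokens = tuple(obj["tokens"])
        entities = tuple(
            EntityTag(
                category=e["category"],
                property_path=tuple(e.get("property_path", [])),
                span=tuple(e["span"]),
                surface=tuple(tokens[e["span"][0]:e["span"][1]]),
            )
            for e in obj.get("entities", [])
        )
        relations = tuple(
            Relation(
                {
                    (tuple(s["path"]), s["kind"]): entities[s["entity"]]
                    for s in rel["slots"]
                },
                confidence=rel.get("confidence", 1.0),
            )
            for rel in obj.get("relations", [])
        )
        return TaggedSentence(
            sentence_id=str(obj["sentence_id"]),
            tokens=tokens,
            entities=entities,
            relations=relations,
        )
    except SentenceValidationError:
        raise
    except Exception as exc:
        raise SentenceValidationError(str(exc), line=line) from exc


def read_sentences(path: str | Path) -> list[TaggedSentence]:
    """Read a JSONL corpus, reporting malformed lines by number."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise SentenceValidationError(
                    f"invalid JSON: {exc}", line=lineno
                ) from exc
            try:
                sentences.append(_sentence_from_dict(obj, line=lineno))
            except Exception as exc:
                if isinstance(exc, SentenceValidationError):
                    raise
                raise SentenceValidationError(str(exc), line=lineno) from exc
    return sentences


def write_sentences(sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps(_sentence_to_dict(s), ensure_ascii=False))
            fh.write("\n")


# -- phrases -----------------------------------------------------------


def _inline_entity_to_dict(e: EntityTag) -> dict:
    return {
        "category": e.category,
        "property_path": list(e.property_path),
        "span": list(e.span),
        "surface": list(e.surface),
    }


def _inline_entity_from_dict(obj: dict) -> EntityTag:
    return EntityTag(
        category=obj["category"],
        property_path=tuple(obj["property_path"]),
        span=tuple(obj["span"]),
        surface=tuple(obj["surface"]),
    )


def phrase_to_dict(p: Phrase) -> dict:
    return {
        "sentence_id": p.sentence_id,
        "tokens": list(p.tokens),
        "relations": [
            {
                "confidence": rel.confidence,
                "slots": [
                    {
                        "path": list(path),
                        "kind": kind,
                        "entity": _inline_entity_to_dict(e),
                    }
                    for (path, kind), e in rel.slots.items()
                ],
            }
            for rel in p.relations
        ],
        "elements": [list(el) for el in p.elements],
        "element_weights": list(p.element_weights),
        "confidence": p.confidence,
        "pooled_middles": p.pooled_middles,
    }


def phrase_from_dict(obj: dict) -> Phrase:
    relations = tuple(
        Relation(
            {
                (tuple(s["path"]), s["kind"]): _inline_entity_from_dict(
                    s["entity"]
                )
                for s in rel["slots"]
            },
            confidence=rel.get("confidence", 1.0),
        )
        for rel in obj["relations"]
    )
    entities = tuple(
        sorted(
            (e for rel in relations for e in rel.slots.values()),
            key=lambda e: e.span,
        )
    )
    return Phrase(
        sentence_id=obj["sentence_id"],
        tokens=tuple(obj["tokens"]),
        relations=relations,
        entities_in_order=entities,
        elements=tuple(tuple(el) for el in obj["elements"]),
        element_weights=tuple(obj["element_weights"]),
        confidence=obj["confidence"],
        pooled_middles=obj.get("pooled_middles", False),
    )


# -- hyperparameters ---------------------------------------------------


def hyperparams_to_dict(p: Hyperparams) -> dict:
    return {
        "tau_h": p.tau_h,
        "tau_l": p.tau_l,
        "tau_c": p.tau_c,
        "normalization": p.normalization,
        "emulation_10": p.emulation_10,
        "min_record_confidence": p.min_record_confidence,
        "single_best": p.single_best,
        "max_prefix_len": p.max_prefix_len,
        "max_suffix_len": p.max_suffix_len,
        "weights": {
            "prefix": p.weights.prefix,
            "middles": p.weights.middles,
            "suffix": p.weights.suffix,
        },
        "pooled_middles": p.pooled_middles,
    }


def hyperparams_from_dict(obj: dict) -> Hyperparams:
    obj = dict(obj)
    w = obj.pop("weights", None)
    weights = WeightConfig(**w) if w else WeightConfig()
    return Hyperparams(weights=weights, **obj)


def load_hyperparams(path: str | Path) -> Hyperparams:
    """Read hyperparameters from a YAML config mirroring the field names."""
    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh) or {}
    return hyperparams_from_dict(obj)


# -- model archives ----------------------------------------------------


def save_model(
    model: SnowballModel, path: str | Path, seed: int | None = None
) -> None:
    """Write a lossless model archive (UTF-8 JSON)."""
    obj = {
        "format_version": FORMAT_VERSION,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": seed,
        "schema": schema_to_dict(model.schema),
        "hyperparams": hyperparams_to_dict(model.params),
        "clusters": [
            {
                "members": [phrase_to_dict(m) for m in cl.members],
                "pattern": phrase_to_dict(cl.pattern),
            }
            for group in model.clusters.values()
            for cl in group
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, ensure_ascii=False, indent=1)


def load_model(path: str | Path) -> SnowballModel:
    """Load a model archive; partitions and pattern confidences are
    reproduced exactly (patterns are recomputed deterministically from the
    stored members)."""
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"unreadable model archive: {exc}") from exc
    version = obj.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"model archive format {version!r} is incompatible with "
            f"this version (expected {FORMAT_VERSION!r})"
        )
    schema = schema_from_dict(obj["schema"])
    model = SnowballModel(schema, hyperparams_from_dict(obj["hyperparams"]))
    for cl_obj in obj["clusters"]:
        members = [phrase_from_dict(m) for m in cl_obj["members"]]
        key = pseudocluster_key(members[0], schema)
        model.clusters.setdefault(key, []).append(Cluster(key, members))
    return model


def export_phrases(model: SnowballModel, path: str | Path) -> int:
    """Write all labeled phrases of a model for transfer to another model."""
    phrases = model.all_phrases()
    obj = {
        "format_version": FORMAT_VERSION,
        "phrases": [phrase_to_dict(p) for p in phrases],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, ensure_ascii=False, indent=1)
    return len(phrases)


def import_phrases(path: str | Path) -> list[Phrase]:
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"unreadable phrase archive: {exc}") from exc
    if obj.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError("phrase archive format is incompatible")
    return [phrase_from_dict(p) for p in obj["phrases"]]


# -- records -----------------------------------------------------------

RECORD_COLUMNS = [
    "sentence_id", "compound", "property_name", "specifier", "value",
    "unit", "confidence",
]


def records_to_dataframe(records: Sequence[DataRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sentence_id": r.sentence_id,
                "compound": r.compound,
                "property_name": r.property_name,
                "specifier": r.specifier,
                "value": r.value,
                "unit": r.unit,
                "confidence": r.confidence,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def write_records(records: Sequence[DataRecord], path: str | Path) -> None:
    """Write records as CSV (default) or JSON depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                records_to_dataframe(records).to_dict(orient="records"),
                fh,
                ensure_ascii=False,
                indent=1,
            )
    else:
        records_to_dataframe(records).to_csv(path, index=False)
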