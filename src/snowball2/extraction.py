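"""Unsupervised data extraction with banded similarity and bootstrapping.

A new sentence is expanded into candidate relations exactly as in
training; each candidate phrase is compared with the extraction patterns
of its pseudocluster.  Two thresholds band the matches: the high threshold
tau_h is a *hard*, exclusive boundary — when any pattern matches at or
above it, only the single best cluster is considered and the candidate's
confidence is computed against that cluster's internal phrases; the low
threshold tau_l (tau_l <= tau_h) is a *soft*, inclusive boundary — all
clusters matching at or above it contribute.  Below tau_l a candidate has
zero confidence and is rejected.

The confidence of a candidate relation r_c is the complement of the
product of per-term complements,

    C(r_c) = 1 - [ prod_i (1 - C_i * sim_i) ] ** (1/n),

where the terms run over the matched patterns (soft band) or the internal
phrases of the single matched cluster (hard band) and n is the number of
terms.  The geometric 1/n normalization keeps the score comparable across
cluster counts; dropping it recovers the earlier Snowball formulation
(the built-in 1.0 emulation mode additionally pins tau_c to 1 so no new
clusters are seeded), and a "single term" variant keeps only the best
term.

Per sentence, each compound keeps only its highest-confidence accepted
candidate.  An accepted candidate in the hard band is absorbed into the
best cluster immediately (the learning rate is fixed at 1: patterns and
confidences always stay synchronized); an accepted soft-band candidate
whose confidence reaches tau_c seeds a new single-member cluster, which is
how the model bootstraps coverage of novel phrasings.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .clustering import Cluster, ClusterKey, pseudocluster_key, triangle_sort_cluster
from .errors import ConfigError, InvalidInputError
from .schema import (
    COMPOUND,
    Phrase,
    PropertySchema,
    Relation,
    TaggedSentence,
    WeightConfig,
    decompose,
)
from .training import enumerate_candidates
from .vectorspace import PhraseVector, similarity, vectorize

__all__ = [
    "Hyperparams",
    "MatchReport",
    "DataRecord",
    "SnowballModel",
    "match_bands",
    "candidate_confidence",
    "extract",
    "relation_to_records",
]

Normalization = Literal["geometric", "single_term", "none"]

BAND_HARD = "hard"
BAND_SOFT = "soft"
BAND_NONE = "none"

DECISION_ACCEPT_INTO_CLUSTER = "accept_into_cluster"
DECISION_ACCEPT_NEW_CLUSTER = "accept_new_cluster"
DECISION_ACCEPT_NO_LEARN = "accept_no_learn"
DECISION_REJECT = "reject"


@dataclass(frozen=True)
class Hyperparams:
    """All tunable knobs of a Snowball model.

    tau_h and tau_l are the high (hard, exclusive) and low (soft,
    inclusive) similarity thresholds, tau_l <= tau_h; tau_c is the minimum
    candidate confidence for seeding a new cluster from unseen text.
    ``emulation_10`` switches on the earlier-version emulation: it forces
    ``normalization="none"`` and ``tau_c=1``.  Element weights and
    prefix/suffix lengths configure phrase decomposition and travel with
    the model so training and extraction stay consistent.
    """

    tau_h: float = 0.75
    tau_l: float = 0.6
    tau_c: float = 0.8
    normalization: Normalization = "geometric"
    emulation_10: bool = False
    min_record_confidence: float = 0.0
    single_best: bool = True
    max_prefix_len: int = 3
    max_suffix_len: int = 3
    weights: WeightConfig = field(default_factory=WeightConfig)
    pooled_middles: bool = False

    def __post_init__(self) -> None:
        if self.emulation_10:
            object.__setattr__(self, "normalization", "none")
            object.__setattr__(self, "tau_c", 1.0)
        if not (0.0 < self.tau_l <= self.tau_h <= 1.0):
            raise ConfigError(
                f"need 0 < tau_l <= tau_h <= 1, got tau_l={self.tau_l}, "
                f"tau_h={self.tau_h}"
            )
        if not (0.0 <= self.tau_c <= 1.0):
            raise ConfigError(f"tau_c={self.tau_c} outside [0, 1]")
        if not (0.0 <= self.min_record_confidence <= 1.0):
            raise ConfigError("min_record_confidence outside [0, 1]")
        if self.normalization not in ("geometric", "single_term", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.max_prefix_len < 0 or self.max_suffix_len < 0:
            raise ConfigError("prefix/suffix lengths must be >= 0")

    def decompose_kwargs(self) -> dict:
        return {
            "max_prefix_len": self.max_prefix_len,
            "max_suffix_len": self.max_suffix_len,
            "weights": self.weights,
            "pooled_middles": self.pooled_middles,
        }


@dataclass
class MatchReport:
    """How one candidate phrase fared against the cluster model."""

    candidate: Phrase
    matched: list[tuple[Cluster, float]]
    band: str
    confidence: float = 0.0
    decision: str = DECISION_REJECT


@dataclass(frozen=True)
class DataRecord:
    """An extracted {compound, property, value, unit} tuple."""

    sentence_id: str
    compound: str
    property_name: str
    specifier: str
    value: str
    unit: str
    confidence: float

    def slots_tuple(self) -> tuple:
        """Identity under the exact-match protocol (confidence excluded)."""
        return (
            self.sentence_id,
            self.compound,
            self.property_name,
            self.specifier,
            self.value,
            self.unit,
        )


def relation_to_records(
    sentence_id: str, relation: Relation, confidence: float
) -> list[DataRecord]:
    """Flatten a relation into one record per property model it fills."""
    compound = " ".join(relation.compound.surface)
    by_path: dict[tuple[str, ...], dict[str, str]] = {}
    for (path, kind), ent in relation.slots.items():
        if kind == COMPOUND:
            continue
        by_path.setdefault(path, {})[kind] = " ".join(ent.surface)
    records = []
    for path in sorted(by_path, key=lambda p: (len(p), p)):
        slots = by_path[path]
        records.append(
            DataRecord(
                sentence_id=sentence_id,
                compound=compound,
                property_name=path[-1],
                specifier=slots.get("specifier", ""),
                value=slots.get("value", ""),
                unit=slots.get("unit", ""),
                confidence=confidence,
            )
        )
    return records


class SnowballModel:
    """All clusters of labeled phrases plus the hyperparameters.

    Clusters are grouped by pseudocluster key.  Clustering happens after
    training (not during), so hyperparameters can be changed and the
    phrases reclustered without re-annotating anything.
    """

    def __init__(
        self,
        schema: PropertySchema,
        params: Hyperparams | None = None,
    ):
        self.schema = schema
        self.params = params or Hyperparams()
        self.clusters: dict[ClusterKey, list[Cluster]] = {}

    # -- construction -------------------------------------------------

    def add_training_phrases(self, phrases: Iterable[Phrase]) -> None:
        """Add curated phrases and recluster the affected pseudoclusters."""
        fresh: dict[ClusterKey, list[Phrase]] = {}
        for phrase in phrases:
            key = pseudocluster_key(phrase, self.schema)
            fresh.setdefault(key, []).append(phrase)
        for key, new_members in fresh.items():
            members = [
                m for c in self.clusters.get(key, []) for m in c.members
            ]
            members.extend(new_members)
            self.clusters[key] = triangle_sort_cluster(
                members,
                self.params.tau_h,
                single_best=self.params.single_best,
                key=key,
            )

    def recluster(self, params: Hyperparams | None = None) -> None:
        """Rebuild every pseudocluster's partition, e.g. after changing
        tau_h; fully reversible because member phrases are kept intact."""
        if params is not None:
            self.params = params
        for key in list(self.clusters):
            members = [m for c in self.clusters[key] for m in c.members]
            self.clusters[key] = triangle_sort_cluster(
                members,
                self.params.tau_h,
                single_best=self.params.single_best,
                key=key,
            )

    def all_phrases(self) -> list[Phrase]:
        return [
            m
            for group in self.clusters.values()
            for cl in group
            for m in cl.members
        ]

    @property
    def n_clusters(self) -> int:
        return sum(len(group) for group in self.clusters.values())

    @property
    def n_phrases(self) -> int:
        return sum(
            len(cl.members) for group in self.clusters.values() for cl in group
        )

    def copy(self) -> "SnowballModel":
        return copy.deepcopy(self)

    # -- extraction ----------------------------------------------------

    def extract(
        self,
        sentence: TaggedSentence,
        schema: PropertySchema | None = None,
        learn: bool = True,
    ) -> list[DataRecord]:
        records, _ = extract(sentence, self, schema=schema, learn=learn)
        return records


def match_bands(
    candidate: PhraseVector,
    key: ClusterKey,
    model: SnowballModel,
) -> tuple[str, list[tuple[Cluster, float]]]:
    """Band a candidate phrase against the clusters sharing its key.

    Hard band: some cluster reaches tau_h — only the single best such
    cluster is retained, all weaker matches are neglected.  Soft band:
    no hard match, but at least one cluster reaches tau_l — all such
    clusters are retained and considered equally.  Otherwise: no band.
    """
    params = model.params
    group = model.clusters.get(key, [])
    sims = [(cl, cl.similarity_to(candidate)) for cl in group]
    hard = [(cl, s) for cl, s in sims if s >= params.tau_h]
    if hard:
        best = max(enumerate(hard), key=lambda t: (t[1][1], -t[0]))[1]
        return BAND_HARD, [best]
    soft = [(cl, s) for cl, s in sims if s >= params.tau_l]
    if soft:
        return BAND_SOFT, soft
    return BAND_NONE, []


def _combine(terms: Sequence[float], normalization: Normalization) -> float:
    if not terms:
        return 0.0
    if normalization == "single_term":
        return min(1.0, max(0.0, max(terms)))
    prod = 1.0
    for t in terms:
        prod *= 1.0 - min(1.0, max(0.0, t))
    if normalization == "geometric":
        prod = prod ** (1.0 / len(terms))
    return min(1.0, max(0.0, 1.0 - prod))


def candidate_confidence(
    candidate: PhraseVector,
    band: str,
    matched: Sequence[tuple[Cluster, float]],
    params: Hyperparams,
) -> float:
    """Confidence C(r_c) of a candidate relation given its matches.

    Soft band: terms C(P_i) * sim(p_c, P_i) over the matched patterns.
    Hard band: the candidate is compared with the internal phrases of the
    single matched cluster, terms C_i * sim(p_c, p_i).  An unmatched
    candidate always has zero confidence.
    """
    if band == BAND_NONE or not matched:
        return 0.0
    if band == BAND_HARD:
        cluster = matched[0][0]
        terms = [
            member.confidence * similarity(candidate, vectorize(member))
            for member in cluster.members
        ]
    else:
        terms = [cl.pattern_confidence * s for cl, s in matched]
    return _combine(terms, params.normalization)


def extract(
    sentence: TaggedSentence,
    model: SnowballModel,
    schema: PropertySchema | None = None,
    learn: bool = True,
) -> tuple[list[DataRecord], list[MatchReport]]:
    """Extract confidence-scored records from one pre-tagged sentence.

    Enumerates candidate relations, scores every candidate phrase, keeps
    per compound the highest-confidence accepted candidate (ties broken by
    earliest spans), then applies the banded accept/reject policy: hard
    band — absorb the phrase into its best cluster; soft band — emit, and
    additionally seed a new cluster when the confidence reaches tau_c; no
    band — reject.  Records below ``min_record_confidence`` are dropped.
    Set ``learn=False`` to score against a frozen model.
    """
    schema = schema or model.schema
    params = model.params
    if not sentence.entities:
        return [], []

    reports: list[MatchReport] = []
    for rel in enumerate_candidates(sentence, schema):
        phrase = decompose(
            sentence, rel, confidence=0.0, **params.decompose_kwargs()
        )
        key = pseudocluster_key(phrase, schema)
        vec = vectorize(phrase)
        band, matched = match_bands(vec, key, model)
        conf = candidate_confidence(vec, band, matched, params)
        reports.append(
            MatchReport(candidate=phrase, matched=matched, band=band,
                        confidence=conf, decision=DECISION_REJECT)
        )

    by_compound: dict[tuple[int, int], list[MatchReport]] = {}
    for rep in reports:
        span = rep.candidate.relations[0].compound.span
        by_compound.setdefault(span, []).append(rep)

    records: list[DataRecord] = []
    for span in sorted(by_compound):
        accepted = [r for r in by_compound[span] if r.band != BAND_NONE]
        if not accepted:
            continue
        winner = sorted(
            accepted,
            key=lambda r: (-r.confidence, r.candidate.relations[0].span_signature()),
        )[0]
        phrase = winner.candidate.with_confidence(winner.confidence)
        key = pseudocluster_key(phrase, schema)
        if winner.band == BAND_HARD:
            winner.decision = DECISION_ACCEPT_INTO_CLUSTER
            if learn:
                winner.matched[0][0].add(phrase)
        elif winner.confidence >= params.tau_c:
            winner.decision = DECISION_ACCEPT_NEW_CLUSTER
            if learn:
                model.clusters.setdefault(key, []).append(
                    Cluster(key, [phrase])
                )
        else:
            winner.decision = DECISION_ACCEPT_NO_LEARN
        if winner.confidence >= params.min_record_confidence:
            records.extend(
                relation_to_records(
                    sentence.sentence_id,
                    phrase.relations[0],
                    winner.confidence,
                )
            )
    return records, reports
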