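"""Two-level clustering of labeled phrases.

First level: phrases are grouped into *pseudoclusters* purely by the count
and positional ordering of their entities, compared per property model and
never by property name — so a band-gap phrase and a Curie-temperature
phrase with the same entity layout share a pseudocluster and one model can
serve any property.

Second level: within a pseudocluster, a single-pass classification pass
(SPCA) assigns each phrase to a cluster whose synthesized *extraction
pattern* it matches at or above the high similarity threshold tau_h,
seeding a new cluster otherwise.  Because a plain single pass depends on
presentation order, the order-invariant entry point sorts the work with a
*similarity triangle*: pairwise similarities are computed once, and the
minimum-similarity pair is clustered first, repeatedly, until the triangle
is cleared.  Splitting the least similar pairs first maximizes the number
of clusters and makes the partition independent of training order.

The extraction pattern of a cluster is a synthesized phrase built from the
modal element (as a token sequence) of its members, ties favoring the most
recently added member, with confidence C(P) = sum_i v_i * C_i where C_i is
the confidence of the members contributing element i.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import IncomparablePhrasesError, InvalidRelationError
from .schema import COMPOUND, Phrase, PropertySchema, Relation
from .vectorspace import PhraseVector, similarity, vectorize

__all__ = [
    "ClusterKey",
    "Cluster",
    "pseudocluster_key",
    "spca_cluster",
    "triangle_sort_cluster",
    "build_pattern",
    "partition_signature",
]


@dataclass(frozen=True)
class ClusterKey:
    """Layout signature of a phrase: entity count, compound position, and
    per property model the entity index positions and slot-kind order.

    Property names are deliberately absent so models describing different
    properties with identical layout compare equal.
    """

    n_entities: int
    n_elements: int
    compound_position: int
    model_signatures: tuple[tuple[tuple[int, ...], tuple[str, ...]], ...]


def pseudocluster_key(phrase: Phrase, schema: PropertySchema) -> ClusterKey:
    """First-level (pseudocluster) key of a phrase under a schema.

    The comparison of entities is localized to individual property models:
    for each model present in the relation, in schema preorder, the
    signature records where that model's entities sit in the span-ordered
    entity list and in which slot-kind order.
    """
    if len(phrase.relations) != 1:
        raise InvalidRelationError("pseudocluster keys are per-relation")
    rel = phrase.relations[0]
    ordered = phrase.entities_in_order
    index = {ent: i for i, ent in enumerate(ordered)}

    known_paths = {path for _, path in schema.walk()}
    by_path: dict[tuple[str, ...], list[tuple[int, str]]] = {}
    for (path, kind), ent in rel.slots.items():
        if kind == COMPOUND:
            continue
        if path not in known_paths:
            raise InvalidRelationError(
                f"relation slot path {path} not present in schema "
                f"{schema.name!r}"
            )
        by_path.setdefault(path, []).append((index[ent], kind))

    signatures = []
    for _, path in schema.walk():
        if path not in by_path:
            continue
        entries = sorted(by_path[path])
        signatures.append(
            (tuple(i for i, _ in entries), tuple(k for _, k in entries))
        )
    return ClusterKey(
        n_entities=len(ordered),
        n_elements=len(phrase.elements),
        compound_position=index[rel.compound],
        model_signatures=tuple(signatures),
    )


def build_pattern(members: Sequence[Phrase]) -> Phrase:
    """Synthesize the extraction pattern of a member list.

    Per element slot the modal token sequence (case-insensitive) across
    members is selected; ties are broken toward the sequence most recently
    added, so the pattern always favors the newest information.  The
    pattern confidence is the weighted sum of the confidences of the
    contributing members (the best-attested confidence where several
    members share the chosen sequence).
    """
    if not members:
        raise InvalidRelationError("cannot build a pattern for an empty cluster")
    newest = members[-1]
    n_el = len(newest.elements)
    chosen_elements: list[tuple[str, ...]] = []
    confidence = 0.0
    for i in range(n_el):
        stats: dict[tuple[str, ...], dict] = {}
        for pos, member in enumerate(members):
            seq = tuple(t.lower() for t in member.elements[i])
            st = stats.setdefault(seq, {"count": 0, "newest": -1, "conf": 0.0})
            st["count"] += 1
            st["newest"] = pos
            st["surface"] = member.elements[i]
            st["conf"] = max(st["conf"], member.confidence)
        best = max(stats.values(), key=lambda st: (st["count"], st["newest"]))
        chosen_elements.append(best["surface"])
        confidence += newest.element_weights[i] * best["conf"]
    confidence = min(1.0, max(0.0, confidence))
    return replace(
        newest,
        elements=tuple(chosen_elements),
        confidence=confidence,
    )


class Cluster:
    """A group of layout-compatible phrases represented by one pattern.

    Members are kept in insertion order; the pattern and its confidence
    C(P) are recomputed from the current members after every insertion or
    removal, which makes clustering fully reversible: removing the last
    added phrase restores the previous state exactly.
    """

    def __init__(self, key: ClusterKey | None, members: Iterable[Phrase] = ()):
        self.key = key
        self.members: list[Phrase] = []
        self.pattern: Phrase | None = None
        self.pattern_vector: PhraseVector | None = None
        for phrase in members:
            self.add(phrase)

    @property
    def pattern_confidence(self) -> float:
        return self.pattern.confidence if self.pattern is not None else 0.0

    def add(self, phrase: Phrase) -> None:
        self.members.append(phrase)
        self._refresh()

    def remove(self, phrase: Phrase) -> None:
        """Remove the most recent occurrence of ``phrase`` and recompute."""
        for i in range(len(self.members) - 1, -1, -1):
            if self.members[i] == phrase:
                del self.members[i]
                break
        else:
            raise InvalidRelationError("phrase is not a member of this cluster")
        self._refresh()

    def _refresh(self) -> None:
        if self.members:
            self.pattern = build_pattern(self.members)
            self.pattern_vector = vectorize(self.pattern)
        else:
            self.pattern = None
            self.pattern_vector = None

    def similarity_to(self, vector: PhraseVector) -> float:
        if self.pattern_vector is None:
            return 0.0
        return similarity(vector, self.pattern_vector)

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Cluster({len(self.members)} members, C(P)={self.pattern_confidence:.3f})"


def spca_cluster(
    phrases: Sequence[Phrase],
    tau_h: float,
    *,
    single_best: bool = True,
    clusters: list[Cluster] | None = None,
    key: ClusterKey | None = None,
) -> list[Cluster]:
    """Single-pass classification of phrases, in the order given.

    A phrase joins an existing cluster when its similarity to the cluster's
    extraction pattern reaches ``tau_h``; with ``single_best`` only the
    best-matching such cluster receives it (avoiding redundant copies),
    otherwise every matching cluster does.  A phrase matching no cluster
    seeds a new one.  Patterns and confidences are updated after each
    insertion, so later phrases see the freshest patterns.
    """
    if not (0.0 < tau_h <= 1.0):
        raise IncomparablePhrasesError("tau_h must lie in (0, 1]")
    clusters = clusters if clusters is not None else []
    for phrase in phrases:
        vec = vectorize(phrase)
        scored = [(c.similarity_to(vec), i) for i, c in enumerate(clusters)]
        matching = [(s, i) for s, i in scored if s >= tau_h]
        if not matching:
            clusters.append(Cluster(key, [phrase]))
        elif single_best:
            # best similarity; ties toward the earliest-created cluster
            _, best_i = max(matching, key=lambda t: (t[0], -t[1]))
            clusters[best_i].add(phrase)
        else:
            for _, i in matching:
                clusters[i].add(phrase)
    return clusters


def triangle_sort_cluster(
    phrases: Sequence[Phrase],
    tau_h: float,
    *,
    single_best: bool = True,
    key: ClusterKey | None = None,
) -> list[Cluster]:
    """Order-invariant clustering via the similarity triangle.

    Phrases are first brought into a canonical content order, then the
    strict upper triangle of their pairwise similarity matrix is processed
    minimum-first: the least similar remaining pair is pushed through the
    single-pass step, the pair's row and column are deleted, and the loop
    repeats until the triangle is cleared (a final unpaired phrase is
    passed through on its own).  The resulting partition is identical for
    any permutation of the input.
    """
    phrases = sorted(phrases, key=lambda p: p.sort_key())
    n = len(phrases)
    if n == 0:
        return []
    if n == 1:
        return [Cluster(key, phrases)]

    vecs = [vectorize(p) for p in phrases]
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = similarity(vecs[i], vecs[j])

    clusters: list[Cluster] = []
    active = list(range(n))
    while len(active) >= 2:
        best_pair = None
        best_val = np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                v = sim[i, j]
                if v < best_val:  # ties keep the lowest index pair
                    best_val = v
                    best_pair = (i, j)
        i, j = best_pair
        spca_cluster(
            [phrases[i], phrases[j]], tau_h,
            single_best=single_best, clusters=clusters, key=key,
        )
        active.remove(i)
        active.remove(j)
    if active:
        spca_cluster(
            [phrases[active[0]]], tau_h,
            single_best=single_best, clusters=clusters, key=key,
        )
    return clusters


def partition_signature(clusters: Iterable[Cluster]):
    """Order-free description of a clustering, for invariance comparisons:
    the multiset of member content-key multisets."""
    return tuple(
        sorted(
            tuple(sorted(m.sort_key() for m in c.members)) for c in clusters
        )
    )
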