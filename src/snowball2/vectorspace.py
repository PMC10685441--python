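"""Bag-of-words vector space over phrase elements.

Each element (prefix, middles, suffix) becomes a term-frequency vector over
its own lowercased tokens, scaled to unit L2 norm; an empty element is the
zero vector.  The similarity between two phrases of the same pseudocluster
is the importance-weighted sum of element-wise dot products,

    sim(p, q) = sum_i v_i * (p_i . q_i),

with all unique tokens of the two corresponding elements as the basis.  On
unit vectors with normalized weights this lies in [0, 1] and equals 1 for
identical phrases with no empty elements.  Two empty corresponding elements
contribute 0, not 1: absence of context is not evidence of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import IncomparablePhrasesError
from .schema import Phrase

__all__ = ["ElementVector", "PhraseVector", "vectorize", "similarity"]


@dataclass(frozen=True)
class ElementVector:
    """Unit-L2 (or zero) token-weight vector for one phrase element."""

    token_weights: Mapping[str, float]

    @classmethod
    def from_tokens(cls, tokens: Sequence[str]) -> "ElementVector":
        counts: dict[str, int] = {}
        for tok in tokens:
            t = tok.lower()
            counts[t] = counts.get(t, 0) + 1
        norm = math.sqrt(sum(c * c for c in counts.values()))
        if norm == 0:
            return cls({})
        return cls({t: c / norm for t, c in counts.items()})

    def dot(self, other: "ElementVector") -> float:
        a, b = self.token_weights, other.token_weights
        if len(b) < len(a):
            a, b = b, a
        return sum(w * b[t] for t, w in a.items() if t in b)

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.token_weights.values()))


@dataclass(frozen=True)
class PhraseVector:
    """Ordered element vectors with their importance weights.

    ``entity_count`` is carried as metadata only (the number of entities in
    the underlying relation layout); it plays no role in the similarity.
    """

    element_vectors: tuple[ElementVector, ...]
    element_weights: tuple[float, ...]
    entity_count: int = 0

    def __post_init__(self) -> None:
        if len(self.element_vectors) != len(self.element_weights):
            raise IncomparablePhrasesError(
                "element vectors and weights differ in length"
            )


def vectorize(phrase: Phrase) -> PhraseVector:
    """Convert a phrase's elements to frequency-weighted unit vectors."""
    return PhraseVector(
        element_vectors=tuple(
            ElementVector.from_tokens(el) for el in phrase.elements
        ),
        element_weights=tuple(phrase.element_weights),
        entity_count=len(phrase.entities_in_order),
    )


def similarity(p: PhraseVector, q: PhraseVector) -> float:
    """Weighted element-wise dot-product similarity between two phrases.

    Both arguments must come from the same pseudocluster so their element
    lists align; the weights of ``p`` are used (identical for phrases of
    one pseudocluster under one weight configuration).
    """
    if len(p.element_vectors) != len(q.element_vectors):
        raise IncomparablePhrasesError(
            f"phrases have {len(p.element_vectors)} vs "
            f"{len(q.element_vectors)} elements and cannot be compared"
        )
    return sum(
        w * pv.dot(qv)
        for w, pv, qv in zip(p.element_weights, p.element_vectors, q.element_vectors)
    )
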