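"""scikit-learn-style front end for the Snowball relation extractor.

``SnowballExtractor`` follows the estimator protocol: hyperparameters are
constructor arguments surfaced through ``get_params``/``set_params`` (so
the class composes with sklearn model selection), ``fit`` curates training
phrases from gold-labeled sentences and clusters them, and ``predict``
runs the banded extraction over new sentences.  Note one deliberate
departure from sklearn convention: the extraction process bootstraps — by
default ``predict`` lets the fitted model absorb high-confidence novel
phrases, because that learning loop is the method itself.  Pass
``learn=False`` for a frozen-model prediction.
"""

from __future__ import annotations

from typing import Sequence

from sklearn.base import BaseEstimator

from .errors import InvalidInputError
from .evaluation import EvalResult, evaluate, gold_records
from .extraction import DataRecord, Hyperparams, SnowballModel
from .schema import (
    Phrase,
    PropertySchema,
    Relation,
    TaggedSentence,
    WeightConfig,
    decompose,
)

__all__ = ["SnowballExtractor", "train_model", "extract_records"]


class SnowballExtractor(BaseEstimator):
    """Semisupervised bootstrapping extractor of chemical property records.

    Parameters
    ----------
    schema:
        Property-model tree the sentences are tagged against.
    tau_h, tau_l:
        High (hard) and low (soft) similarity thresholds, ``tau_l <=
        tau_h``.
    tau_c:
        Minimum candidate confidence for seeding a new cluster from
        unseen text.
    normalization:
        ``"geometric"`` (confidence product normalized by the number of
        terms), ``"none"`` (plain product complement) or
        ``"single_term"`` (best term only).
    emulation_10:
        Emulate the earlier Snowball behavior: forces
        ``normalization="none"`` and ``tau_c=1``.
    prefix_weight, middles_weight, suffix_weight:
        Importance mass of the prefix, all middles jointly, and the
        suffix; normalized to sum one, middles split equally per gap.
    max_prefix_len, max_suffix_len:
        Token budget kept adjacent to the first/last entity.
    min_record_confidence:
        Records scoring below this are dropped from the output.

    Attributes
    ----------
    model_ : SnowballModel
        Clusters of curated phrases plus hyperparameters.
    n_phrases_, n_clusters_ : int
        Training-corpus summary after ``fit``.
    """

    def __init__(
        self,
        schema: PropertySchema | None = None,
        tau_h: float = 0.75,
        tau_l: float = 0.6,
        tau_c: float = 0.8,
        normalization: str = "geometric",
        emulation_10: bool = False,
        single_best: bool = True,
        max_prefix_len: int = 3,
        max_suffix_len: int = 3,
        prefix_weight: float = 0.1,
        middles_weight: float = 0.8,
        suffix_weight: float = 0.1,
        pooled_middles: bool = False,
        min_record_confidence: float = 0.0,
    ):
        self.schema = schema
        self.tau_h = tau_h
        self.tau_l = tau_l
        self.tau_c = tau_c
        self.normalization = normalization
        self.emulation_10 = emulation_10
        self.single_best = single_best
        self.max_prefix_len = max_prefix_len
        self.max_suffix_len = max_suffix_len
        self.prefix_weight = prefix_weight
        self.middles_weight = middles_weight
        self.suffix_weight = suffix_weight
        self.pooled_middles = pooled_middles
        self.min_record_confidence = min_record_confidence

    # ------------------------------------------------------------------

    def _hyperparams(self) -> Hyperparams:
        return Hyperparams(
            tau_h=self.tau_h,
            tau_l=self.tau_l,
            tau_c=self.tau_c,
            normalization=self.normalization,
            emulation_10=self.emulation_10,
            min_record_confidence=self.min_record_confidence,
            single_best=self.single_best,
            max_prefix_len=self.max_prefix_len,
            max_suffix_len=self.max_suffix_len,
            weights=WeightConfig(
                self.prefix_weight, self.middles_weight, self.suffix_weight
            ),
            pooled_middles=self.pooled_middles,
        )

    def fit(
        self,
        X: Sequence[TaggedSentence],
        y: Sequence[Sequence[Relation]] | None = None,
    ) -> "SnowballExtractor":
        """Curate confidence-1.0 phrases from gold relations and cluster.

        ``y`` optionally supplies the gold relations per sentence;
        otherwise each sentence's own ``relations`` field is used.
        """
        if self.schema is None:
            raise InvalidInputError("SnowballExtractor requires a schema")
        params = self._hyperparams()
        phrases: list[Phrase] = []
        for i, sentence in enumerate(X):
            relations = y[i] if y is not None else sentence.relations
            for rel in relations:
                phrases.append(
                    decompose(
                        sentence, rel, confidence=1.0,
                        **params.decompose_kwargs(),
                    )
                )
        model = SnowballModel(self.schema, params)
        model.add_training_phrases(phrases)
        self.model_ = model
        self.n_phrases_ = model.n_phrases
        self.n_clusters_ = model.n_clusters
        return self

    def predict(
        self,
        X: Sequence[TaggedSentence],
        learn: bool = True,
    ) -> list[list[DataRecord]]:
        """Extract records sentence by sentence (bootstrapping unless
        ``learn=False``)."""
        self._check_fitted()
        return [self.model_.extract(s, learn=learn) for s in X]

    def score(
        self,
        X: Sequence[TaggedSentence],
        y: Sequence[Sequence[Relation]] | None = None,
        learn: bool = True,
    ) -> float:
        """Exact-match F-score against gold relations."""
        return self.evaluate(X, y, learn=learn).f_score

    def evaluate(
        self,
        X: Sequence[TaggedSentence],
        y: Sequence[Sequence[Relation]] | None = None,
        learn: bool = True,
    ) -> EvalResult:
        self._check_fitted()
        extracted = [r for recs in self.predict(X, learn=learn) for r in recs]
        gold = gold_records(X, y)
        return evaluate(extracted, gold)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise InvalidInputError(
                "this SnowballExtractor is not fitted yet; call fit first"
            )


def train_model(
    sentences: Sequence[TaggedSentence],
    schema: PropertySchema,
    **params,
) -> SnowballModel:
    """Functional wrapper: fit an extractor and return its model."""
    est = SnowballExtractor(schema=schema, **params)
    est.fit(sentences)
    return est.model_


def extract_records(
    sentences: Sequence[TaggedSentence],
    model: SnowballModel,
    learn: bool = True,
) -> list[DataRecord]:
    """Functional wrapper: extract from many sentences with one model."""
    out: list[DataRecord] = []
    for s in sentences:
        out.extend(model.extract(s, learn=learn))
    return out
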