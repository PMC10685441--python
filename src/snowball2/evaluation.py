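"""Exact-match evaluation and hyperparameter studies.

A record counts as a true positive only when every slot — sentence,
compound, property name, specifier, value and unit — matches a gold record
exactly; anything less is a false positive (and the unmatched gold record
a false negative).  This protocol is stricter than manual validation,
where minor incompleteness is often forgiven, so absolute numbers are not
comparable to loosely validated studies.  Precision = TP/(TP+FP),
recall = TP/(TP+FN), F is their harmonic mean; 0/0 is defined as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .extraction import (
    DataRecord,
    Hyperparams,
    SnowballModel,
    relation_to_records,
)
from .schema import PropertySchema, Relation, TaggedSentence

__all__ = [
    "EvalResult",
    "evaluate",
    "gold_records",
    "recovery_study",
    "training_size_study",
]


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def gold_records(
    sentences: Sequence[TaggedSentence],
    y: Sequence[Sequence[Relation]] | None = None,
) -> list[DataRecord]:
    """Flatten gold relations into records (confidence 1.0)."""
    out: list[DataRecord] = []
    for i, s in enumerate(sentences):
        relations = y[i] if y is not None else s.relations
        for rel in relations:
            out.extend(relation_to_records(s.sentence_id, rel, 1.0))
    return out


def evaluate(
    extracted: Iterable[DataRecord], gold: Iterable[DataRecord]
) -> EvalResult:
    """Count exact slot matches between extracted and gold records."""
    ex = Counter(r.slots_tuple() for r in extracted)
    gd = Counter(r.slots_tuple() for r in gold)
    tp = sum(min(c, gd.get(k, 0)) for k, c in ex.items())
    fp = sum(ex.values()) - tp
    fn = sum(gd.values()) - tp
    return EvalResult(tp=tp, fp=fp, fn=fn)


def recovery_study(
    train: Sequence[TaggedSentence],
    test: Sequence[TaggedSentence],
    schema: PropertySchema,
    tau_h_grid: Sequence[float],
    tau_l_grid: Sequence[float],
    base_params: Hyperparams | None = None,
) -> pd.DataFrame:
    """Precision/recall/F surface over the triangular (tau_h, tau_l) grid.

    One model is trained (and clustered) per tau_h; each tau_l <= tau_h
    point scores a frozen copy of that model on the test split, so the
    surface reflects the thresholds alone, not accumulated bootstrapping.
    """
    from .estimator import SnowballExtractor  # local import, avoids cycle

    base = base_params or Hyperparams()
    rows = []
    for tau_h in tau_h_grid:
        ref = None
        for tau_l in tau_l_grid:
            if tau_l > tau_h:
                continue
            params = Hyperparams(
                tau_h=tau_h,
                tau_l=tau_l,
                tau_c=base.tau_c,
                normalization=base.normalization,
                emulation_10=base.emulation_10,
                min_record_confidence=base.min_record_confidence,
                single_best=base.single_best,
                max_prefix_len=base.max_prefix_len,
                max_suffix_len=base.max_suffix_len,
                weights=base.weights,
                pooled_middles=base.pooled_middles,
            )
            if ref is None:
                ref = SnowballModel(schema, params)
                est_phrases = []
                for s in train:
                    for rel in s.relations:
                        from .schema import decompose

                        est_phrases.append(
                            decompose(
                                s, rel, confidence=1.0,
                                **params.decompose_kwargs(),
                            )
                        )
                ref.add_training_phrases(est_phrases)
            model = ref.copy()
            model.params = params
            extracted = []
            for s in test:
                extracted.extend(model.extract(s, learn=False))
            res = evaluate(extracted, gold_records(test))
            rows.append(
                {
                    "tau_h": tau_h,
                    "tau_l": tau_l,
                    "tp": res.tp,
                    "fp": res.fp,
                    "fn": res.fn,
                    "precision": res.precision,
                    "recall": res.recall,
                    "f_score": res.f_score,
                }
            )
    return pd.DataFrame(rows)


def training_size_study(
    train: Sequence[TaggedSentence],
    test: Sequence[TaggedSentence],
    schema: PropertySchema,
    sizes: Sequence[int],
    n_repeats: int = 30,
    seed: int = 0,
    params: Hyperparams | None = None,
) -> pd.DataFrame:
    """Mean/std of P, R, F over random training subsamples of given sizes."""
    params = params or Hyperparams()
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        scores = []
        for _ in range(n_repeats):
            idx = rng.choice(len(train), size=min(size, len(train)), replace=False)
            subset = [train[i] for i in sorted(idx)]
            model = SnowballModel(schema, params)
            from .schema import decompose

            phrases = [
                decompose(s, rel, confidence=1.0, **params.decompose_kwargs())
                for s in subset
                for rel in s.relations
            ]
            model.add_training_phrases(phrases)
            extracted = []
            for s in test:
                extracted.extend(model.extract(s, learn=False))
            res = evaluate(extracted, gold_records(test))
            scores.append((res.precision, res.recall, res.f_score))
        arr = np.asarray(scores)
        rows.append(
            {
                "size": size,
                "precision_mean": arr[:, 0].mean(),
                "recall_mean": arr[:, 1].mean(),
                "f_mean": arr[:, 2].mean(),
                "precision_std": arr[:, 0].std(),
                "recall_std": arr[:, 1].std(),
                "f_std": arr[:, 2].std(),
            }
        )
    return pd.DataFrame(rows)
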