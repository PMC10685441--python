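"""Banded matching, the confidence calculus, and bootstrap learning."""

import pytest

from snowball2.clustering import Cluster, pseudocluster_key
from snowball2.errors import ConfigError
from snowball2.extraction import (
    BAND_HARD,
    BAND_NONE,
    BAND_SOFT,
    Hyperparams,
    SnowballModel,
    candidate_confidence,
    extract,
    match_bands,
    relation_to_records,
)
from snowball2.schema import COMPOUND, PropertySchema, decompose
from snowball2.vectorspace import vectorize

from conftest import TOY_SCHEMA, make_sentence, relation_from_entities

# --- a tiny closed world with non-empty elements ----------------------
# Template "<pre> X <verb> about <val> roughly speaking" keeps every
# element non-empty so identical sentences reach similarity 1.0.

SCHEMA = PropertySchema("prop", ("value",))


def _sentence(sid, pre, compound, verb, value):
    tokens = [pre, compound, verb, "about", value, "roughly", "speaking"]
    return make_sentence(
        sid, tokens,
        [(COMPOUND, (1, 2), ()), ("value", (4, 5), ("prop",))],
    )


def _phrase(sid, pre, compound, verb, value, conf=1.0):
    s = _sentence(sid, pre, compound, verb, value)
    return decompose(
        s, relation_from_entities(s.entities), confidence=conf
    )


def _model(params=None, train=()):
    model = SnowballModel(SCHEMA, params or Hyperparams(tau_h=0.75, tau_l=0.4))
    model.add_training_phrases(list(train))
    return model


class TestHyperparams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            Hyperparams(tau_h=0.5, tau_l=0.6)

    def test_emulation_mode_pins_normalization_and_tau_c(self):
        p = Hyperparams(emulation_10=True, tau_c=0.3, normalization="geometric")
        assert p.normalization == "none"
        assert p.tau_c == 1.0


class TestMatchBands:
    def _three_cluster_model(self):
        train = [
            _phrase("t1", "the", "TiO2", "measures", "3.2"),
            _phrase("t2", "a", "ZnO", "reaches", "3.3"),
            _phrase("t3", "some", "GaN", "nears", "3.4"),
        ]
        return _model(Hyperparams(tau_h=0.9, tau_l=0.1), train)

    def test_hard_match_excludes_weaker_clusters(self):
        model = self._three_cluster_model()
        cand = _phrase("c", "the", "CdSe", "measures", "2.0")
        key = pseudocluster_key(cand, SCHEMA)
        band, matched = match_bands(vectorize(cand), key, model)
        assert band == BAND_HARD
        assert len(matched) == 1
        assert matched[0][1] == pytest.approx(1.0)

    def test_soft_match_keeps_all_reachable_clusters(self):
        model = self._three_cluster_model()
        # "the ... measures about" overlaps every pattern in the shared
        # "about" middle and nothing reaches tau_h=0.9 except exact matches
        cand = _phrase("c", "the", "CdSe", "shows", "2.0")
        key = pseudocluster_key(cand, SCHEMA)
        band, matched = match_bands(vectorize(cand), key, model)
        assert band == BAND_SOFT
        assert len(matched) == 3

    def test_out_of_range_candidate_matches_nothing(self):
        model = self._three_cluster_model()
        cand = _phrase("c", "beyond", "CdSe", "dwarfs", "2.0")
        cand = cand.with_confidence(0.0)
        key = pseudocluster_key(cand, SCHEMA)
        band, matched = match_bands(vectorize(cand), key, model)
        # middles still share "about": similarity 0.8*0.5=0.4 >= tau_l=0.1
        # so use a stricter model to test the empty band
        strict = self._three_cluster_model()
        strict.params = Hyperparams(tau_h=0.9, tau_l=0.7)
        band, matched = match_bands(vectorize(cand), key, strict)
        assert band == BAND_NONE and matched == []

    def test_unknown_key_is_no_band(self, band_gap_sentence, band_gap_schema):
        model = self._three_cluster_model()
        other = decompose(
            band_gap_sentence, relation_from_entities(band_gap_sentence.entities)
        )
        key = pseudocluster_key(other, band_gap_schema)
        band, matched = match_bands(vectorize(other), key, model)
        assert band == BAND_NONE


class TestCandidateConfidence:
    def _cluster(self, conf, phrase):
        c = Cluster(None, [phrase.with_confidence(conf)])
        return c

    def test_perfect_match_gives_one(self):
        p = _phrase("t", "the", "TiO2", "measures", "3.2")
        c = self._cluster(1.0, p)
        conf = candidate_confidence(
            vectorize(p), BAND_SOFT, [(c, 1.0)], Hyperparams()
        )
        assert conf == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "normalization, expected",
        [("geometric", 0.5), ("none", 0.75), ("single_term", 0.5)],
    )
    def test_two_half_matches(self, normalization, expected):
        p = _phrase("t", "the", "TiO2", "measures", "3.2")
        matched = [(self._cluster(1.0, p), 0.5), (self._cluster(1.0, p), 0.5)]
        conf = candidate_confidence(
            vectorize(p), BAND_SOFT, matched,
            Hyperparams(normalization=normalization, tau_c=1.0),
        )
        assert conf == pytest.approx(expected)

    def test_no_match_is_zero(self):
        p = _phrase("t", "the", "TiO2", "measures", "3.2")
        assert candidate_confidence(
            vectorize(p), BAND_NONE, [], Hyperparams()
        ) == 0.0

    def test_hard_band_uses_internal_phrases(self):
        a = _phrase("a", "the", "TiO2", "measures", "3.2", conf=1.0)
        b = _phrase("b", "the", "ZnO", "measures", "3.3", conf=0.5)
        cluster = Cluster(None, [a, b])
        cand = _phrase("c", "the", "GaN", "measures", "2.0")
        conf = candidate_confidence(
            vectorize(cand), BAND_HARD, [(cluster, 1.0)], Hyperparams()
        )
        # terms 1.0*1.0 and 0.5*1.0 -> 1 - (0 * 0.5)^(1/2) = 1
        assert conf == pytest.approx(1.0)

    def test_emulation_matches_unnormalized_product_term_for_term(self):
        p = _phrase("t", "the", "TiO2", "measures", "3.2")
        sims = [0.43, 0.61, 0.55]
        confs = [0.9, 0.8, 1.0]
        matched = [
            (self._cluster(c, _phrase(f"m{i}", "the", "X", "verbs", "1.0")), s)
            for i, (c, s) in enumerate(zip(confs, sims))
        ]
        got = candidate_confidence(
            vectorize(p), BAND_SOFT, matched,
            Hyperparams(emulation_10=True, tau_l=0.75),
        )
        expected = 1.0
        for c, s in zip(confs, sims):
            expected *= 1 - c * s
        assert got == pytest.approx(1 - expected, abs=1e-12)


class TestExtract:
    def test_identical_sentence_absorbed_with_full_confidence(self):
        train = _phrase("t1", "the", "TiO2", "measures", "3.2")
        model = _model(train=[train])
        n_before = model.n_phrases
        test = _sentence("x", "the", "CdSe", "measures", "2.0")
        records, reports = extract(test, model)
        assert len(records) == 1
        assert records[0].confidence == pytest.approx(1.0)
        assert records[0].compound == "CdSe"
        assert records[0].value == "2.0"
        assert model.n_phrases == n_before + 1
        assert reports[0].decision == "accept_into_cluster"

    def test_bootstrap_round_trip_creates_cluster_then_hard_matches(self):
        train = _phrase("t1", "the", "TiO2", "measures", "3.2")
        model = _model(
            Hyperparams(tau_h=0.75, tau_l=0.4, tau_c=0.5), [train]
        )
        # paraphrase: shares "the" prefix and "about" in the verb middle,
        # similarity 0.1 + 0.8*0.5 + 0.1 = 0.6 -> soft band, conf 0.6
        para = _sentence("p", "the", "ZnO", "nears", "1.5")
        n_before = model.n_clusters
        records, reports = extract(para, model)
        assert reports[0].band == BAND_SOFT
        assert records[0].confidence == pytest.approx(0.6)
        assert reports[0].decision == "accept_new_cluster"
        assert model.n_clusters == n_before + 1
        # re-presenting the identical sentence now matches at sim 1.0
        again = _sentence("p2", "the", "ZnO", "nears", "1.5")
        _, reports2 = extract(again, model)
        winner = [r for r in reports2 if r.decision != "reject"][0]
        assert winner.band == BAND_HARD
        assert max(s for _, s in winner.matched) == pytest.approx(1.0)

    def test_soft_band_below_tau_c_emits_without_learning(self):
        train = _phrase("t1", "the", "TiO2", "measures", "3.2")
        model = _model(Hyperparams(tau_h=0.75, tau_l=0.4, tau_c=0.9), [train])
        para = _sentence("p", "the", "ZnO", "nears", "1.5")
        n_clusters = model.n_clusters
        records, reports = extract(para, model)
        assert records and reports[0].decision == "accept_no_learn"
        assert model.n_clusters == n_clusters

    def test_rejected_below_tau_l(self):
        train = _phrase("t1", "the", "TiO2", "measures", "3.2")
        model = _model(Hyperparams(tau_h=0.75, tau_l=0.65), [train])
        far = _sentence("f", "beyond", "ZnO", "dwarfs", "1.5")
        records, reports = extract(far, model)
        assert records == []
        assert reports[0].band == BAND_NONE
        assert reports[0].confidence == 0.0

    def test_no_entities_no_output(self):
        model = _model(train=[_phrase("t", "the", "TiO2", "measures", "3.2")])
        empty = make_sentence("e", ["no", "entities", "here"], [])
        assert extract(empty, model) == ([], [])

    def test_tau_l_superset_monotonicity(self):
        """Lowering tau_l only ever adds accepted records."""
        train = [
            _phrase("t1", "the", "TiO2", "measures", "3.2"),
            _phrase("t2", "a", "ZnO", "reaches", "3.3"),
        ]
        tests = [
            _sentence("x1", "the", "GaN", "measures", "2.0"),
            _sentence("x2", "the", "GaN", "nears", "2.1"),
            _sentence("x3", "some", "InP", "dwarfs", "2.2"),
            _sentence("x4", "a", "CdSe", "reaches", "2.3"),
        ]
        accepted = {}
        for tau_l in (0.7, 0.5, 0.3):
            model = _model(Hyperparams(tau_h=0.75, tau_l=tau_l), train)
            recs = []
            for s in tests:
                recs.extend(extract(s, model, learn=False)[0])
            accepted[tau_l] = {r.slots_tuple() for r in recs}
        assert accepted[0.7] <= accepted[0.5] <= accepted[0.3]

    def test_min_record_confidence_zero_is_identity(self):
        train = [_phrase("t1", "the", "TiO2", "measures", "3.2")]
        tests = [
            _sentence("x1", "the", "GaN", "measures", "2.0"),
            _sentence("x2", "the", "GaN", "nears", "2.1"),
        ]
        def run(mrc):
            model = _model(
                Hyperparams(tau_h=0.75, tau_l=0.4, min_record_confidence=mrc),
                train,
            )
            out = []
            for s in tests:
                out.extend(extract(s, model, learn=False)[0])
            return out

        assert [r.slots_tuple() for r in run(0.0)] == [
            r.slots_tuple() for r in run(0.0)
        ]
        unfiltered, filtered = run(0.0), run(0.9)
        assert {r.slots_tuple() for r in filtered} <= {
            r.slots_tuple() for r in unfiltered
        }
        assert len(unfiltered) == 2  # identity at 0: nothing dropped

    def test_bootstrap_confidence_non_decreasing_in_copies(self):
        model = _model(
            Hyperparams(tau_h=0.75, tau_l=0.4, tau_c=0.5),
            [_phrase("t1", "the", "TiO2", "measures", "3.2")],
        )
        confs = []
        for k in range(5):
            s = _sentence(f"n{k}", "the", "ZnO", "nears", "1.5")
            records, _ = extract(s, model)
            confs.append(records[0].confidence)
        assert all(b >= a - 1e-12 for a, b in zip(confs, confs[1:]))

    def test_confidence_zero_iff_no_cluster_reaches_tau_l(self):
        model = _model(
            Hyperparams(tau_h=0.9, tau_l=0.7),
            [_phrase("t1", "the", "TiO2", "measures", "3.2")],
        )
        near = _sentence("a", "the", "GaN", "measures", "2.0")
        far = _sentence("b", "beyond", "GaN", "dwarfs", "2.0")
        _, rep_near = extract(near, model, learn=False)
        _, rep_far = extract(far, model, learn=False)
        assert rep_near[0].confidence > 0.0
        assert rep_far[0].confidence == 0.0


class TestRecords:
    def test_nested_relation_yields_one_record_per_model(self):
        from snowball2.synth import SynthConfig, generate

        corpus = generate(SynthConfig(n_sentences=10, seed=5, nested_rate=1.0))
        s = corpus[0]
        records = relation_to_records(s.sentence_id, s.relations[0], 0.9)
        assert len(records) == 2
        assert {r.property_name for r in records} == {"band_gap", "temperature"}
        assert len({r.compound for r in records}) == 1
        assert all(r.confidence == 0.9 for r in records)
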