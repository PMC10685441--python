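"""Pseudocluster keys, single-pass clustering, triangle sorting, patterns."""

import itertools
import random

import pytest

from snowball2.clustering import (
    Cluster,
    build_pattern,
    partition_signature,
    pseudocluster_key,
    spca_cluster,
    triangle_sort_cluster,
)
from snowball2.errors import IncomparablePhrasesError
from snowball2.schema import (
    COMPOUND,
    PropertySchema,
    decompose,
)
from snowball2.synth import SynthConfig, generate

from conftest import TOY_SCHEMA, make_sentence, relation_from_entities


def _phrase_of(sentence, **kwargs):
    return decompose(sentence, relation_from_entities(sentence.entities), **kwargs)


class TestPseudoclusterKey:
    def test_different_properties_same_layout_share_a_key(self):
        """A nested-temperature band-gap phrase and a nested-diameter Curie
        phrase have identical entity layouts, hence equal keys."""
        bg = PropertySchema(
            "BandGap", nested=(PropertySchema("Temperature", ("value", "unit")),)
        )
        s1 = make_sentence(
            "p1", "At 300 K , TiO2 has a band gap of 3.2 eV .".split(),
            [
                ("value", (1, 2), ("BandGap", "Temperature")),
                ("unit", (2, 3), ("BandGap", "Temperature")),
                (COMPOUND, (4, 5), ()),
                ("specifier", (7, 9), ("BandGap",)),
                ("value", (10, 11), ("BandGap",)),
                ("unit", (11, 12), ("BandGap",)),
            ],
        )
        curie = PropertySchema(
            "Curie", nested=(PropertySchema("Diameter", ("value", "unit")),)
        )
        s2 = make_sentence(
            "p2",
            "The 100 nm Cobalt quantum dot has a Curie temperature of 1394 K .".split(),
            [
                ("value", (1, 2), ("Curie", "Diameter")),
                ("unit", (2, 3), ("Curie", "Diameter")),
                (COMPOUND, (3, 6), ()),
                ("specifier", (8, 10), ("Curie",)),
                ("value", (11, 12), ("Curie",)),
                ("unit", (12, 13), ("Curie",)),
            ],
        )
        k1 = pseudocluster_key(_phrase_of(s1), bg)
        k2 = pseudocluster_key(_phrase_of(s2), curie)
        assert k1 == k2

    def test_identical_phrase_identical_key(self, band_gap_sentence, band_gap_schema):
        p = _phrase_of(band_gap_sentence)
        assert pseudocluster_key(p, band_gap_schema) == pseudocluster_key(
            p, band_gap_schema
        )

    def test_swapping_value_and_unit_changes_the_key(self, band_gap_schema):
        a = make_sentence(
            "a", "X gap 3.2 eV end".split(),
            [
                (COMPOUND, (0, 1), ()),
                ("specifier", (1, 2), ("band_gap",)),
                ("value", (2, 3), ("band_gap",)),
                ("unit", (3, 4), ("band_gap",)),
            ],
        )
        b = make_sentence(
            "b", "X gap eV 3.2 end".split(),
            [
                (COMPOUND, (0, 1), ()),
                ("specifier", (1, 2), ("band_gap",)),
                ("unit", (2, 3), ("band_gap",)),
                ("value", (3, 4), ("band_gap",)),
            ],
        )
        assert pseudocluster_key(_phrase_of(a), band_gap_schema) != \
            pseudocluster_key(_phrase_of(b), band_gap_schema)


class TestSinglePass:
    def test_order_abc_yields_one_cluster(self, toy_phrases):
        out = spca_cluster(
            [toy_phrases["A"], toy_phrases["B"], toy_phrases["C"]], 0.85
        )
        assert len(out) == 1

    def test_order_acb_yields_two_clusters(self, toy_phrases):
        out = spca_cluster(
            [toy_phrases["A"], toy_phrases["C"], toy_phrases["B"]], 0.85
        )
        assert len(out) == 2

    def test_single_phrase_seeds_one_cluster(self, toy_phrases):
        out = spca_cluster([toy_phrases["A"]], 0.85)
        assert len(out) == 1
        assert out[0].members == [toy_phrases["A"]]
        assert out[0].pattern.elements == toy_phrases["A"].elements

    def test_single_best_assigns_each_phrase_once(self, toy_phrases):
        for order in itertools.permutations("ABC"):
            out = spca_cluster([toy_phrases[k] for k in order], 0.85)
            assert sum(len(c) for c in out) == 3


class TestTriangleSort:
    def test_toy_always_two_clusters(self, toy_phrases):
        for order in itertools.permutations("ABC"):
            out = triangle_sort_cluster([toy_phrases[k] for k in order], 0.85)
            assert len(out) == 2

    def test_all_similar_phrases_form_one_cluster(self, toy_phrases):
        out = triangle_sort_cluster(
            [toy_phrases["A"], toy_phrases["B"], toy_phrases["C"]], 0.75
        )
        assert len(out) == 1

    def test_partition_invariant_under_permutation(self):
        corpus = generate(SynthConfig(n_sentences=20, seed=9))
        phrases = [
            decompose(s, rel) for s in corpus for rel in s.relations
        ]
        # restrict to one pseudocluster layout (all plain templates share
        # entity count 4 but differ in ordering; group by element count)
        schema = PropertySchema("band_gap")
        groups = {}
        for p in phrases:
            groups.setdefault(pseudocluster_key(p, schema), []).append(p)
        phrases = max(groups.values(), key=len)
        reference = partition_signature(triangle_sort_cluster(phrases, 0.7))
        rng = random.Random(0)
        for _ in range(50):
            shuffled = phrases[:]
            rng.shuffle(shuffled)
            assert partition_signature(
                triangle_sort_cluster(shuffled, 0.7)
            ) == reference

    def test_reclustering_members_is_idempotent(self, toy_phrases):
        first = triangle_sort_cluster(list(toy_phrases.values()), 0.85)
        members = [m for c in first for m in c.members]
        second = triangle_sort_cluster(members, 0.85)
        assert partition_signature(first) == partition_signature(second)

    def test_empty_and_degenerate_inputs(self, toy_phrases):
        assert triangle_sort_cluster([], 0.85) == []
        out = triangle_sort_cluster([toy_phrases["A"]], 0.85)
        assert len(out) == 1 and len(out[0]) == 1


class TestPattern:
    def test_single_member_pattern_is_the_member(self, toy_phrases):
        a = toy_phrases["A"].with_confidence(0.7)
        pattern = build_pattern([a])
        assert pattern.elements == a.elements
        assert pattern.confidence == pytest.approx(0.7)

    def test_mixed_contributors_weighted_confidence(self):
        """Contributor confidences (1.0, 0.5, 0.0) at weights (.1, .8, .1)
        combine to pattern confidence 0.5."""
        def toy(prefix, middle, suffix, conf):
            s = make_sentence(
                "s", [prefix, "E1", middle, "3.2", suffix],
                [
                    (COMPOUND, (1, 2), ()),
                    ("value", (3, 4), ("prop",)),
                ],
            )
            return _phrase_of(s).with_confidence(conf)

        members = [
            toy("the", "m1", "s1", 1.0),   # prefix source (shared with #2)
            toy("the", "m2", "s2", 0.5),   # middle source (shared with #3)
            toy("px", "m2", "s3", 0.0),    # suffix source (newest tie)
        ]
        pattern = build_pattern(members)
        assert pattern.prefix == ("the",)
        assert pattern.middles == (("m2",),)
        assert pattern.suffix == ("s3",)
        assert pattern.confidence == pytest.approx(0.5)

    def test_all_members_fully_confident(self, toy_phrases):
        pattern = build_pattern([toy_phrases["A"], toy_phrases["B"]])
        assert pattern.confidence == pytest.approx(1.0)

    def test_newest_member_dominates_on_ties(self, toy_phrases):
        pattern = build_pattern([toy_phrases["A"], toy_phrases["B"]])
        assert pattern.elements == toy_phrases["B"].elements

    def test_pattern_confidence_stays_in_unit_interval(self, toy_phrases):
        members = [
            toy_phrases["A"].with_confidence(0.3),
            toy_phrases["B"].with_confidence(0.9),
        ]
        assert 0.0 <= build_pattern(members).confidence <= 1.0


class TestReversibility:
    def test_remove_restores_pre_insertion_state(self, toy_phrases):
        c = Cluster(None, [toy_phrases["A"]])
        before_members = list(c.members)
        before_pattern = c.pattern
        c.add(toy_phrases["B"])
        c.remove(toy_phrases["B"])
        assert c.members == before_members
        assert c.pattern == before_pattern


class TestErrors:
    def test_mixed_element_counts_rejected(self, toy_phrases, band_gap_sentence):
        other = _phrase_of(band_gap_sentence)  # 5 elements vs 3
        with pytest.raises(IncomparablePhrasesError):
            spca_cluster([toy_phrases["A"], other], 0.85)

    def test_invalid_tau_rejected(self, toy_phrases):
        with pytest.raises(IncomparablePhrasesError):
            spca_cluster([toy_phrases["A"]], 0.0)
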