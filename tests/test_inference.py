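"""Colexification inference: worked examples, oracle equivalence, invariants."""

from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from colexnet.errors import ConfigurationError
from colexnet.inference import (
    AFFIX_DEFAULTS,
    OVERLAP_DEFAULTS,
    InferenceConfig,
    affix_colexifications,
    build_affix_index,
    build_network,
    enumerate_affixes,
    full_colexifications,
    infer_language,
    naive_partial_colexifications,
    overlap_colexifications,
)
from colexnet.synth import SynthSpec, generate, perturb
from colexnet.wordlist import Wordlist

from conftest import make_entry


def edge_pairs(instances):
    return {(i.concept_a, i.concept_b) for i in instances}


class TestEnumerateAffixes:
    def test_six_token_form_under_defaults(self):
        # exhaustive check of the two inequalities: only length 3 qualifies
        out = enumerate_affixes(("h", "a", "n", "t", "ʃ", "uː"), AFFIX_DEFAULTS)
        assert set(out) == {
            (("h", "a", "n"), "prefix"),
            (("t", "ʃ", "uː"), "suffix"),
        }

    @pytest.mark.parametrize("n", range(6))
    def test_short_sequences_yield_nothing(self, n):
        assert enumerate_affixes(tuple("abcdef"[:n]), AFFIX_DEFAULTS) == []

    def test_nine_token_form_yields_eight_candidates(self):
        out = enumerate_affixes(tuple("handschuh"), AFFIX_DEFAULTS)
        assert len(out) == 8
        assert {len(a) for a, _ in out} == {3, 4, 5, 6}
        assert (tuple("hand"), "prefix") in out
        assert (tuple("schuh"), "suffix") in out

    def test_sides_restriction(self):
        prefixes = enumerate_affixes(
            tuple("handschuh"), InferenceConfig(sides="prefix")
        )
        assert all(side == "prefix" for _, side in prefixes)
        assert len(prefixes) == 4

    @given(
        tokens=st.lists(st.sampled_from("abc"), min_size=1, max_size=12).map(tuple),
        affix_min=st.integers(1, 4),
        residue_min=st.integers(0, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_admissibility_inequalities_hold(self, tokens, affix_min, residue_min):
        cfg = InferenceConfig(affix_len_min=affix_min, residue_len_min=residue_min)
        out = enumerate_affixes(tokens, cfg)
        for affix, side in out:
            assert len(affix) > affix_min
            assert len(tokens) - len(affix) > residue_min
            assert affix == (
                tokens[: len(affix)] if side == "prefix" else tokens[-len(affix):]
            )
        # completeness: every admissible length appears on both sides
        admissible = [
            length
            for length in range(1, len(tokens))
            if length > affix_min and len(tokens) - length > residue_min
        ]
        assert len(out) == 2 * len(admissible)

    def test_index_keys_are_proper_parts_of_their_hosts(self, glove_forms):
        index = build_affix_index(glove_forms, AFFIX_DEFAULTS)
        assert index  # handschuh contributes
        for key, hosts in index.items():
            for host, side in hosts:
                tokens = host.segments.tokens
                assert len(key) < len(tokens)
                assert key == (
                    tokens[: len(key)] if side == "prefix" else tokens[-len(key):]
                )


class TestFullColexifications:
    def test_earth_world_example(self, earth_forms):
        instances = full_colexifications(earth_forms)
        assert len(instances) == 1
        inst = instances[0]
        assert {inst.concept_a, inst.concept_b} == {"EARTH", "WORLD"}
        assert inst.form_a == inst.form_b == "erde"
        assert inst.sides == ("whole", "whole")

    def test_all_distinct_forms_yield_nothing(self, glove_forms):
        assert full_colexifications(glove_forms) == []

    def test_one_form_three_concepts_matches_brute_force(self):
        forms = [make_entry(str(i), c, "pina") for i, c in enumerate("XYZ")]
        instances = full_colexifications(forms)
        # oracle: enumerate all concept pairs directly
        expected = {
            frozenset((a.concept_id, b.concept_id))
            for a, b in combinations(forms, 2)
            if a.concept_id != b.concept_id and a.form == b.form
        }
        assert {frozenset(p) for p in edge_pairs(instances)} == expected
        assert len(instances) == 3


class TestAffixColexifications:
    def test_glove_example_two_directed_edges(self, glove_forms):
        instances = affix_colexifications(glove_forms)
        assert edge_pairs(instances) == {("HAND", "GLOVE"), ("SHOE", "GLOVE")}
        by_pair = {(i.concept_a, i.concept_b): i for i in instances}
        assert by_pair[("HAND", "GLOVE")].sides == ("whole", "prefix")
        assert by_pair[("SHOE", "GLOVE")].sides == ("whole", "suffix")
        # the witness affix is the affix word's entire form
        assert by_pair[("HAND", "GLOVE")].shared == tuple("hand")

    def test_direction_is_from_affix_to_host(self):
        forms = [
            make_entry("1", "FINGER", "finger"),
            make_entry("2", "FINGERNAIL", "fingernagel"),
        ]
        instances = affix_colexifications(forms)
        assert edge_pairs(instances) == {("FINGER", "FINGERNAIL")}

    def test_identical_forms_are_not_affix_related(self):
        forms = [make_entry("1", "X", "pina"), make_entry("2", "Y", "pina")]
        assert affix_colexifications(forms) == []
        assert len(full_colexifications(forms)) == 1

    def test_affix_on_both_sides_yields_two_witnesses(self):
        # "ara" is both prefix and suffix of "araXYara"
        forms = [make_entry("1", "A", "ara"), make_entry("2", "B", "araxyara")]
        instances = affix_colexifications(forms)
        assert {i.sides for i in instances} == {("whole", "prefix"), ("whole", "suffix")}


class TestOverlapColexifications:
    def test_waterfall_watermelon_share_water(self):
        forms = [
            make_entry("1", "WATERFALL", "waterfall"),
            make_entry("2", "WATERMELON", "watermelon"),
        ]
        instances = overlap_colexifications(forms)
        assert len(instances) == 1
        assert instances[0].shared == tuple("water")
        assert instances[0].sides == ("prefix", "prefix")

    def test_part_of_pairs_are_excluded(self):
        forms = [make_entry("1", "HAND", "hand"), make_entry("2", "GLOVE", "handschuh")]
        assert overlap_colexifications(forms) == []

    def test_shared_length_must_exceed_threshold(self):
        # exactly 4 shared tokens: below the exclusive overlap threshold
        forms = [
            make_entry("1", "A", "abcdwxyz"),
            make_entry("2", "B", "abcdmnopq"),
        ]
        assert overlap_colexifications(forms) == []
        # one more shared token crosses it
        forms5 = [
            make_entry("1", "A", "abcdewxyz"),
            make_entry("2", "B", "abcdemnopq"),
        ]
        assert len(overlap_colexifications(forms5)) == 1

    def test_pair_reported_once_at_longest_shared_affix(self):
        forms = [
            make_entry("1", "A", "abcdefwxyz"),
            make_entry("2", "B", "abcdefmnopq"),
        ]
        instances = overlap_colexifications(forms)
        assert len(instances) == 1
        assert instances[0].shared == tuple("abcdef")

    def test_side_mixed_overlap_admitted_by_default_and_excludable(self):
        # "salto" is a suffix of one word and a prefix of the other
        forms = [
            make_entry("1", "SOMERSAULT", "mortalsalto"),
            make_entry("2", "SALTATION", "saltomortale"),
        ]
        mixed = overlap_colexifications(forms)
        assert len(mixed) == 1
        assert set(mixed[0].sides) == {"prefix", "suffix"}
        strict_cfg = InferenceConfig(
            affix_len_min=4, residue_len_min=3, same_side_only=True
        )
        assert overlap_colexifications(forms, strict_cfg) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", ["affix", "overlap"])
    @pytest.mark.parametrize("seed", range(10))
    def test_efficient_equals_naive_on_random_lexicons(self, kind, seed):
        wordlist, _ = generate(SynthSpec(n_languages=5, n_concepts=10, seed=seed))
        noisy = perturb(wordlist, 0.5, seed=seed, collision_len=3)
        cfg = AFFIX_DEFAULTS if kind == "affix" else OVERLAP_DEFAULTS
        for wl in (wordlist, noisy):
            for language, forms in wl.languages.items():
                efficient = set(infer_language(forms, kind, cfg))
                naive = set(naive_partial_colexifications(forms, cfg, kind))
                assert efficient == naive

    def test_glove_example_naive_agrees(self, glove_forms):
        assert set(naive_partial_colexifications(glove_forms, AFFIX_DEFAULTS, "affix")) == set(
            affix_colexifications(glove_forms)
        )

    def test_empty_language(self):
        assert naive_partial_colexifications([], AFFIX_DEFAULTS, "affix") == []
        assert naive_partial_colexifications([], OVERLAP_DEFAULTS, "overlap") == []


class TestThresholdMonotonicity:
    @pytest.mark.parametrize("kind", ["affix", "overlap"])
    def test_raising_thresholds_never_adds_instances(self, kind):
        wordlist, _ = generate(SynthSpec(n_languages=3, n_concepts=12, seed=3))
        grid = [(2, 2), (3, 2), (2, 3), (4, 3), (5, 4)]
        for language, forms in wordlist.languages.items():
            sets = {
                (a, r): {
                    (i.concept_a, i.concept_b, i.form_a, i.form_b)
                    for i in infer_language(
                        forms, kind, InferenceConfig(affix_len_min=a, residue_len_min=r)
                    )
                }
                for a, r in grid
            }
            for (a1, r1) in grid:
                for (a2, r2) in grid:
                    if a2 >= a1 and r2 >= r1:
                        assert sets[(a2, r2)] <= sets[(a1, r1)]


class TestBuildNetwork:
    def test_full_network_from_earth_example(self, earth_wordlist):
        net = build_network(earth_wordlist, "full")
        assert not net.directed
        assert net.graph.number_of_edges() == 1
        assert set(net.graph.nodes) == {"EARTH", "WORLD"}
        edge = net.graph.edges["EARTH", "WORLD"]
        assert edge["weight_forms"] == edge["weight_languages"] == 1

    def test_affix_network_aggregates_across_languages(self, glove_forms):
        other = [
            make_entry("1", "HAND", "mano", language="italian"),
            make_entry("2", "SHOE", "scarpa", language="italian"),
            make_entry("3", "GLOVE", "manoscarpa", language="italian"),
        ]
        net = build_network(Wordlist(glove_forms + other), "affix")
        assert net.directed
        edge = net.graph.edges["HAND", "GLOVE"]
        assert edge["weight_languages"] == 2
        assert edge["weight_forms"] == 2
        # each language is its own family on family-less data
        assert edge["weight_families"] == 2

    def test_single_language_weights_are_one(self, glove_wordlist):
        net = build_network(glove_wordlist, "affix")
        for _, _, data in net.graph.edges(data=True):
            assert data["weight_languages"] == data["weight_families"] == 1

    def test_isolated_concepts_are_nodes(self, glove_forms):
        wl = Wordlist(glove_forms + [make_entry("4", "MOON", "luna")])
        net = build_network(wl, "affix")
        assert "MOON" in net.graph.nodes
        assert net.graph.degree("MOON") == 0

    def test_unknown_kind_is_configuration_error(self, glove_wordlist):
        with pytest.raises(ConfigurationError):
            build_network(glove_wordlist, "bogus")

    def test_weight_ordering_and_witness_invariants(self):
        wordlist, _ = generate(
            SynthSpec(n_languages=6, n_concepts=15, n_families=3, seed=11)
        )
        for kind in ("full", "affix", "overlap"):
            net = build_network(wordlist, kind)
            for a, b, data in net.graph.edges(data=True):
                assert a != b
                assert (
                    data["weight_families"]
                    <= data["weight_languages"]
                    <= data["weight_forms"]
                )
                assert len(data["witnesses"]) == data["weight_forms"]
                for w in data["witnesses"]:
                    if kind == "affix":
                        # witness form_a must be a proper peripheral part of form_b
                        ta, tb = w.tokens_a, w.tokens_b
                        assert len(ta) < len(tb)
                        assert tb[: len(ta)] == ta or tb[-len(ta):] == ta
                        assert w.shared == ta
                    elif kind == "overlap":
                        for tokens, side in zip((w.tokens_a, w.tokens_b), w.sides):
                            assert (
                                tokens[: len(w.shared)] == w.shared
                                if side == "prefix"
                                else tokens[-len(w.shared):] == w.shared
                            )

    def test_deterministic_across_runs(self, glove_forms):
        wl1 = Wordlist(list(glove_forms))
        wl2 = Wordlist(list(reversed(glove_forms)))
        from colexnet.export import network_to_dict

        for kind in ("full", "affix", "overlap"):
            assert network_to_dict(build_network(wl1, kind)) == network_to_dict(
                build_network(wl2, kind)
            )
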