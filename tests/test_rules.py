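"""Rule matching semantics, interaction extraction, characterization, catalog IO."""

import itertools

import pytest
from hypothesis import given, strategies as st

from seqmine.corpus import AGENE, ItemSequence, build_sequence_database, encode_sentence
from seqmine.mining import is_subsequence
from seqmine.rules import (
    CatalogError,
    ExtractionRule,
    RuleCategory,
    characterize,
    extract_interactions,
    infer_direction,
    match_rule,
    read_catalog,
    write_catalog,
)

from conftest import make_sentence

INTERACT_RULE = ExtractionRule(
    "i1", ("AGENE", "interact@vvz", "with@in", "AGENE"), RuleCategory("interaction")
)
ASSOC_RULE = ExtractionRule(
    "i2", ("AGENE", "association@nn", "with@in", "AGENE"), RuleCategory("interaction")
)


def brute_force_embeddings(rule_items, seq):
    """Oracle: every strictly increasing index tuple that realizes the rule."""
    out = []
    n = len(seq.items)
    for combo in itertools.combinations(range(n), len(rule_items)):
        ok = True
        for want, pos in zip(rule_items, combo):
            if want == AGENE:
                if pos not in seq.agene_slots:
                    ok = False
                    break
            elif seq.items[pos] != want:
                ok = False
                break
        if ok:
            out.append(combo)
    return out


class TestMatchRule:
    def test_direct_match(self, myc_stat3_sentences):
        seq = encode_sentence(myc_stat3_sentences[0])
        (m,) = match_rule(INTERACT_RULE, seq)
        names = tuple(seq.mention_names[i] for i in m.gene_pair)
        assert names == ("MYC", "STAT3")

    def test_gap_match(self, myc_stat3_sentences):
        seq = encode_sentence(myc_stat3_sentences[1])
        (m,) = match_rule(INTERACT_RULE, seq)
        names = tuple(seq.mention_names[i] for i in m.gene_pair)
        assert names == ("MYC", "STAT3")
        # the final AGENE is matched across a three-token gap
        assert m.embedding[3] - m.embedding[2] - 1 == 3

    def test_association_rule_on_published_pairs(self, association_sentences):
        pairs = []
        for s in association_sentences:
            seq = encode_sentence(s)
            for m in match_rule(ASSOC_RULE, seq):
                pairs.append(tuple(seq.mention_names[i] for i in m.gene_pair))
        assert pairs == [("SHC1", "CRKL"), ("CBL", "CRKL")]

    def test_max_gap_tightening_is_monotone(self, myc_stat3_sentences):
        seq = encode_sentence(myc_stat3_sentences[1])
        counts = [
            len(match_rule(INTERACT_RULE, seq, max_gap=g)) for g in (None, 5, 3, 2, 0)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 1 and counts[-1] == 0

    def test_stop_items_halt_gap_traversal(self):
        s = make_sentence(
            "stop",
            [("GENE", "AAA1"), ("interacts", "interact", "VVZ"),
             ("with", "with", "IN"), ("but", "but", "CC"), ("GENE", "BBB2")],
        )
        seq = encode_sentence(s)
        assert len(match_rule(INTERACT_RULE, seq)) == 1
        assert match_rule(INTERACT_RULE, seq, stop_items={"but@cc"}) == []

    def test_agene_binds_only_gene_positions(self):
        # the lemma 'agene' as a plain word must not satisfy an AGENE item
        s = make_sentence(
            "trick",
            [("AGENE", "agene", "NN"), ("interacts", "interact", "VVZ"),
             ("with", "with", "IN"), ("GENE", "BBB2"), ("GENE", "CCC3")],
        )
        seq = encode_sentence(s)
        matches = match_rule(INTERACT_RULE, seq)
        assert len(matches) == 0  # no gene position before the verb

    @given(st.data())
    def test_all_embeddings_match_bruteforce(self, data):
        alphabet = ["x@nn", "y@in", "z@vvz", AGENE]
        items = data.draw(
            st.lists(st.sampled_from(alphabet), min_size=3, max_size=12)
        )
        slots = {i: n for n, i in enumerate(j for j, it in enumerate(items) if it == AGENE)}
        seq = ItemSequence(
            "h", tuple(items), slots,
            mention_names=tuple(f"G{n}" for n in range(len(slots))),
        )
        rule_items = tuple(
            data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=4))
        )
        rule_items = (AGENE,) + rule_items + (AGENE,)  # ensure a reportable pair
        rule = ExtractionRule("h1", rule_items, RuleCategory("interaction"))
        got = [m.embedding for m in match_rule(rule, seq)]
        assert got == brute_force_embeddings(rule_items, seq)


class TestExtractInteractions:
    def test_two_sentences_two_interactions(self, myc_stat3_sentences):
        db = build_sequence_database(myc_stat3_sentences)
        dets = extract_interactions([INTERACT_RULE], db)
        assert len(dets) == 2
        assert all(d.gene_names == ("MYC", "STAT3") for d in dets)

    def test_no_gene_pairs_no_detections(self):
        db = build_sequence_database(
            [make_sentence("n1", [("nothing", "nothing", "NN")])],
            require_min_mentions=0,
        )
        assert extract_interactions([INTERACT_RULE], db) == []

    def test_three_mentions_yield_all_matching_pairs(self):
        s = make_sentence(
            "tri",
            [("GENE", "AAA1"), ("interacts", "interact", "VVZ"),
             ("with", "with", "IN"), ("GENE", "BBB2"), ("and", "and", "CC"),
             ("GENE", "CCC3")],
        )
        dets = extract_interactions([INTERACT_RULE], build_sequence_database([s]))
        assert [d.gene_names for d in dets] == [("AAA1", "BBB2"), ("AAA1", "CCC3")]

    def test_invariant_to_rule_and_corpus_order(self, myc_stat3_sentences):
        db1 = build_sequence_database(myc_stat3_sentences)
        db2 = build_sequence_database(list(reversed(myc_stat3_sentences)))
        rules_fwd = [INTERACT_RULE, ASSOC_RULE]
        a = extract_interactions(rules_fwd, db1)
        b = extract_interactions(list(reversed(rules_fwd)), db2)
        assert [(d.sentence_id, d.gene_names) for d in a] == [
            (d.sentence_id, d.gene_names) for d in b
        ]

    def test_supporting_rules_accumulate_not_multiply(self):
        dup = ExtractionRule("i9", INTERACT_RULE.items, RuleCategory("interaction"))
        s = make_sentence(
            "acc",
            [("GENE", "AAA1"), ("interacts", "interact", "VVZ"),
             ("with", "with", "IN"), ("GENE", "BBB2")],
        )
        dets = extract_interactions([INTERACT_RULE, dup], build_sequence_database([s]))
        assert len(dets) == 1
        assert dets[0].supporting_rule_ids == ["i1", "i9"]

    def test_direction_metadata_fills_ordered_pair(self):
        directed = ExtractionRule(
            "d1", ("activation@nn", "of@in", "AGENE", "by@in", "AGENE"),
            RuleCategory("interaction"), direction="right_to_left",
        )
        s = make_sentence(
            "dir",
            [("activation", "activation", "NN"), ("of", "of", "IN"),
             ("GENE", "AAA1"), ("by", "by", "IN"), ("GENE", "BBB2")],
        )
        (det,) = extract_interactions([directed], build_sequence_database([s]))
        assert det.directed_names == ("BBB2", "AAA1")  # right gene is the agent

    def test_characterization_rule_rejected(self):
        char = ExtractionRule(
            "c1", ("in@in", "mouse@nn", "AGENE", "AGENE"),
            RuleCategory("characterization", "organism"),
        )
        with pytest.raises(CatalogError):
            extract_interactions([char], [])


class TestCharacterize:
    POSSIBILITY = ExtractionRule(
        "c1", ("the@dt", "possibility@nn", "that@in/that", "AGENE", "AGENE"),
        RuleCategory("characterization", "assumption"),
    )
    FIBRO = ExtractionRule(
        "c2", ("in@in", "fibroblast@nns", "AGENE", "AGENE"),
        RuleCategory("characterization", "component"),
    )

    def _sentence(self):
        return make_sentence(
            "ch1",
            [("the", "the", "DT"), ("possibility", "possibility", "NN"),
             ("that", "that", "IN/that"), ("GENE", "AAA1"),
             ("interacts", "interact", "VVZ"), ("with", "with", "IN"),
             ("GENE", "BBB2")],
        )

    def test_modality_attaches_to_detected_pair(self):
        db = build_sequence_database([self._sentence()])
        dets = extract_interactions([INTERACT_RULE], db)
        characterize(dets, [self.POSSIBILITY], db)
        assert dets[0].characterizations == [("assumption", "c1")]

    def test_context_rule_attaches(self):
        s = make_sentence(
            "ch2",
            [("in", "in", "IN"), ("fibroblasts", "fibroblast", "NNS"),
             ("GENE", "AAA1"), ("activates", "activate", "VVZ"), ("GENE", "BBB2")],
        )
        act = ExtractionRule("i3", ("AGENE", "activate@vvz", "AGENE"),
                             RuleCategory("interaction"))
        db = build_sequence_database([s])
        dets = extract_interactions([act], db)
        characterize(dets, [self.FIBRO], db)
        assert dets[0].characterizations == [("component", "c2")]

    def _four_gene_sentence(self):
        # interactions bind AAA1 to later genes; the fibroblast context
        # pattern can only bind the (CCC3, DDD4) pair after its prefix
        return make_sentence(
            "ch3",
            [("GENE", "AAA1"), ("interacts", "interact", "VVZ"),
             ("with", "with", "IN"), ("GENE", "BBB2"),
             ("in", "in", "IN"), ("fibroblasts", "fibroblast", "NNS"),
             ("GENE", "CCC3"), ("GENE", "DDD4")],
        )

    def test_mismatched_pair_not_attached(self):
        db = build_sequence_database([self._four_gene_sentence()])
        dets = extract_interactions([INTERACT_RULE], db)
        assert {d.gene_names for d in dets} == {
            ("AAA1", "BBB2"), ("AAA1", "CCC3"), ("AAA1", "DDD4")
        }
        characterize(dets, [self.FIBRO], db)
        assert all(d.characterizations == [] for d in dets)

    def test_loose_mode_attaches_on_co_occurrence(self):
        db = build_sequence_database([self._four_gene_sentence()])
        dets = extract_interactions([INTERACT_RULE], db)
        characterize(dets, [self.FIBRO], db, require_same_pair=False)
        assert all(d.characterizations == [("component", "c2")] for d in dets)


class TestCatalogIO:
    def _rules(self):
        return [
            ExtractionRule("r1", INTERACT_RULE.items, RuleCategory("interaction"),
                           direction="left_to_right"),
            ExtractionRule("r2", ("in@in", "mouse@nn", "AGENE", "AGENE"),
                           RuleCategory("characterization", "organism")),
        ]

    def test_round_trip_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "c1.json", tmp_path / "c2.json"
        write_catalog(self._rules(), p1)
        write_catalog(read_catalog(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert read_catalog(p1) == self._rules()

    def test_interaction_rule_with_one_agene_rejected(self):
        with pytest.raises(CatalogError, match="AGENE"):
            ExtractionRule("bad", ("AGENE", "bind@vvz"), RuleCategory("interaction"))

    def test_unknown_subcategory_rejected(self):
        with pytest.raises(CatalogError, match="subcategory"):
            RuleCategory("characterization", "mood")

    def test_mixed_catalog_loads_into_separate_views(self, tmp_path):
        from seqmine.rules import characterization_rules, interaction_rules

        p = tmp_path / "c.json"
        write_catalog(self._rules(), p)
        cat = read_catalog(p)
        assert [r.rule_id for r in interaction_rules(cat)] == ["r1"]
        assert [r.rule_id for r in characterization_rules(cat)] == ["r2"]

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.json"
        rules = self._rules()
        rules[1] = ExtractionRule("r1", rules[1].items, rules[1].category)
        write_catalog(rules, p)
        with pytest.raises(CatalogError, match="duplicate"):
            read_catalog(p)


class TestDirectionHeuristic:
    @pytest.mark.parametrize(
        "items, expected",
        [
            (("AGENE", "phosphorylate@vvn", "by@in", "AGENE"), "right_to_left"),
            (("activation@nn", "of@in", "AGENE", "by@in", "AGENE"), "right_to_left"),
            (("AGENE", "interact@vvz", "with@in", "AGENE"), "unknown"),
        ],
    )
    def test_examples(self, items, expected):
        assert infer_direction(items) == expected
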