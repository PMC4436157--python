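"""Pair-level scoring, f-score arithmetic, and oracle validation."""

import pytest
from hypothesis import given, strategies as st

from seqmine.corpus import build_sequence_database
from seqmine.evaluate import (
    EvalResult,
    GoldInteraction,
    OracleDB,
    fscore,
    pattern_stats_tsv,
    read_gold_tsv,
    score,
    validate_against_oracle,
    verdicts_tsv,
    write_gold_tsv,
)
from seqmine.rules import DetectedInteraction, ExtractionRule, RuleCategory

from conftest import make_sentence

ASSOC_RULE = ExtractionRule(
    "assoc", ("AGENE", "association@nn", "with@in", "AGENE"),
    RuleCategory("interaction"),
)


def det(sid, a, b, doc=""):
    return DetectedInteraction(doc, sid, tuple(sorted((a, b))), (0, 1))


class TestFscore:
    @pytest.mark.parametrize(
        "p, r, expected",
        [(35.6, 78.6, 49.0), (25.3, 46.5, 32.8), (46.7, 66.8, 55.0)],
    )
    def test_published_rows(self, p, r, expected):
        assert round(fscore(p, r), 1) == expected

    @given(st.floats(min_value=0.1, max_value=100))
    def test_identity_on_equal_arguments(self, x):
        assert fscore(x, x) == pytest.approx(x)

    @given(
        st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100)
    )
    def test_bounds_and_symmetry(self, p, r):
        f = fscore(p, r)
        assert min(p, r) - 1e-9 <= f <= max(p, r) + 1e-9
        assert f == pytest.approx(fscore(r, p))

    def test_zero_convention(self):
        assert fscore(0.0, 0.0) == 0.0


class TestScore:
    def test_perfect(self):
        gold = [GoldInteraction("s1", "A", "B")]
        res = score([det("s1", "A", "B")], gold)
        assert (res.precision, res.recall, res.fscore_value) == (100.0, 100.0, 100.0)

    def test_wrong_pair(self):
        gold = [GoldInteraction("s1", "A", "B")]
        res = score([det("s1", "A", "C")], gold)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_unordered_pair_semantics(self):
        gold = [GoldInteraction("s1", "B", "A")]
        assert score([det("s1", "A", "B")], gold).tp == 1

    def test_hand_counted_fixture(self):
        gold = [GoldInteraction("s1", "A", "B"), GoldInteraction("s1", "C", "D"),
                GoldInteraction("s2", "A", "B"), GoldInteraction("s3", "E", "F")]
        predicted = [det("s1", "A", "B"), det("s2", "A", "B"), det("s2", "X", "Y")]
        res = score(predicted, gold)
        assert (res.tp, res.fp, res.fn) == (2, 1, 2)
        d = res.as_dict()
        assert (d["precision"], d["recall"], d["fscore"]) == (66.7, 50.0, 57.1)

    def test_invariant_to_input_order_and_duplicates(self):
        gold = [GoldInteraction("s1", "A", "B")]
        preds = [det("s1", "A", "B"), det("s1", "B", "A")]
        res = score(preds, gold)
        assert (res.tp, res.fp) == (1, 0)
        # tp+fn = |gold|, tp+fp = |deduplicated predictions|
        assert res.tp + res.fn == 1
        assert res.tp + res.fp == 1

    def test_gold_tsv_round_trip(self, tmp_path):
        gold = [GoldInteraction("s1", "A", "B"), GoldInteraction("s2", "C", "D")]
        p = tmp_path / "gold.tsv"
        write_gold_tsv(gold, p)
        assert read_gold_tsv(p) == gold


class TestOracleValidation:
    def _corpus(self, association_sentences):
        return build_sequence_database(association_sentences)

    def test_published_verdict_split(self, association_sentences):
        """With an oracle holding only (CBL, CRKL, 10204582), the
        association rule's two detections split into one in-oracle and
        one not-in-oracle verdict."""
        oracle = OracleDB.from_records([("CBL", "CRKL", "10204582")])
        stats, verdicts = validate_against_oracle(
            [ASSOC_RULE], self._corpus(association_sentences), oracle
        )
        (s,) = stats
        assert (s.retrieved, s.true_positives) == (2, 1)
        assert s.precision_vs_oracle == pytest.approx(0.5)
        by_pair = {frozenset((v.gene_a, v.gene_b)): v.verdict for v in verdicts}
        assert by_pair[frozenset(("SHC1", "CRKL"))] == "not_in_oracle"
        assert by_pair[frozenset(("CBL", "CRKL"))] == "in_oracle"

    def test_rule_with_no_detections_has_undefined_precision(
        self, association_sentences
    ):
        reveal = ExtractionRule(
            "reveal", ("AGENE", "reveal@vvd", "AGENE"), RuleCategory("interaction")
        )
        stats, _ = validate_against_oracle(
            [reveal], self._corpus(association_sentences), OracleDB(set())
        )
        assert stats[0].retrieved == 0
        assert stats[0].precision_vs_oracle is None
        assert "undefined" in pattern_stats_tsv(stats)

    def test_pmid_must_match(self, association_sentences):
        oracle = OracleDB.from_records([("CBL", "CRKL", "99999999")])
        stats, verdicts = validate_against_oracle(
            [ASSOC_RULE], self._corpus(association_sentences), oracle
        )
        assert stats[0].true_positives == 0
        assert all(v.verdict == "not_in_oracle" for v in verdicts)

    def test_symbol_comparison_case_insensitive(self, association_sentences):
        oracle = OracleDB.from_records([("cbl", "crkl", "10204582")])
        stats, _ = validate_against_oracle(
            [ASSOC_RULE], self._corpus(association_sentences), oracle
        )
        assert stats[0].true_positives == 1

    def test_counts_invariant_to_corpus_shuffling(self, association_sentences):
        oracle = OracleDB.from_records([("CBL", "CRKL", "10204582")])
        fwd = build_sequence_database(association_sentences)
        rev = build_sequence_database(list(reversed(association_sentences)))
        s1, _ = validate_against_oracle([ASSOC_RULE], fwd, oracle)
        s2, _ = validate_against_oracle([ASSOC_RULE], rev, oracle)
        assert s1 == s2

    def test_dedup_to_pair_pmid(self):
        # the same pair detected in two sentences of one abstract counts
        # once (the oracle records interactions, not sentences)
        spec = [("GENE", "AAA1"), ("association", "association", "NN"),
                ("with", "with", "IN"), ("GENE", "BBB2")]
        s1 = make_sentence("r1", spec, doc_id="123")
        s2 = make_sentence("r2", spec, doc_id="123")
        oracle = OracleDB.from_records([("AAA1", "BBB2", "123")])
        stats, verdicts = validate_against_oracle(
            [ASSOC_RULE], build_sequence_database([s1, s2]), oracle
        )
        assert (stats[0].retrieved, stats[0].true_positives) == (1, 1)
        per_sent_stats, per_sent_verdicts = validate_against_oracle(
            [ASSOC_RULE], build_sequence_database([s1, s2]), oracle,
            per_sentence=True,
        )
        assert per_sent_stats == stats  # counts unchanged in audit mode
        assert len(per_sent_verdicts) == 2
        assert "in_oracle" in verdicts_tsv(per_sent_verdicts)

    def test_oracle_tsv_round_trip(self, tmp_path):
        oracle = OracleDB.from_records(
            [("CBL", "CRKL", "10204582"), ("A1", "B2", "77")]
        )
        p = tmp_path / "oracle.tsv"
        oracle.to_tsv(p)
        assert OracleDB.from_tsv(p).triples == oracle.triples
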