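"""Automatic rule validation against an interaction-database oracle.

Applies the rule <AGENE association@nn with@in AGENE> to two hand-tagged
sentences from one abstract (PMID 10204582) and checks each detected
gene pair against a toy BioGRID-style oracle: a detection is a true
positive only when the same unordered pair is recorded for the same
PMID.  One of the two pairs is in the oracle, the other is not — a rule
with mostly-in-oracle detections is likely a good extraction rule.
"""

from seqmine.corpus import GeneMention, TaggedSentence, Token, build_sequence_database
from seqmine.evaluate import OracleDB, pattern_stats_tsv, validate_against_oracle, verdicts_tsv
from seqmine.rules import ExtractionRule, RuleCategory


def sentence(sid, words, genes, pmid):
    tokens = [Token(w, w.lower(), pos) for w, pos in words]
    mentions = []
    for i, (w, pos) in enumerate(words):
        if w in genes:
            mentions.append(GeneMention(i, i + 1, w))
    return TaggedSentence(sid, pmid, tokens, mentions)


s1 = sentence(
    "a", [("phosphorylation", "NN"), ("of", "IN"), ("SHC1", "NP"), ("and", "CC"),
          ("the", "DT"), ("association", "NN"), ("of", "IN"), ("Cbl", "NP"),
          ("with", "IN"), ("CRKL", "NP")],
    genes={"SHC1", "CRKL"}, pmid="10204582",
)
s2 = sentence(
    "b", [("phosphorylation", "NN"), ("of", "IN"), ("CBL", "NP"), ("and", "CC"),
          ("its", "PP$"), ("inducible", "JJ"), ("association", "NN"),
          ("with", "IN"), ("CRKL", "NP")],
    genes={"CBL", "CRKL"}, pmid="10204582",
)

rule = ExtractionRule(
    "assoc", ("AGENE", "association@nn", "with@in", "AGENE"),
    RuleCategory("interaction"),
)
oracle = OracleDB.from_records([("CBL", "CRKL", "10204582")])

stats, verdicts = validate_against_oracle(
    [rule], build_sequence_database([s1, s2]), oracle
)
print(pattern_stats_tsv(stats))
print(verdicts_tsv(verdicts))
# retrieved=2, true_positives=1: the (CBL, CRKL) pair is in the oracle for
# this PMID, the (SHC1, CRKL) pair is not (though it may still be a real,
# merely unrecorded interaction).
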