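import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from seqmine.corpus import GeneMention, TaggedSentence, Token


@pytest.fixture
def sdb1():
    """The four-sequence worked example database."""
    return [tuple("abcd"), tuple("bde"), tuple("acde"), tuple("adcb")]


def make_sentence(sid, spec, doc_id="", final_period=True):
    """Build a TaggedSentence from a compact spec: a list whose entries
    are either (surface, lemma, pos) token triples or ('GENE', symbol)
    gene mentions."""
    tokens, mentions = [], []
    for entry in spec:
        if entry[0] == "GENE":
            sym = entry[1]
            mentions.append(GeneMention(len(tokens), len(tokens) + 1, sym))
            tokens.append(Token(sym, sym.lower(), "np"))
        else:
            surface, lemma, pos = entry
            tokens.append(Token(surface, lemma, pos))
    if final_period:
        tokens.append(Token(".", ".", "sent"))
    return TaggedSentence(sid, doc_id, tokens, mentions)


@pytest.fixture
def myc_stat3_sentences():
    """The two interaction sentences 'MYC interacts with (genes in
    particular) STAT3', hand-tagged."""
    s1 = make_sentence(
        "m1",
        [("GENE", "MYC"), ("interacts", "interact", "VVZ"), ("with", "with", "IN"),
         ("GENE", "STAT3")],
    )
    s2 = make_sentence(
        "m2",
        [("GENE", "MYC"), ("interacts", "interact", "VVZ"), ("with", "with", "IN"),
         ("genes", "gene", "NNS"), ("in", "in", "IN"),
         ("particular", "particular", "JJ"), ("GENE", "STAT3")],
    )
    return [s1, s2]


@pytest.fixture
def association_sentences():
    """Hand-tagged reductions of the two published example abstracts'
    sentences matched by the 'AGENE association with AGENE' rule:
    one yields the pair (SHC1, CRKL), the other (CBL, CRKL); both come
    from PMID 10204582."""
    s1 = make_sentence(
        "t5a",
        [("tyrosine", "tyrosine", "NN"), ("phosphorylation", "phosphorylation", "NN"),
         ("of", "of", "IN"), ("GENE", "SHC1"), ("and", "and", "CC"),
         ("the", "the", "DT"), ("association", "association", "NN"),
         ("of", "of", "IN"), ("Cbl", "cbl", "NP"), ("with", "with", "IN"),
         ("GENE", "CRKL")],
        doc_id="10204582",
    )
    s2 = make_sentence(
        "t5b",
        [("the", "the", "DT"), ("tyrosine", "tyrosine", "NN"),
         ("phosphorylation", "phosphorylation", "NN"), ("of", "of", "IN"),
         ("GENE", "CBL"), ("and", "and", "CC"), ("its", "its", "PP$"),
         ("inducible", "inducible", "JJ"), ("association", "association", "NN"),
         ("with", "with", "IN"), ("GENE", "CRKL")],
        doc_id="10204582",
    )
    return [s1, s2]
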