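"""Seeded synthetic corpora with planted interaction templates.

The generator emulates the statistical structure of a training corpus of
interaction sentences: a pool of gene symbols, a set of pattern-shaped
templates planted into a stated number of sentences each (with random
filler tokens in the gaps), distractor sentences that contain two or
more genes but no template, and background sentences with fewer than two
genes.  Gold annotations record every planted pair.  It does not attempt
fluent English — only the frequency structure the miner consumes.

Characterization templates end with an ``AGENE AGENE`` pair; each of
their sentences embeds one randomly chosen interaction template between
that pair, so the characterization always has a detectable interaction
to attach to.  The filler vocabulary contains no noun or verb items and
is disjoint from all template items, so the linguistic constraints are
exercised cleanly.

Everything is deterministic under the corpus spec's mandatory seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import AGENE, GeneMention, TaggedSentence, Token
from .evaluate import GoldInteraction, OracleDB
from .ner import Lexicon, LexiconEntry
from .rules import RuleCategory

#: non-noun/verb fillers (lemma, pos); disjoint from all default template items
FILLER_VOCAB: tuple[tuple[str, str], ...] = (
    ("a", "dt"), ("an", "dt"), ("this", "dt"), ("these", "dt"),
    ("however", "rb"), ("recently", "rb"), ("also", "rb"), ("further", "rb"),
    ("significantly", "rb"), ("strongly", "rb"), ("directly", "rb"),
    ("markedly", "rb"), ("novel", "jj"), ("specific", "jj"),
    ("functional", "jj"), ("important", "jj"), ("potential", "jj"),
    ("several", "jj"), ("at", "in"), ("on", "in"), ("from", "in"),
    ("during", "in"), ("between", "in"), ("under", "in"),
    ("and", "cc"), ("or", "cc"),
)


class SpecError(ValueError):
    """Infeasible or inconsistent corpus specification."""


@dataclass(frozen=True)
class TemplateSpec:
    name: str
    items: tuple[str, ...]
    category: RuleCategory
    plant_count: int

    def __post_init__(self) -> None:
        if self.plant_count < 0:
            raise SpecError(f"template {self.name!r}: plant_count must be >= 0")
        n_agene = sum(1 for it in self.items if it == AGENE)
        if self.category.kind == "interaction" and n_agene < 2:
            raise SpecError(
                f"interaction template {self.name!r} needs >= 2 AGENE items"
            )
        if self.category.kind == "characterization" and self.items[-2:] != (AGENE, AGENE):
            raise SpecError(
                f"characterization template {self.name!r} must end with AGENE AGENE "
                "(the pair it characterizes)"
            )


@dataclass(frozen=True)
class CorpusSpec:
    n_sentences: int
    templates: tuple[TemplateSpec, ...]
    seed: int
    distractor_rate: float = 0.3
    gene_pool: tuple[str, ...] = ()
    gap_noise_mean: float = 0.8
    allow_self_pairs: bool = False

    def __post_init__(self) -> None:
        planted = sum(t.plant_count for t in self.templates)
        distractors = round(self.distractor_rate * self.n_sentences)
        if planted + distractors > self.n_sentences:
            raise SpecError(
                f"{planted} planted + {distractors} distractor sentences exceed "
                f"n_sentences={self.n_sentences}"
            )
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise SpecError("distractor_rate must be in [0, 1]")


@dataclass
class PlantRecord:
    template: TemplateSpec
    sentence_id: str
    doc_id: str
    pair: tuple[str, str]
    embedded_template: str | None = None  # interaction carried by a char sentence


def default_gene_pool(n: int = 40, seed: int = 0) -> tuple[str, ...]:
    """Deterministic pool of synthetic gene symbols (e.g. 'TQK3')."""
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    seen: set[str] = set()
    letters = np.array(list(string.ascii_uppercase))
    while len(pool) < n:
        sym = "".join(rng.choice(letters, size=3)) + str(rng.integers(1, 10))
        if sym not in seen:
            seen.add(sym)
            pool.append(sym)
    return tuple(pool)


def default_interaction_templates(plant_count: int = 15) -> tuple[TemplateSpec, ...]:
    inter = RuleCategory(kind="interaction")
    raw = {
        "interact": ("AGENE", "interact@vvz", "with@in", "AGENE"),
        "bind": ("AGENE", "bind@vvz", "to@to", "AGENE"),
        "activate": ("AGENE", "activate@vvz", "AGENE"),
        "inhibit": ("AGENE", "inhibit@vvz", "AGENE"),
        "activation_by": ("activation@nn", "of@in", "AGENE", "by@in", "AGENE"),
        "association": ("AGENE", "association@nn", "with@in", "AGENE"),
        "regulate_expression": (
            "AGENE", "regulate@vvz", "expression@nn", "of@in", "AGENE"
        ),
        "play_role": ("AGENE", "play@vvz", "role@nn", "in@in", "AGENE"),
    }
    return tuple(
        TemplateSpec(name, items, inter, plant_count) for name, items in raw.items()
    )


def default_characterization_templates(plant_count: int = 12) -> tuple[TemplateSpec, ...]:
    raw = {
        "possibility": (
            ("the@dt", "possibility@nn", "that@in/that", "AGENE", "AGENE"),
            "assumption",
        ),
        "demonstrated": (
            ("be@vbz", "demonstrate@vvn", "that@in/that", "AGENE", "AGENE"),
            "demonstration",
        ),
        "fibroblasts": (("in@in", "fibroblast@nns", "AGENE", "AGENE"), "component"),
        "mouse": (("in@in", "mouse@nn", "AGENE", "AGENE"), "organism"),
    }
    return tuple(
        TemplateSpec(name, items, RuleCategory("characterization", sub), plant_count)
        for name, (items, sub) in raw.items()
    )


def default_corpus_spec(
    seed: int,
    n_sentences: int = 300,
    interaction_plant_count: int = 15,
    characterization_plant_count: int = 12,
    distractor_rate: float = 0.3,
) -> CorpusSpec:
    """The study conditions used throughout the test suite."""
    return CorpusSpec(
        n_sentences=n_sentences,
        templates=default_interaction_templates(interaction_plant_count)
        + default_characterization_templates(characterization_plant_count),
        seed=seed,
        distractor_rate=distractor_rate,
    )


# ---------------------------------------------------------------------------
# generation


def _item_token(item: str) -> Token:
    lemma, _, pos = item.rpartition("@")
    return Token(surface=lemma, lemma=lemma, pos=pos)


def _gene_token(symbol: str) -> Token:
    return Token(surface=symbol, lemma=symbol.lower(), pos="np")


def _with_fillers(
    core: Sequence[Token], rng: np.random.Generator, mean: float
) -> tuple[list[Token], dict[int, int]]:
    """Insert Poisson(mean) fillers into every gap; returns tokens plus a
    map old token index -> new token index for mention realignment."""
    out: list[Token] = []
    remap: dict[int, int] = {}
    for i, tok in enumerate(core):
        for _ in range(rng.poisson(mean)):
            lemma, pos = FILLER_VOCAB[rng.integers(0, len(FILLER_VOCAB))]
            out.append(Token(lemma, lemma, pos))
        remap[i] = len(out)
        out.append(tok)
    return out, remap


def _instantiate(
    items: Sequence[str],
    genes: Sequence[str],
    rng: np.random.Generator,
    gap_mean: float,
) -> tuple[list[Token], list[GeneMention]]:
    core: list[Token] = []
    gene_positions: list[int] = []
    gi = 0
    for item in items:
        if item == AGENE:
            gene_positions.append(len(core))
            core.append(_gene_token(genes[gi]))
            gi += 1
        else:
            core.append(_item_token(item))
    tokens, remap = _with_fillers(core, rng, gap_mean)
    tokens.append(Token(".", ".", "sent"))
    mentions = [
        GeneMention(remap[p], remap[p] + 1, core[p].surface) for p in gene_positions
    ]
    return tokens, mentions


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[TaggedSentence], list[GoldInteraction], list[PlantRecord]]:
    """Generate (sentences, gold interactions, planted-template registry).

    Sentence composition: every template is instantiated plant_count
    times; round(distractor_rate * n) distractor sentences carry 2-3
    genes and fillers but no template; the remainder are background
    sentences with 0-1 genes (pruned by the >= 2-mention corpus filter).
    Deterministic under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    pool = spec.gene_pool or default_gene_pool(seed=spec.seed)
    interaction_templates = [t for t in spec.templates if t.category.kind == "interaction"]

    def draw_genes(n: int) -> list[str]:
        if spec.allow_self_pairs:
            return [pool[rng.integers(0, len(pool))] for _ in range(n)]
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in idx]

    drafts: list[tuple[TaggedSentence, PlantRecord | None]] = []

    for template in spec.templates:
        for _ in range(template.plant_count):
            embedded: TemplateSpec | None = None
            if template.category.kind == "characterization":
                if not interaction_templates:
                    raise SpecError(
                        "characterization templates require at least one "
                        "interaction template to embed"
                    )
                embedded = interaction_templates[
                    rng.integers(0, len(interaction_templates))
                ]
                items = template.items[:-2] + embedded.items
            else:
                items = template.items
            n_genes = sum(1 for it in items if it == AGENE)
            genes = draw_genes(n_genes)
            tokens, mentions = _instantiate(items, genes, rng, spec.gap_noise_mean)
            sent = TaggedSentence("pending", "pending", tokens, mentions)
            record = PlantRecord(
                template=template,
                sentence_id="pending",
                doc_id="pending",
                pair=(genes[-2], genes[-1]) if template.category.kind == "characterization"
                else _template_pair(template.items, genes),
                embedded_template=embedded.name if embedded else None,
            )
            drafts.append((sent, record))

    n_distractors = round(spec.distractor_rate * spec.n_sentences)
    for _ in range(n_distractors):
        n_genes = int(rng.integers(2, 4))
        genes = draw_genes(n_genes)
        core: list[Token] = [_gene_token(g) for g in genes]
        n_fill = int(rng.integers(4, 9))
        for _ in range(n_fill):
            lemma, pos = FILLER_VOCAB[rng.integers(0, len(FILLER_VOCAB))]
            core.insert(int(rng.integers(0, len(core) + 1)), Token(lemma, lemma, pos))
        core.append(Token(".", ".", "sent"))
        mentions = [
            GeneMention(i, i + 1, tok.surface)
            for i, tok in enumerate(core)
            if tok.pos == "np"
        ]
        drafts.append((TaggedSentence("pending", "pending", core, mentions), None))

    n_background = spec.n_sentences - len(drafts)
    for _ in range(n_background):
        n_genes = int(rng.integers(0, 2))
        core = [_gene_token(g) for g in draw_genes(n_genes)]
        for _ in range(int(rng.integers(3, 8))):
            lemma, pos = FILLER_VOCAB[rng.integers(0, len(FILLER_VOCAB))]
            core.insert(int(rng.integers(0, len(core) + 1)), Token(lemma, lemma, pos))
        core.append(Token(".", ".", "sent"))
        mentions = [
            GeneMention(i, i + 1, tok.surface)
            for i, tok in enumerate(core)
            if tok.pos == "np"
        ]
        drafts.append((TaggedSentence("pending", "pending", core, mentions), None))

    order = rng.permutation(len(drafts))
    sentences: list[TaggedSentence] = []
    gold: list[GoldInteraction] = []
    registry: list[PlantRecord] = []
    for new_idx, old_idx in enumerate(order):
        sent, record = drafts[old_idx]
        sid = f"s{new_idx + 1:04d}"
        pmid = str(10_000_000 + new_idx)
        sent.sentence_id = sid
        sent.doc_id = pmid
        sentences.append(sent)
        if record is not None:
            record.sentence_id = sid
            record.doc_id = pmid
            registry.append(record)
            gold.append(GoldInteraction(sid, record.pair[0], record.pair[1]))
    return sentences, gold, registry


def _template_pair(items: Sequence[str], genes: Sequence[str]) -> tuple[str, str]:
    """The gold pair of an interaction template: its first two AGENEs."""
    return (genes[0], genes[1])


# ---------------------------------------------------------------------------
# lexicon and oracle generation

_STEMS_IN = ("cyclin", "tubulin", "laminin", "ferritin", "keratin", "myosin")
_STEMS_ASE = ("kinase", "ceramidase", "transferase", "phosphatase", "helicase")
_ADJ = ("alkaline", "acidic", "neuronal", "hepatic", "mitochondrial", "nuclear")


def generate_lexicon(n_entries: int, seed: int) -> Lexicon:
    """Synthetic HUGO-like lexicon whose full names exercise every
    significant-part rule (word in -in, word in -ase, word + 'protein')."""
    rng = np.random.default_rng(seed)
    pool = default_gene_pool(n_entries, seed=seed + 1)
    entries = []
    for i, symbol in enumerate(pool[:n_entries]):
        kind = i % 4
        adj = _ADJ[rng.integers(0, len(_ADJ))]
        num = int(rng.integers(1, 9))
        if kind == 0:
            full = f"{adj} {_STEMS_ASE[rng.integers(0, len(_STEMS_ASE))]} {num}"
        elif kind == 1:
            full = f"{_STEMS_IN[rng.integers(0, len(_STEMS_IN))]} {num}"
        elif kind == 2:
            full = f"{symbol[:2]} binding protein {num}"
        else:
            full = f"{adj} factor {num}"  # no significant part
        old = (f"{symbol}OLD",) if rng.random() < 0.5 else ()
        alias = (f"{symbol.lower()}-{num}",) if rng.random() < 0.5 else ()
        entries.append(
            LexiconEntry(
                symbol=symbol,
                old_acronyms=old,
                aliases=alias,
                full_name=full,
            )
        )
    return Lexicon(entries)


def generate_oracle(
    gold: Sequence[GoldInteraction],
    doc_ids: Mapping[str, str],
    coverage_fraction: float,
    seed: int,
) -> OracleDB:
    """Oracle containing a stated fraction of the distinct gold (pair,
    PMID) triples, to exercise in/not-in verdict splits."""
    if not (0.0 <= coverage_fraction <= 1.0):
        raise SpecError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[frozenset[str], str]] = set()
    for g in gold:
        pmid = doc_ids[g.sentence_id]
        key = (frozenset((g.gene_a.upper(), g.gene_b.upper())), pmid)
        if key not in seen:
            seen.add(key)
            triples.append((g.gene_a, g.gene_b, pmid))
    n_keep = round(coverage_fraction * len(triples))
    keep_idx = sorted(rng.choice(len(triples), size=n_keep, replace=False)) if n_keep else []
    return OracleDB.from_records(triples[i] for i in keep_idx)


# ---------------------------------------------------------------------------
# YAML spec loading (CLI `simulate`)


def corpus_spec_from_yaml(text: str) -> CorpusSpec:
    import yaml

    data = yaml.safe_load(text)
    templates = []
    for t in data.get("templates", []):
        templates.append(
            TemplateSpec(
                name=t["name"],
                items=tuple(t["items"]),
                category=RuleCategory(
                    kind=t.get("kind", "interaction"),
                    subcategory=t.get("subcategory"),
                ),
                plant_count=int(t.get("plant_count", 0)),
            )
        )
    return CorpusSpec(
        n_sentences=int(data["n_sentences"]),
        templates=tuple(templates) or default_interaction_templates()
        + default_characterization_templates(),
        seed=int(data["seed"]),
        distractor_rate=float(data.get("distractor_rate", 0.3)),
        gap_noise_mean=float(data.get("gap_noise_mean", 0.8)),
    )
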