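"""Gene-annotated, POS-tagged corpora and their item-sequence encoding.

A training or testing corpus is a set of sentences in which gene mentions
are annotated and every token carries a lemma and a part-of-speech tag
(TreeTagger English tagset codes such as ``nn``, ``vvz``, ``in``).  For
mining and rule matching each sentence is encoded as an ordered *item
sequence*: every gene mention (possibly multi-token) collapses to the
single placeholder item ``AGENE`` and every other token becomes
``lemma@pos`` (both halves lowercased).  Sentence-final punctuation is
retained as an ordinary item (e.g. ``.@sent``).

Three input dialects are supported:

``conll_tsv``
    one token per line, ``surface<TAB>lemma<TAB>pos<TAB>bio``, where the
    BIO column is ``B-GENE:SYMBOL`` / ``I-GENE`` / ``O``; blank line
    between sentences; ``#sid=`` and ``#doc=`` comment headers.
``inline_marker``
    plain text with ``<gene_name=SYMBOL>`` or ``<gene_name="SYMBOL">``
    spans.  Lemma/POS require an external tagging step; a tagger callback
    may be supplied, otherwise tokens default to ``lower(surface)@unk``.
``aimed_xml``
    XML with sentence elements containing protein-mention subelements;
    element names are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

AGENE = "AGENE"

#: signature of an optional tagging adapter: surfaces -> [(lemma, pos), ...]
Tagger = Callable[[Sequence[str]], Sequence[tuple[str, str]]]


class CorpusError(ValueError):
    """Malformed corpus input (parse errors, invalid mention spans)."""


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str

    def __post_init__(self) -> None:
        if not self.surface or not self.pos:
            raise CorpusError(f"token needs non-empty surface and pos: {self!r}")


@dataclass(frozen=True)
class GeneMention:
    """Half-open token span [start, end) naming a gene."""

    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid mention span [{self.start}, {self.end})")


@dataclass
class TaggedSentence:
    sentence_id: str
    doc_id: str
    tokens: list[Token]
    mentions: list[GeneMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        spans = sorted((m.start, m.end) for m in self.mentions)
        for m in self.mentions:
            if m.end > n:
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: mention {m.name!r} span "
                    f"[{m.start}, {m.end}) exceeds {n} tokens"
                )
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: overlapping gene mentions"
                )


@dataclass(frozen=True)
class ItemSequence:
    """Encoded sentence: ordered items plus the AGENE position -> mention map.

    ``doc_id`` and ``mention_names`` are carried along so that detections
    can report gene names and PMIDs without a side lookup.
    """

    sid: str
    items: tuple[str, ...]
    agene_slots: Mapping[int, int]
    doc_id: str = ""
    mention_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class SequenceDatabase:
    sequences: list[ItemSequence]

    def __post_init__(self) -> None:
        sids = [s.sid for s in self.sequences]
        if len(set(sids)) != len(sids):
            raise CorpusError("duplicate sequence ids in database")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def item_lists(self) -> list[tuple[str, ...]]:
        return [s.items for s in self.sequences]


# ---------------------------------------------------------------------------
# encoding


def make_item(lemma: str, pos: str) -> str:
    return f"{lemma.lower()}@{pos.lower()}"


def encode_sentence(sentence: TaggedSentence) -> ItemSequence:
    """Encode one sentence: mentions collapse to AGENE, tokens to lemma@pos."""
    by_start = {m.start: (i, m) for i, m in enumerate(sentence.mentions)}
    items: list[str] = []
    slots: dict[int, int] = {}
    t = 0
    n = len(sentence.tokens)
    while t < n:
        if t in by_start:
            idx, mention = by_start[t]
            slots[len(items)] = idx
            items.append(AGENE)
            t = mention.end
        else:
            tok = sentence.tokens[t]
            items.append(make_item(tok.lemma, tok.pos))
            t += 1
    return ItemSequence(
        sid=sentence.sentence_id,
        items=tuple(items),
        agene_slots=slots,
        doc_id=sentence.doc_id,
        mention_names=tuple(m.name for m in sentence.mentions),
    )


def build_sequence_database(
    sentences: Iterable[TaggedSentence], require_min_mentions: int = 2
) -> SequenceDatabase:
    """Encode sentences with at least ``require_min_mentions`` gene mentions.

    Sentences with fewer mentions are dropped: with fewer than two gene
    names an interaction cannot be expressed without anaphora, which is
    out of scope.
    """
    kept = [
        encode_sentence(s)
        for s in sentences
        if len(s.mentions) >= require_min_mentions
    ]
    return SequenceDatabase(kept)


# ---------------------------------------------------------------------------
# conll_tsv dialect


def _parse_conll(text: str, source: str = "<string>") -> list[TaggedSentence]:
    sentences: list[TaggedSentence] = []
    tokens: list[Token] = []
    mentions: list[GeneMention] = []
    open_mention: list | None = None  # [start, name]
    sid: str | None = None
    doc: str = ""
    auto = 0

    def close_mention(pos: int) -> None:
        nonlocal open_mention
        if open_mention is not None:
            mentions.append(GeneMention(open_mention[0], pos, open_mention[1]))
            open_mention = None

    def flush() -> None:
        nonlocal tokens, mentions, sid, doc, auto, open_mention
        close_mention(len(tokens))
        if tokens:
            auto += 1
            sentences.append(
                TaggedSentence(
                    sentence_id=sid if sid is not None else f"s{auto}",
                    doc_id=doc,
                    tokens=tokens,
                    mentions=mentions,
                )
            )
        tokens, mentions, sid = [], [], None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#sid="):
            sid = line[len("#sid="):].strip()
            continue
        if line.startswith("#doc="):
            doc = line[len("#doc="):].strip()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise CorpusError(f"{source}:{lineno}: expected 4 TAB columns, got {len(cols)}")
        surface, lemma, pos, bio = cols
        if bio == "O":
            close_mention(len(tokens))
        elif bio.startswith("B-GENE:"):
            close_mention(len(tokens))
            open_mention = [len(tokens), bio[len("B-GENE:"):]]
        elif bio == "I-GENE":
            if open_mention is None:
                raise CorpusError(f"{source}:{lineno}: I-GENE without open mention")
        else:
            raise CorpusError(f"{source}:{lineno}: bad BIO tag {bio!r}")
        tokens.append(Token(surface=surface, lemma=lemma or surface, pos=pos))
    flush()
    return sentences


def write_conll(sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    """Serialize sentences in the conll_tsv dialect (round-trips losslessly)."""
    lines: list[str] = []
    for s in sentences:
        lines.append(f"#sid={s.sentence_id}")
        if s.doc_id:
            lines.append(f"#doc={s.doc_id}")
        tags = ["O"] * len(s.tokens)
        for m in s.mentions:
            tags[m.start] = f"B-GENE:{m.name}"
            for i in range(m.start + 1, m.end):
                tags[i] = "I-GENE"
        for tok, tag in zip(s.tokens, tags):
            lines.append(f"{tok.surface}\t{tok.lemma}\t{tok.pos}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# inline_marker dialect

_MARKER_RE = re.compile(r'<gene_name=(?:"(?P<q>[^"]*)"|(?P<u>[^>\s"]+))\s*>')
_WORD_RE = re.compile(r"\w+(?:-\w+)*|[^\w\s]")


def _default_tags(surfaces: Sequence[str]) -> list[tuple[str, str]]:
    out = []
    for i, w in enumerate(surfaces):
        if w == "." and i == len(surfaces) - 1:
            out.append((".", "sent"))
        elif not any(c.isalnum() for c in w):
            out.append((w, "punct"))
        else:
            out.append((w.lower(), "unk"))
    return out


def _parse_inline(
    text: str, tagger: Tagger | None = None, source: str = "<string>"
) -> list[TaggedSentence]:
    sentences: list[TaggedSentence] = []
    for num, line in enumerate(
        (l for l in text.splitlines() if l.strip()), start=1
    ):
        surfaces: list[str] = []
        mentions: list[GeneMention] = []
        pos_ = 0
        for m in _MARKER_RE.finditer(line):
            for w in _WORD_RE.findall(line[pos_:m.start()]):
                surfaces.append(w)
            name = m.group("q") if m.group("q") is not None else m.group("u")
            mentions.append(GeneMention(len(surfaces), len(surfaces) + 1, name))
            surfaces.append(name)
            pos_ = m.end()
        for w in _WORD_RE.findall(line[pos_:]):
            surfaces.append(w)
        tags = list((tagger or _default_tags)(surfaces))
        if len(tags) != len(surfaces):
            raise CorpusError(f"{source}:{num}: tagger returned {len(tags)} tags "
                              f"for {len(surfaces)} tokens")
        # gene tokens are proper nouns regardless of the tagger's guess
        for gm in mentions:
            tags[gm.start] = (surfaces[gm.start].lower(), "np")
        tokens = [Token(s, lem, p) for s, (lem, p) in zip(surfaces, tags)]
        sentences.append(
            TaggedSentence(f"s{num}", "", tokens, mentions)
        )
    return sentences


# ---------------------------------------------------------------------------
# aimed_xml dialect


@dataclass(frozen=True)
class XmlDialect:
    sentence_tag: str = "sentence"
    protein_tag: str = "protein"
    sentence_id_attr: str = "id"
    document_tag: str = "document"
    document_id_attr: str = "id"


def _parse_aimed(
    path: str | Path,
    tagger: Tagger | None = None,
    dialect: XmlDialect | None = None,
) -> list[TaggedSentence]:
    from lxml import etree

    cfg = dialect or XmlDialect()
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message passthrough
        raise CorpusError(f"{path}: {exc}") from exc

    sentences: list[TaggedSentence] = []
    for n, sent_el in enumerate(tree.iter(cfg.sentence_tag), start=1):
        doc_id = ""
        anc = sent_el.getparent()
        while anc is not None:
            if anc.tag == cfg.document_tag:
                doc_id = anc.get(cfg.document_id_attr, "")
                break
            anc = anc.getparent()
        sid = sent_el.get(cfg.sentence_id_attr) or f"s{n}"

        surfaces: list[str] = []
        mentions: list[GeneMention] = []
        if sent_el.text:
            surfaces.extend(_WORD_RE.findall(sent_el.text))
        for child in sent_el:
            if child.tag == cfg.protein_tag:
                name = " ".join("".join(child.itertext()).split())
                words = _WORD_RE.findall(name) or [name]
                start = len(surfaces)
                surfaces.extend(words)
                mentions.append(GeneMention(start, len(surfaces), name))
            else:
                surfaces.extend(_WORD_RE.findall("".join(child.itertext())))
            if child.tail:
                surfaces.extend(_WORD_RE.findall(child.tail))
        tags = list((tagger or _default_tags)(surfaces))
        for gm in mentions:
            for i in range(gm.start, gm.end):
                tags[i] = (surfaces[i].lower(), "np")
        tokens = [Token(s, lem, p) for s, (lem, p) in zip(surfaces, tags)]
        sentences.append(TaggedSentence(sid, doc_id, tokens, mentions))
    return sentences


# ---------------------------------------------------------------------------
# front door

DIALECTS = ("conll_tsv", "inline_marker", "aimed_xml")


def read_tagged_corpus(
    path: str | Path,
    dialect: str,
    tagger: Tagger | None = None,
    xml_dialect: XmlDialect | None = None,
) -> list[TaggedSentence]:
    """Read a gene-annotated corpus file in the named dialect."""
    if dialect not in DIALECTS:
        raise CorpusError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    p = Path(path)
    if dialect == "aimed_xml":
        return _parse_aimed(p, tagger=tagger, dialect=xml_dialect)
    text = p.read_text(encoding="utf-8")
    if dialect == "conll_tsv":
        return _parse_conll(text, source=str(p))
    return _parse_inline(text, tagger=tagger, source=str(p))
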