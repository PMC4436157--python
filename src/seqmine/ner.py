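"""Dictionary-based gene named-entity recognition.

Matching is tiered over a HUGO-like lexicon: official acronym, then old
acronyms, then alias acronyms, then the full official name, and finally
*significant parts* of the full name (with plural forms).  Dictionary
lookup has good precision but poor recall; the later tiers are recall
improvements.  Acronyms that are also common English words (e.g. BAD,
AGO) are flagged ambiguous and match only when written in full
uppercase.

Significant parts of a full name are: a word ending in "in" (insulin), a
word ending in "ase" (transferase), and a word together with a following
"protein" ("binding protein").  Parts shorter than a minimum length are
dropped to avoid matching fragments like "in".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

_TOKEN_RE = re.compile(r"\w+(?:-\w+)*")

_GREEK = frozenset(
    "alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu "
    "xi omicron pi rho sigma tau upsilon phi chi psi omega".split()
)

#: tier names in priority order; also the evidence labels on matches
EVIDENCE_TIERS = (
    "official", "old", "alias", "full_name", "significant_part", "plural_part"
)


class LexiconError(ValueError):
    """Malformed lexicon input."""


@dataclass(frozen=True)
class LexiconEntry:
    symbol: str
    old_acronyms: tuple[str, ...] = ()
    aliases: tuple[str, ...] = ()
    full_name: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.symbol:
            raise LexiconError("lexicon entry with empty symbol")


@dataclass(frozen=True)
class RecognizedGene:
    token_start: int
    token_end: int
    char_start: int
    char_end: int
    canonical_symbol: str
    evidence: str


@dataclass(frozen=True)
class NERConfig:
    enabled_tiers: tuple[str, ...] = EVIDENCE_TIERS
    min_part_length: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.enabled_tiers) - set(EVIDENCE_TIERS)
        if unknown:
            raise ValueError(f"unknown NER tiers: {sorted(unknown)}")


def significant_parts(full_name: str, min_length: int = 5) -> list[str]:
    """Discriminative fragments of a full gene name.

    The literal word "protein" never forms a part on its own (it would
    match every '... protein' name); it only contributes through the
    word-plus-"protein" collocation rule.
    """
    words = [w.lower() for w in _TOKEN_RE.findall(full_name)]
    parts: list[str] = []
    for i, w in enumerate(words):
        if w != "protein" and len(w) >= min_length and (
            w.endswith("in") or w.endswith("ase")
        ):
            parts.append(w)
        if (
            i + 1 < len(words)
            and words[i + 1] == "protein"
            and w != "protein"
            and len(w) >= min_length - 2  # the collocation itself is discriminative
        ):
            parts.append(f"{w} protein")
    return list(dict.fromkeys(parts))


def _plural_forms(part: str) -> list[str]:
    head, _, last = part.rpartition(" ")
    out = []
    for suffix in ("s", "es"):
        plural = last + suffix
        out.append(f"{head} {plural}".strip())
    return out


def _name_key(full_name: str) -> tuple[str, ...]:
    """Full-name match key: lowercased words minus numbers and Greek letters."""
    words = []
    for w in _TOKEN_RE.findall(full_name):
        lw = w.lower()
        if lw.isdigit() or lw in _GREEK:
            continue
        words.append(lw)
    return tuple(words)


@dataclass
class Lexicon:
    entries: list[LexiconEntry]
    _by_symbol: dict[str, LexiconEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_symbol = {}
        for e in self.entries:
            if e.symbol in self._by_symbol:
                raise LexiconError(f"duplicate lexicon symbol {e.symbol!r}")
            self._by_symbol[e.symbol] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, symbol: str) -> LexiconEntry:
        return self._by_symbol[symbol]

    def match_keys(self, config: NERConfig | None = None):
        """(key tokens, symbol, evidence tier, ambiguous) for every enabled tier."""
        cfg = config or NERConfig()
        tiers = set(cfg.enabled_tiers)
        for e in self.entries:
            if "official" in tiers:
                yield (e.symbol.lower(),), e.symbol, "official", e.ambiguous
            if "old" in tiers:
                for a in e.old_acronyms:
                    yield (a.lower(),), e.symbol, "old", e.ambiguous
            if "alias" in tiers:
                for a in e.aliases:
                    yield (a.lower(),), e.symbol, "alias", e.ambiguous
            if "full_name" in tiers and e.full_name:
                key = _name_key(e.full_name)
                if key:
                    yield key, e.symbol, "full_name", False
            if e.full_name and ({"significant_part", "plural_part"} & tiers):
                for part in significant_parts(e.full_name, cfg.min_part_length):
                    if "significant_part" in tiers:
                        yield tuple(part.split()), e.symbol, "significant_part", False
                    if "plural_part" in tiers:
                        for pl in _plural_forms(part):
                            yield tuple(pl.split()), e.symbol, "plural_part", False


def recognize(
    text: str, lexicon: Lexicon, config: NERConfig | None = None
) -> list[RecognizedGene]:
    """Recognize gene names in free text.

    Word-boundary, token-based matching, case-insensitive except for
    ambiguous acronyms which require full uppercase.  Overlaps resolve
    longest-match-first, then leftmost, then by tier priority; the
    result never contains overlapping spans.
    """
    cfg = config or NERConfig()
    tokens = [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    lowered = [t[0].lower() for t in tokens]
    tier_rank = {t: i for i, t in enumerate(EVIDENCE_TIERS)}

    candidates: list[tuple[int, int, int, str, str]] = []
    for key, symbol, tier, ambiguous in lexicon.match_keys(cfg):
        k = len(key)
        for i in range(0, len(tokens) - k + 1):
            if tuple(lowered[i:i + k]) != key:
                continue
            if ambiguous and not all(tokens[i + j][0].isupper() for j in range(k)):
                continue
            candidates.append((i, i + k, tier_rank[tier], symbol, tier))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2], c[3]))
    taken = [False] * len(tokens)
    out: list[RecognizedGene] = []
    for start, end, _rank, symbol, tier in candidates:
        if any(taken[start:end]):
            continue
        for j in range(start, end):
            taken[j] = True
        out.append(
            RecognizedGene(
                token_start=start,
                token_end=end,
                char_start=tokens[start][1],
                char_end=tokens[end - 1][2],
                canonical_symbol=symbol,
                evidence=tier,
            )
        )
    out.sort(key=lambda g: g.token_start)
    return out


def filter_min_genes(
    docs: Iterable[tuple[str, Sequence[RecognizedGene]]], n: int = 2
) -> list[tuple[str, Sequence[RecognizedGene]]]:
    """Keep documents mentioning at least n *distinct* canonical symbols.

    A document whose recognized genes all share one symbol cannot carry a
    gene-gene interaction and is pruned.
    """
    return [
        (doc_id, genes)
        for doc_id, genes in docs
        if len({g.canonical_symbol for g in genes}) >= n
    ]


# ---------------------------------------------------------------------------
# lexicon IO
#
# TSV: symbol<TAB>old1|old2<TAB>alias1|alias2<TAB>full name
# ambiguous list: one acronym per line


def _split_field(raw: str) -> tuple[str, ...]:
    return tuple(x for x in (part.strip() for part in raw.split("|")) if x)


def load_lexicon(
    tsv_path: str | Path, ambiguous_list_path: str | Path | None = None
) -> Lexicon:
    ambiguous: set[str] = set()
    if ambiguous_list_path is not None:
        for line in Path(ambiguous_list_path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                ambiguous.add(line.strip())
    entries = []
    for lineno, line in enumerate(
        Path(tsv_path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise LexiconError(
                f"{tsv_path}:{lineno}: expected 4 TAB columns, got {len(cols)}"
            )
        symbol, old, alias, full = cols
        if not symbol.strip():
            raise LexiconError(f"{tsv_path}:{lineno}: empty symbol")
        entries.append(
            LexiconEntry(
                symbol=symbol.strip(),
                old_acronyms=_split_field(old),
                aliases=_split_field(alias),
                full_name=full.strip(),
                ambiguous=symbol.strip() in ambiguous,
            )
        )
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, tsv_path: str | Path) -> None:
    lines = [
        "\t".join(
            [e.symbol, "|".join(e.old_acronyms), "|".join(e.aliases), e.full_name]
        )
        for e in lexicon.entries
    ]
    Path(tsv_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
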