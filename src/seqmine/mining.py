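"""Frequent sequential pattern mining with per-sequence support.

A *sequence* is an ordered list of atomic items.  A sequence ``s1`` is
included in ``s2`` (``s1 ≼ s2``) when an order-preserving embedding of
``s1`` into ``s2`` exists, with arbitrary gaps between matched positions.
The *support* of a pattern is the number of database sequences that
contain it — a sequence containing a pattern several times still counts
once.  A pattern is *frequent* when its support reaches ``minsup``.

``mine_frequent`` is a prefix-projection (PrefixSpan-style) miner;
``mine_frequent_bruteforce`` enumerates every distinct subsequence of
every database sequence and serves as an independent oracle on small
instances.  Both return the identical canonical result: all non-empty
frequent patterns, sorted by (length, items).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import SequenceDatabase

ItemSeq = Sequence[str]


@dataclass(frozen=True)
class Pattern:
    items: tuple[str, ...]
    support: int | None = field(default=None, compare=False)

    def __str__(self) -> str:
        sup = "" if self.support is None else f" [{self.support}]"
        return "<" + " ".join(self.items) + ">" + sup


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters.

    minsup: absolute count (int >= 1) or relative fraction (0 < f <= 1)
        of database sequences; a fraction f over N sequences means an
        absolute threshold of ceil(f * N) (at least that fraction).
    max_pattern_length: item-count cap on mined patterns; None = unbounded.
        Corpus-scale mining at low minsup produces tens of millions of
        patterns; the default cap keeps desk-scale runs bounded.
    """

    minsup: int | float = 2
    max_pattern_length: int | None = 10

    def __post_init__(self) -> None:
        if isinstance(self.minsup, bool) or (
            isinstance(self.minsup, int) and self.minsup < 1
        ):
            raise ValueError(f"absolute minsup must be >= 1, got {self.minsup}")
        if isinstance(self.minsup, float) and not (0.0 < self.minsup <= 1.0):
            raise ValueError(f"relative minsup must be in (0, 1], got {self.minsup}")
        if self.max_pattern_length is not None and self.max_pattern_length < 1:
            raise ValueError("max_pattern_length must be >= 1 or None")

    def absolute_minsup(self, n_sequences: int) -> int:
        if isinstance(self.minsup, float):
            return max(1, math.ceil(self.minsup * n_sequences))
        return self.minsup


def _as_item_lists(db: SequenceDatabase | Iterable[ItemSeq]) -> list[tuple[str, ...]]:
    if isinstance(db, SequenceDatabase):
        return db.item_lists()
    return [tuple(s) for s in db]


def is_subsequence(s1: ItemSeq, s2: ItemSeq) -> bool:
    """True iff s1 ≼ s2 (order-preserving embedding with arbitrary gaps)."""
    it = iter(s2)
    return all(item in it for item in s1)


def support(pattern: ItemSeq, db: SequenceDatabase | Iterable[ItemSeq]) -> int:
    """Number of database sequences containing the pattern (each counted once)."""
    seqs = _as_item_lists(db)
    return sum(1 for s in seqs if is_subsequence(pattern, s))


def relative_support(pattern: ItemSeq, db: SequenceDatabase | Iterable[ItemSeq]) -> float:
    seqs = _as_item_lists(db)
    if not seqs:
        raise ZeroDivisionError("relative support is undefined on an empty database")
    return sum(1 for s in seqs if is_subsequence(pattern, s)) / len(seqs)


def canonical_sort(patterns: Iterable[Pattern]) -> list[Pattern]:
    """Deterministic order: by length, then lexicographic on items."""
    return sorted(patterns, key=lambda p: (len(p.items), p.items))


# ---------------------------------------------------------------------------
# PrefixSpan


def mine_frequent(
    db: SequenceDatabase | Iterable[ItemSeq], cfg: MiningConfig | None = None
) -> list[Pattern]:
    """All non-empty frequent sequential patterns, canonically ordered.

    Prefix-projection search: the projected database of a prefix is the
    list of (sequence index, next start position) pairs; extending the
    prefix by item x keeps the sequences where x occurs at or after the
    start position.  Support counting is per-sequence by construction.
    """
    cfg = cfg or MiningConfig()
    seqs = _as_item_lists(db)
    minsup = cfg.absolute_minsup(len(seqs))
    cap = cfg.max_pattern_length
    out: list[Pattern] = []

    # positions[i][item] = sorted occurrence positions of item in sequence i
    positions: list[dict[str, list[int]]] = []
    for s in seqs:
        occ: dict[str, list[int]] = {}
        for pos, item in enumerate(s):
            occ.setdefault(item, []).append(pos)
        positions.append(occ)

    import bisect

    def extensions(projection: list[tuple[int, int]]) -> dict[str, list[tuple[int, int]]]:
        """item -> projected database after appending that item."""
        ext: dict[str, list[tuple[int, int]]] = {}
        for si, start in projection:
            for item, occ in positions[si].items():
                j = bisect.bisect_left(occ, start)
                if j < len(occ):
                    ext.setdefault(item, []).append((si, occ[j] + 1))
        return ext

    def grow(prefix: tuple[str, ...], projection: list[tuple[int, int]]) -> None:
        for item, proj in sorted(extensions(projection).items()):
            if len(proj) < minsup:
                continue
            pat = prefix + (item,)
            out.append(Pattern(pat, support=len(proj)))
            if cap is None or len(pat) < cap:
                grow(pat, proj)

    grow((), [(i, 0) for i in range(len(seqs))])
    return canonical_sort(out)


def mine_frequent_bruteforce(
    db: SequenceDatabase | Iterable[ItemSeq], cfg: MiningConfig | None = None
) -> list[Pattern]:
    """Exhaustive oracle: enumerate every distinct subsequence of every
    sequence, count per-sequence support, keep the frequent ones.

    Exponential in sequence length — intended for small test instances
    (around ten sequences of length around ten).
    """
    cfg = cfg or MiningConfig()
    seqs = _as_item_lists(db)
    minsup = cfg.absolute_minsup(len(seqs))
    cap = cfg.max_pattern_length

    candidates: set[tuple[str, ...]] = set()
    for s in seqs:
        subs: set[tuple[str, ...]] = {()}
        for item in s:
            subs |= {sub + (item,) for sub in subs
                     if cap is None or len(sub) < cap}
        candidates |= subs
    candidates.discard(())

    frequent = []
    for cand in candidates:
        sup = sum(1 for s in seqs if is_subsequence(cand, s))
        if sup >= minsup:
            frequent.append(Pattern(cand, support=sup))
    return canonical_sort(frequent)


# ---------------------------------------------------------------------------
# serialization


def write_patterns(patterns: Iterable[Pattern], path: str | Path, fmt: str = "tsv") -> None:
    patterns = list(patterns)
    p = Path(path)
    if fmt == "tsv":
        lines = [" ".join(pat.items) + "\t" + str(pat.support or 0) for pat in patterns]
        p.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "json":
        p.write_text(
            json.dumps(
                [{"items": list(pat.items), "support": pat.support} for pat in patterns],
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown pattern format {fmt!r}")


def read_patterns(path: str | Path) -> list[Pattern]:
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    if text.lstrip().startswith("["):
        return [
            Pattern(tuple(d["items"]), support=d.get("support"))
            for d in json.loads(text)
        ]
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        items_str, _, sup = line.partition("\t")
        out.append(Pattern(tuple(items_str.split()), support=int(sup) if sup else None))
    return out
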