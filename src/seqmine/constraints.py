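"""Linguistic constraint conjunction over frequent patterns.

Frequency alone leaves far too many patterns to curate.  Three further
constraints select gene-interaction candidates:

1. the pattern contains two gene placeholders (``AGENE`` items) — an
   interaction needs two participants;
2. the pattern contains at least one noun or verb — the word that carries
   the interaction semantics;
3. among the patterns passing 1–2 (and frequency), only the *maximal*
   ones under subsequence inclusion are retained, removing redundancy.

The conjunction of the three (plus frequency) is referred to as C_G;
``apply_CG`` computes its satisfaction set from an already
frequency-filtered pattern list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .corpus import AGENE
from .mining import Pattern, canonical_sort, is_subsequence

#: TreeTagger English noun codes all start with n (nn, nns, np, nps) and
#: verb codes with v (vb*, vh*, vv*); the modal md is not a verb here.
DEFAULT_NOUN_PREFIXES = ("n",)
DEFAULT_VERB_PREFIXES = ("v",)


@dataclass(frozen=True)
class ConstraintConfig:
    noun_pos_prefixes: tuple[str, ...] = DEFAULT_NOUN_PREFIXES
    verb_pos_prefixes: tuple[str, ...] = DEFAULT_VERB_PREFIXES
    required_agene_count: int = 2
    #: when True, require exactly required_agene_count AGENE items rather
    #: than at least that many
    exact_agene_count: bool = False

    def __post_init__(self) -> None:
        if not self.noun_pos_prefixes or not self.verb_pos_prefixes:
            raise ValueError("POS prefix sets must be non-empty")
        if self.required_agene_count < 0:
            raise ValueError("required_agene_count must be >= 0")


def constraint_config_from_yaml(text: str) -> ConstraintConfig:
    """Load a config from a YAML block with keys noun_prefixes,
    verb_prefixes, agene_min (and optional agene_exact)."""
    import yaml

    data = yaml.safe_load(text) or {}
    kwargs = {}
    if "noun_prefixes" in data:
        kwargs["noun_pos_prefixes"] = tuple(data["noun_prefixes"])
    if "verb_prefixes" in data:
        kwargs["verb_pos_prefixes"] = tuple(data["verb_prefixes"])
    if "agene_min" in data:
        kwargs["required_agene_count"] = int(data["agene_min"])
    if "agene_exact" in data:
        kwargs["exact_agene_count"] = bool(data["agene_exact"])
    return ConstraintConfig(**kwargs)


def item_pos(item: str) -> str | None:
    """POS half of a lemma@pos item; None for AGENE or malformed items."""
    if item == AGENE or "@" not in item:
        return None
    return item.rsplit("@", 1)[1]


def is_noun_or_verb_item(item: str, cfg: ConstraintConfig | None = None) -> bool:
    cfg = cfg or ConstraintConfig()
    pos = item_pos(item)
    if pos is None or pos == "md":
        return False
    return pos.startswith(tuple(cfg.noun_pos_prefixes) + tuple(cfg.verb_pos_prefixes))


def contains_required_agene(p: Pattern, cfg: ConstraintConfig | None = None) -> bool:
    cfg = cfg or ConstraintConfig()
    n = sum(1 for it in p.items if it == AGENE)
    if cfg.exact_agene_count:
        return n == cfg.required_agene_count
    return n >= cfg.required_agene_count


def contains_noun_or_verb(p: Pattern, cfg: ConstraintConfig | None = None) -> bool:
    cfg = cfg or ConstraintConfig()
    return any(is_noun_or_verb_item(it, cfg) for it in p.items)


def satisfies_structural(p: Pattern, cfg: ConstraintConfig | None = None) -> bool:
    """Both non-maximality structural tests of C_G."""
    cfg = cfg or ConstraintConfig()
    return contains_required_agene(p, cfg) and contains_noun_or_verb(p, cfg)


def maximal_filter(patterns: Iterable[Pattern]) -> list[Pattern]:
    """Patterns that are not a proper subsequence of any other pattern in
    the input (an antichain under ≼).  Duplicates are collapsed first.
    Quadratic pairwise inclusion test; fine at post-constraint scale.
    """
    unique: dict[tuple[str, ...], Pattern] = {}
    for p in patterns:
        prev = unique.get(p.items)
        if prev is None or (p.support or 0) > (prev.support or 0):
            unique[p.items] = p
    pats = list(unique.values())
    keep = []
    for p in pats:
        if not any(
            p.items != q.items and is_subsequence(p.items, q.items) for q in pats
        ):
            keep.append(p)
    return canonical_sort(keep)


def apply_CG(
    frequent: Iterable[Pattern], cfg: ConstraintConfig | None = None
) -> list[Pattern]:
    """SAT(C_G) for an already frequency-filtered pattern list.

    Maximality is computed among the structurally admissible patterns,
    not the full frequent set — an inadmissible superpattern therefore
    cannot shadow an admissible one.
    """
    cfg = cfg or ConstraintConfig()
    admissible = [p for p in frequent if satisfies_structural(p, cfg)]
    return maximal_filter(admissible)
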