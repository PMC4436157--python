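"""Recursive mining: condensing SAT(C_G) to at most k patterns per keyword.

Even after the linguistic constraints, the pattern set is usually too
large for expert review.  The condensation step groups patterns by each
noun or verb item X_i occurring in them (a pattern with m noun/verb
items is duplicated into all m groups), then repeatedly re-mines each
group: the current pattern set is treated as a sequence database and
mined at relative support 1/k, the structural constraints and maximality
are re-applied, and the result replaces the set.  The loop stops as soon
as at most k patterns remain, so the final output cannot exceed n x k
patterns where n is the number of keyword groups.

Inside a round the 1/k fraction over |E| patterns is the absolute
threshold ceil(|E| / k) ("at least a fraction 1/k").  After the first
round every surviving set is an antichain, so its full members have
within-group support 1 < ceil(|E|/k) whenever |E| > k, which forces a
strict shrink toward shared subsequences and guarantees termination;
``max_iterations`` is only a safety net.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from .constraints import (
    ConstraintConfig,
    is_noun_or_verb_item,
    maximal_filter,
    satisfies_structural,
)
from .mining import MiningConfig, Pattern, canonical_sort, is_subsequence, mine_frequent

log = logging.getLogger(__name__)


class RecursiveMiningError(RuntimeError):
    """A keyword group failed to converge within max_iterations."""

    def __init__(self, keyword: str, iterations: int):
        super().__init__(
            f"recursive mining of group {keyword!r} did not converge "
            f"within {iterations} iterations"
        )
        self.keyword = keyword


@dataclass
class KeywordGroup:
    keyword: str
    members: list[Pattern]

    def __post_init__(self) -> None:
        for p in self.members:
            if self.keyword not in p.items:
                raise ValueError(
                    f"pattern {p.items} does not contain group keyword {self.keyword!r}"
                )


@dataclass(frozen=True)
class RecursiveConfig:
    k: int = 4
    max_iterations: int = 25
    #: re-require the group keyword as a round constraint (off by default:
    #: group membership is defined once, on the initial SAT(C_G) set)
    strict_keyword: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.max_iterations < 1:
            raise ValueError("k and max_iterations must be >= 1")


@dataclass
class GroupProvenance:
    """Audit record of one group's reduction."""

    keyword: str
    initial_size: int
    rounds: int
    fallback: bool
    final: list[Pattern] = field(default_factory=list)


def group_by_keyword(
    sat_cg: Iterable[Pattern], cfg: ConstraintConfig | None = None
) -> list[KeywordGroup]:
    """One group per distinct noun/verb item occurring in the pattern set."""
    cfg = cfg or ConstraintConfig()
    groups: dict[str, list[Pattern]] = {}
    for p in sat_cg:
        for kw in dict.fromkeys(it for it in p.items if is_noun_or_verb_item(it, cfg)):
            groups.setdefault(kw, []).append(p)
    return [KeywordGroup(kw, members) for kw, members in sorted(groups.items())]


def _dedupe(patterns: Iterable[Pattern]) -> list[Pattern]:
    seen: dict[tuple[str, ...], Pattern] = {}
    for p in patterns:
        prev = seen.get(p.items)
        if prev is None or (p.support or 0) > (prev.support or 0):
            seen[p.items] = p
    return canonical_sort(seen.values())


def recursive_reduce(
    group: KeywordGroup,
    rcfg: RecursiveConfig | None = None,
    ccfg: ConstraintConfig | None = None,
    provenance: GroupProvenance | None = None,
) -> list[Pattern]:
    """Re-mine a keyword group until at most k patterns remain.

    If a round produces no admissible pattern at all (a degenerate group
    whose members share no frequent admissible subsequence), the k
    highest-support members of the pre-round set are returned and a
    warning is logged.
    """
    rcfg = rcfg or RecursiveConfig()
    ccfg = ccfg or ConstraintConfig()
    if not group.members:
        raise ValueError(f"group {group.keyword!r} is empty")

    current = _dedupe(group.members)
    max_len = max(len(p.items) for p in current)
    for round_no in range(rcfg.max_iterations):
        if len(current) <= rcfg.k:
            if provenance is not None:
                provenance.rounds = round_no
                provenance.final = list(current)
            return current
        minsup = math.ceil(len(current) / rcfg.k)
        mined = mine_frequent(
            [p.items for p in current],
            MiningConfig(minsup=minsup, max_pattern_length=max_len),
        )
        admissible = [p for p in mined if satisfies_structural(p, ccfg)]
        if rcfg.strict_keyword:
            admissible = [
                p for p in admissible if is_subsequence((group.keyword,), p.items)
            ]
        reduced = maximal_filter(admissible)
        if not reduced:
            log.warning(
                "degenerate keyword group %r: no admissible pattern at "
                "support %d/%d; keeping %d highest-support members",
                group.keyword, minsup, len(current), rcfg.k,
            )
            fallback = sorted(
                current, key=lambda p: (-(p.support or 0), len(p.items), p.items)
            )[: rcfg.k]
            result = canonical_sort(fallback)
            if provenance is not None:
                provenance.rounds = round_no + 1
                provenance.fallback = True
                provenance.final = list(result)
            return result
        current = reduced
    raise RecursiveMiningError(group.keyword, rcfg.max_iterations)


def run_recursive_mining(
    sat_cg: Iterable[Pattern],
    rcfg: RecursiveConfig | None = None,
    ccfg: ConstraintConfig | None = None,
    collect_provenance: list[GroupProvenance] | None = None,
) -> list[Pattern]:
    """Union of per-group reductions, deduplicated and canonically ordered.

    The output size is bounded by (number of keyword groups) x k.
    """
    rcfg = rcfg or RecursiveConfig()
    ccfg = ccfg or ConstraintConfig()
    out: list[Pattern] = []
    for group in group_by_keyword(sat_cg, ccfg):
        prov = GroupProvenance(group.keyword, len(group.members), 0, False)
        try:
            out.extend(recursive_reduce(group, rcfg, ccfg, provenance=prov))
        except RecursiveMiningError:
            raise
        if collect_provenance is not None:
            collect_provenance.append(prov)
    return _dedupe(out)
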