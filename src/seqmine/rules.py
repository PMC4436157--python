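"""Extraction rules: categorized patterns applied to sentences.

A validated pattern becomes an *extraction rule* with a category:
``interaction`` rules detect a gene pair in interaction (optionally with
an interaction type such as binding or inhibition, and a direction);
``characterization`` rules attach semantics to an already detected pair,
either a *modality* (assumption, observation, demonstration,
related_work, negation) or a *biological context* (organism, component,
biological_situation, biological_relation).

Matching is gap-tolerant subsequence embedding: zero or more sentence
items may appear between two consecutive rule items, and *every*
embedding is enumerated, not only the first.  ``AGENE`` rule items bind
only to gene-mention positions.  An optional ``max_gap`` limits the
number of skipped items between consecutive matches and an optional
stop-item list ("but", "however" ...) refuses embeddings that jump over
a stop item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .corpus import AGENE, ItemSequence, SequenceDatabase
from .mining import Pattern

MODALITY_SUBCATEGORIES = frozenset(
    {"assumption", "observation", "demonstration", "related_work", "negation"}
)
BIOLOGICAL_CONTEXT_SUBCATEGORIES = frozenset(
    {"organism", "component", "biological_situation", "biological_relation"}
)
CHARACTERIZATION_SUBCATEGORIES = MODALITY_SUBCATEGORIES | BIOLOGICAL_CONTEXT_SUBCATEGORIES

Direction = Literal["left_to_right", "right_to_left", "undirected", "unknown"]
DIRECTIONS = ("left_to_right", "right_to_left", "undirected", "unknown")


class CatalogError(ValueError):
    """Invalid rule catalog content."""


@dataclass(frozen=True)
class RuleCategory:
    kind: Literal["interaction", "characterization"]
    subcategory: str | None = None
    interaction_type: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "interaction":
            if self.subcategory is not None:
                raise CatalogError("interaction rules take interaction_type, not subcategory")
        elif self.kind == "characterization":
            if self.subcategory not in CHARACTERIZATION_SUBCATEGORIES:
                raise CatalogError(
                    f"unknown characterization subcategory {self.subcategory!r}"
                )
            if self.interaction_type is not None:
                raise CatalogError("characterization rules take no interaction_type")
        else:
            raise CatalogError(f"unknown rule kind {self.kind!r}")


@dataclass(frozen=True)
class ExtractionRule:
    rule_id: str
    items: tuple[str, ...]
    category: RuleCategory
    direction: Direction = "unknown"

    def __post_init__(self) -> None:
        if not self.items:
            raise CatalogError(f"rule {self.rule_id!r}: empty item list")
        if self.direction not in DIRECTIONS:
            raise CatalogError(f"rule {self.rule_id!r}: bad direction {self.direction!r}")
        if (
            self.category.kind == "interaction"
            and sum(1 for it in self.items if it == AGENE) < 2
        ):
            raise CatalogError(
                f"interaction rule {self.rule_id!r} must contain >= 2 AGENE items"
            )


@dataclass(frozen=True)
class Match:
    rule_id: str
    sentence_id: str
    embedding: tuple[int, ...]
    #: mention indices bound to the first two AGENE items of the rule
    gene_pair: tuple[int, int]


@dataclass
class DetectedInteraction:
    doc_id: str
    sentence_id: str
    gene_names: tuple[str, str]          # unordered; stored sorted
    mention_pair: tuple[int, int]        # mention indices, sorted
    directed_names: tuple[str, str] | None = None
    supporting_rule_ids: list[str] = field(default_factory=list)
    characterizations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pair_key(self) -> tuple[str, tuple[int, int]]:
        return (self.sentence_id, self.mention_pair)


# ---------------------------------------------------------------------------
# matching


def match_rule(
    rule: ExtractionRule | Pattern,
    seq: ItemSequence,
    max_gap: int | None = None,
    stop_items: frozenset[str] | set[str] | None = None,
) -> list[Match]:
    """All embeddings of a rule's items into an encoded sentence.

    Embeddings are strictly increasing position tuples; AGENE rule items
    bind only to positions carrying a gene mention.  Matches are
    returned in lexicographic order of their embeddings, which makes the
    output deterministic.
    """
    items = rule.items
    rule_id = rule.rule_id if isinstance(rule, ExtractionRule) else "<pattern>"
    agene_rule_positions = [i for i, it in enumerate(items) if it == AGENE]
    matches: list[Match] = []
    n = len(seq.items)

    def blocked(lo: int, hi: int) -> bool:
        if not stop_items:
            return False
        return any(seq.items[j] in stop_items for j in range(lo + 1, hi))

    def walk(ri: int, start: int, emb: list[int]) -> None:
        if ri == len(items):
            if len(agene_rule_positions) >= 2:
                a, b = (emb[agene_rule_positions[0]], emb[agene_rule_positions[1]])
                pair = (seq.agene_slots[a], seq.agene_slots[b])
            else:
                return  # a rule without two genes yields no pair to report
            matches.append(Match(rule_id, seq.sid, tuple(emb), pair))
            return
        want = items[ri]
        for pos in range(start, n):
            if emb:
                gap = pos - emb[-1] - 1
                if max_gap is not None and gap > max_gap:
                    break
                if blocked(emb[-1], pos):
                    break
            if want == AGENE:
                if pos not in seq.agene_slots:
                    continue
            elif seq.items[pos] != want:
                continue
            emb.append(pos)
            walk(ri + 1, pos + 1, emb)
            emb.pop()

    walk(0, 0, [])
    return matches


def _as_rules(rules: Iterable[ExtractionRule | Pattern]) -> list[ExtractionRule]:
    out = []
    for i, r in enumerate(rules):
        if isinstance(r, ExtractionRule):
            out.append(r)
        else:
            out.append(patterns_to_rules([r], kind="interaction", prefix=f"p{i}")[0])
    return out


def patterns_to_rules(
    patterns: Iterable[Pattern],
    kind: str = "interaction",
    subcategory: str | None = None,
    prefix: str = "r",
) -> list[ExtractionRule]:
    """Wrap mined patterns as uncurated rules of one category."""
    cat = RuleCategory(kind=kind, subcategory=subcategory)  # type: ignore[arg-type]
    return [
        ExtractionRule(rule_id=f"{prefix}{i:03d}", items=tuple(p.items), category=cat)
        for i, p in enumerate(patterns, start=1)
    ]


def extract_interactions(
    rules: Sequence[ExtractionRule],
    corpus: SequenceDatabase | Iterable[ItemSequence],
    max_gap: int | None = None,
    stop_items: frozenset[str] | set[str] | None = None,
) -> list[DetectedInteraction]:
    """Detected interactions: one per distinct (sentence, unordered
    mention pair) with at least one rule match; supporting rules
    accumulate.  Output order is deterministic and independent of rule
    and corpus ordering.
    """
    for r in rules:
        if r.category.kind != "interaction":
            raise CatalogError(f"rule {r.rule_id!r} is not an interaction rule")
    found: dict[tuple[str, tuple[int, int]], DetectedInteraction] = {}
    for seq in corpus:
        for rule in rules:
            for m in match_rule(rule, seq, max_gap=max_gap, stop_items=stop_items):
                a, b = m.gene_pair
                if a == b:
                    continue  # unreachable: AGENE slots are distinct positions
                key = (seq.sid, tuple(sorted((a, b))))
                det = found.get(key)
                if det is None:
                    names = (seq.mention_names[a], seq.mention_names[b])
                    det = DetectedInteraction(
                        doc_id=seq.doc_id,
                        sentence_id=seq.sid,
                        gene_names=tuple(sorted(names)),  # type: ignore[arg-type]
                        mention_pair=key[1],
                    )
                    found[key] = det
                if rule.rule_id not in det.supporting_rule_ids:
                    det.supporting_rule_ids.append(rule.rule_id)
                if det.directed_names is None and rule.direction != "unknown":
                    names = (seq.mention_names[a], seq.mention_names[b])
                    if rule.direction == "left_to_right":
                        det.directed_names = names
                    elif rule.direction == "right_to_left":
                        det.directed_names = (names[1], names[0])
    for det in found.values():
        det.supporting_rule_ids.sort()
    return [found[k] for k in sorted(found)]


def characterize(
    interactions: Sequence[DetectedInteraction],
    char_rules: Sequence[ExtractionRule],
    corpus: SequenceDatabase | Iterable[ItemSequence],
    max_gap: int | None = None,
    require_same_pair: bool = True,
) -> list[DetectedInteraction]:
    """Attach characterizations to already detected interactions.

    A characterization rule attaches to an interaction iff it matches the
    same sentence and (by default) its first two AGENE bindings are the
    interaction's mention pair.  With ``require_same_pair=False`` mere
    co-occurrence in the sentence suffices (looser reading).
    """
    for r in char_rules:
        if r.category.kind != "characterization":
            raise CatalogError(f"rule {r.rule_id!r} is not a characterization rule")
    by_sid = {seq.sid: seq for seq in corpus}
    for det in interactions:
        seq = by_sid.get(det.sentence_id)
        if seq is None:
            continue
        for rule in char_rules:
            for m in match_rule(rule, seq, max_gap=max_gap):
                if require_same_pair and tuple(sorted(m.gene_pair)) != det.mention_pair:
                    continue
                tag = (rule.category.subcategory or "", rule.rule_id)
                if tag not in det.characterizations:
                    det.characterizations.append(tag)
                break
    return list(interactions)


# ---------------------------------------------------------------------------
# direction heuristic (opt-in curation aid)


def infer_direction(items: Sequence[str]) -> Direction:
    """Heuristic direction tag: a passive participle followed by by@in, or
    a nominalization with of@in ... by@in, implies the right gene is the
    agent.  Everything else stays unknown; curation overrides."""
    toks = list(items)
    for i, it in enumerate(toks):
        if it.endswith("@vvn") and "by@in" in toks[i + 1:]:
            return "right_to_left"
        if it.endswith("@nn") and "of@in" in toks[i + 1:]:
            rest = toks[i + 1:]
            if "by@in" in rest[rest.index("of@in") + 1:]:
                return "right_to_left"
    return "unknown"


# ---------------------------------------------------------------------------
# catalog IO


def write_catalog(rules: Iterable[ExtractionRule], path: str | Path) -> None:
    payload = {
        "rules": [
            {
                "id": r.rule_id,
                "items": list(r.items),
                "kind": r.category.kind,
                "subcategory": r.category.subcategory,
                "interaction_type": r.category.interaction_type,
                "direction": r.direction,
            }
            for r in rules
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_catalog(path: str | Path) -> list[ExtractionRule]:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CatalogError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "rules" not in payload:
        raise CatalogError(f"{path}: expected a top-level 'rules' list")
    rules = []
    seen_ids: set[str] = set()
    for entry in payload["rules"]:
        rid = entry.get("id")
        if not rid or rid in seen_ids:
            raise CatalogError(f"{path}: missing or duplicate rule id {rid!r}")
        seen_ids.add(rid)
        cat = RuleCategory(
            kind=entry.get("kind"),
            subcategory=entry.get("subcategory"),
            interaction_type=entry.get("interaction_type"),
        )
        rules.append(
            ExtractionRule(
                rule_id=rid,
                items=tuple(entry.get("items") or ()),
                category=cat,
                direction=entry.get("direction", "unknown"),
            )
        )
    return rules


def interaction_rules(rules: Iterable[ExtractionRule]) -> list[ExtractionRule]:
    return [r for r in rules if r.category.kind == "interaction"]


def characterization_rules(rules: Iterable[ExtractionRule]) -> list[ExtractionRule]:
    return [r for r in rules if r.category.kind == "characterization"]


def detections_to_tsv(interactions: Iterable[DetectedInteraction]) -> str:
    """doc_id sentence_id geneA geneB rule_ids characterizations"""
    lines = []
    for d in interactions:
        chars = ";".join(f"{sub}:{rid}" for sub, rid in d.characterizations)
        lines.append(
            "\t".join(
                [
                    d.doc_id,
                    d.sentence_id,
                    d.gene_names[0],
                    d.gene_names[1],
                    ";".join(d.supporting_rule_ids),
                    chars,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
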