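"""Pair-level scoring of detections and oracle validation of rules.

Detection quality is scored at the level of unordered gene-name pairs
per sentence: a true positive is a mentioned gene pair that is both
annotated as interacting and detected.  Precision, recall and the
f-score (harmonic mean, f = 2PR/(P+R)) are reported as percentages,
rounded to one decimal for reporting with unrounded internal arithmetic.

Rules can also be assessed automatically against an interaction
database used as an *oracle* (BioGRID-style triples of two gene symbols
and a PMID): a detection is a true positive iff the same unordered gene
pair is recorded for the same PMID.  Per rule this yields retrieved /
true-positive counts (precision undefined when a rule retrieves
nothing), and per detection an in/not-in verdict with the sentence for
audit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import ItemSequence, SequenceDatabase
from .rules import DetectedInteraction, ExtractionRule, extract_interactions


@dataclass(frozen=True)
class GoldInteraction:
    sentence_id: str
    gene_a: str
    gene_b: str

    @property
    def key(self) -> tuple[str, frozenset[str]]:
        return (self.sentence_id, frozenset((self.gene_a, self.gene_b)))


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fscore_value(self) -> float:
        return fscore(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": round(self.precision, 1),
            "recall": round(self.recall, 1),
            "fscore": round(self.fscore_value, 1),
        }


def fscore(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, on the input scale.

    Zero by convention when both inputs are zero.
    """
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def score(
    predicted: Iterable[DetectedInteraction], gold: Iterable[GoldInteraction]
) -> EvalResult:
    """TP/FP/FN over distinct (sentence, unordered gene-name pair) keys."""
    pred_keys = {(d.sentence_id, frozenset(d.gene_names)) for d in predicted}
    gold_keys = {g.key for g in gold}
    return EvalResult(
        tp=len(pred_keys & gold_keys),
        fp=len(pred_keys - gold_keys),
        fn=len(gold_keys - pred_keys),
    )


# ---------------------------------------------------------------------------
# oracle validation


def _pair_key(a: str, b: str) -> frozenset[str]:
    return frozenset((a.upper(), b.upper()))


@dataclass
class OracleDB:
    """Set of (gene symbol, gene symbol, PMID) interaction triples.

    Symbol comparison is case-insensitive on canonical symbols; the pair
    is unordered.
    """

    triples: set[tuple[frozenset[str], str]]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "OracleDB":
        return cls({(_pair_key(a, b), str(pmid)) for a, b, pmid in records})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OracleDB":
        records = []
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(f"{path}:{lineno}: expected geneA<TAB>geneB<TAB>pmid")
            records.append((cols[0], cols[1], cols[2]))
        return cls.from_records(records)

    def to_tsv(self, path: str | Path) -> None:
        lines = sorted(
            "\t".join([*sorted(pair), pmid]) for pair, pmid in self.triples
        )
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")

    def __contains__(self, item: tuple[str, str, str]) -> bool:
        a, b, pmid = item
        return (_pair_key(a, b), str(pmid)) in self.triples

    def __len__(self) -> int:
        return len(self.triples)


@dataclass(frozen=True)
class PatternStats:
    rule_id: str
    retrieved: int
    true_positives: int

    @property
    def precision_vs_oracle(self) -> float | None:
        """Fraction of retrieved interactions present in the oracle;
        None (undefined) when the rule retrieved nothing."""
        if self.retrieved == 0:
            return None
        return self.true_positives / self.retrieved


@dataclass(frozen=True)
class DetectionVerdict:
    rule_id: str
    pmid: str
    gene_a: str
    gene_b: str
    verdict: str  # "in_oracle" | "not_in_oracle"
    sentence_id: str


def validate_against_oracle(
    rules: Sequence[ExtractionRule],
    corpus: SequenceDatabase | Sequence[ItemSequence],
    oracle: OracleDB,
    max_gap: int | None = None,
    per_sentence: bool = False,
) -> tuple[list[PatternStats], list[DetectionVerdict]]:
    """Assess each rule individually against the interaction oracle.

    By default detections are deduplicated to distinct (gene pair, PMID)
    before counting — the oracle records interactions, not sentences.
    ``per_sentence=True`` keeps one verdict row per sentence for audit.
    """
    corpus_list = list(corpus)
    stats: list[PatternStats] = []
    verdicts: list[DetectionVerdict] = []
    for rule in rules:
        detections = extract_interactions([rule], corpus_list, max_gap=max_gap)
        seen: set[tuple[frozenset[str], str]] = set()
        retrieved = 0
        true_pos = 0
        for det in detections:
            key = (_pair_key(*det.gene_names), det.doc_id)
            first = key not in seen
            if first:
                seen.add(key)
                retrieved += 1
            if not first and not per_sentence:
                continue
            hit = (det.gene_names[0], det.gene_names[1], det.doc_id) in oracle
            if first and hit:
                true_pos += 1
            verdicts.append(
                DetectionVerdict(
                    rule_id=rule.rule_id,
                    pmid=det.doc_id,
                    gene_a=det.gene_names[0],
                    gene_b=det.gene_names[1],
                    verdict="in_oracle" if hit else "not_in_oracle",
                    sentence_id=det.sentence_id,
                )
            )
        stats.append(
            PatternStats(rule_id=rule.rule_id, retrieved=retrieved, true_positives=true_pos)
        )
    return stats, verdicts


# ---------------------------------------------------------------------------
# TSV helpers


def read_gold_tsv(path: str | Path) -> list[GoldInteraction]:
    out = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ValueError(f"{path}:{lineno}: expected sentence_id<TAB>geneA<TAB>geneB")
        out.append(GoldInteraction(cols[0], cols[1], cols[2]))
    return out


def write_gold_tsv(gold: Iterable[GoldInteraction], path: str | Path) -> None:
    lines = [f"{g.sentence_id}\t{g.gene_a}\t{g.gene_b}" for g in gold]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def pattern_stats_tsv(stats: Iterable[PatternStats]) -> str:
    """rule_id, retrieved count, true positives, oracle precision."""
    buf = StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["rule_id", "retrieved", "true_positives", "precision"])
    for s in stats:
        prec = "undefined" if s.precision_vs_oracle is None else f"{s.precision_vs_oracle:.3f}"
        writer.writerow([s.rule_id, s.retrieved, s.true_positives, prec])
    return buf.getvalue()


def verdicts_tsv(verdicts: Iterable[DetectionVerdict]) -> str:
    buf = StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["rule_id", "pmid", "gene_a", "gene_b", "verdict", "sentence_id"])
    for v in verdicts:
        writer.writerow([v.rule_id, v.pmid, v.gene_a, v.gene_b, v.verdict, v.sentence_id])
    return buf.getvalue()
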