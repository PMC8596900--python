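"""Evaluation metrics for entity recognition and terminology usability.

Precision = correctly recognized entities / entities recognized by the
system; recall = correctly recognized entities / entities in the expert
reference; F-measure = 2·P·R / (P + R).  Span comparison is exact on
(start, end, type) by default, with a lenient same-type-overlap criterion
behind a flag.  Terminology coverage is the fraction of clinical terms in
a corpus that match (after normalization) a standard or common term
defined in the terminology.

Metrics are computed from unrounded intermediates; rounding to 3 decimals
happens only at display.  A compatibility flag computes F1 from
3-decimal-rounded precision/recall instead, which some published tables
require.  Zero denominators yield NaN (undefined), never 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .alignment import percent_1dp
from .crf_ner import EntitySpan
from .terminology import TerminologyGraph


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, for display parity with printed tables."""
    if math.isnan(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EntityCounts:
    """The three integers all recognition metrics derive from."""

    n_correct: int
    n_predicted: int
    n_gold: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= min(self.n_predicted, self.n_gold):
            raise ValueError(
                f"need 0 <= correct <= min(predicted, gold); got {self}"
            )

    def __add__(self, other: "EntityCounts") -> "EntityCounts":
        return EntityCounts(
            self.n_correct + other.n_correct,
            self.n_predicted + other.n_predicted,
            self.n_gold + other.n_gold,
        )


def precision(counts: EntityCounts) -> float:
    if counts.n_predicted == 0:
        return math.nan
    return counts.n_correct / counts.n_predicted


def recall(counts: EntityCounts) -> float:
    if counts.n_gold == 0:
        return math.nan
    return counts.n_correct / counts.n_gold


def f1(counts: EntityCounts, from_rounded: bool = False) -> float:
    """Harmonic mean of precision and recall.

    ``from_rounded`` computes it from the 3-decimal displayed P and R
    rather than the unrounded values.
    """
    p, r = precision(counts), recall(counts)
    if math.isnan(p) or math.isnan(r):
        return math.nan
    if from_rounded:
        p, r = round3(p), round3(r)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


@dataclass(frozen=True)
class MetricResult:
    precision: float
    recall: float
    f1: float

    def rounded(self) -> "MetricResult":
        return MetricResult(round3(self.precision), round3(self.recall), round3(self.f1))


def metrics(counts: EntityCounts, f1_from_rounded: bool = False) -> MetricResult:
    return MetricResult(
        precision(counts), recall(counts), f1(counts, from_rounded=f1_from_rounded)
    )


# --------------------------------------------------------------------------
# span comparison
# --------------------------------------------------------------------------


def _check_no_overlap(spans: Sequence[EntitySpan], who: str) -> None:
    by_type: dict[str, list[EntitySpan]] = {}
    for sp in spans:
        by_type.setdefault(sp.entity_type, []).append(sp)
    for typ, group in by_type.items():
        group = sorted(group, key=lambda s: (s.start, s.end))
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping {who} spans of type {typ}: {a} / {b}")


@dataclass
class SpanComparison:
    pooled: EntityCounts
    per_type: dict[str, EntityCounts] = field(default_factory=dict)


def compare_spans(
    predicted: Sequence[EntitySpan],
    gold: Sequence[EntitySpan],
    criterion: str = "exact",
) -> SpanComparison:
    """Count correct/predicted/gold entities, per type and pooled.

    ``criterion="exact"`` requires identical (start, end, type);
    ``criterion="lenient"`` accepts any same-type overlap (each gold span
    matched at most once, greedily in position order).
    """
    if criterion not in {"exact", "lenient"}:
        raise ValueError(f"unknown criterion: {criterion!r}")
    _check_no_overlap(predicted, "predicted")
    _check_no_overlap(gold, "gold")
    types = sorted(
        {sp.entity_type for sp in predicted} | {sp.entity_type for sp in gold}
    )
    per_type: dict[str, EntityCounts] = {}
    for typ in types:
        p = sorted((s for s in predicted if s.entity_type == typ),
                   key=lambda s: s.start)
        g = sorted((s for s in gold if s.entity_type == typ), key=lambda s: s.start)
        if criterion == "exact":
            correct = len({(s.start, s.end) for s in p} & {(s.start, s.end) for s in g})
        else:
            used = [False] * len(g)
            correct = 0
            for sp in p:
                for i, gs in enumerate(g):
                    if not used[i] and sp.start < gs.end and gs.start < sp.end:
                        used[i] = True
                        correct += 1
                        break
        per_type[typ] = EntityCounts(correct, len(p), len(g))
    pooled = sum(per_type.values(), EntityCounts(0, 0, 0))
    return SpanComparison(pooled=pooled, per_type=per_type)


# --------------------------------------------------------------------------
# terminology coverage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageResult:
    n_matched: int
    n_total: int

    @property
    def coverage(self) -> float:
        return self.n_matched / self.n_total

    @property
    def percentage(self) -> float:
        return percent_1dp(self.n_matched, self.n_total)


def terminology_coverage(
    clinical_terms: Sequence[str], graph: TerminologyGraph
) -> CoverageResult:
    """Fraction of corpus terms matching a defined standard or common term."""
    if not clinical_terms:
        raise ValueError("empty term list")
    matched = sum(1 for t in clinical_terms if graph.resolve(t))
    return CoverageResult(n_matched=matched, n_total=len(clinical_terms))


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-entity-type metric rows plus optional per-type coverage."""

    counts: dict[str, EntityCounts]
    results: dict[str, MetricResult]
    pooled_counts: EntityCounts
    pooled: MetricResult
    coverage: dict[str, CoverageResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for typ, c in self.counts.items():
            m = self.results[typ].rounded()
            rows.append(
                {
                    "type": typ,
                    "n_correct": c.n_correct,
                    "n_predicted": c.n_predicted,
                    "n_gold": c.n_gold,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
        pm = self.pooled.rounded()
        rows.append(
            {
                "type": "ALL",
                "n_correct": self.pooled_counts.n_correct,
                "n_predicted": self.pooled_counts.n_predicted,
                "n_gold": self.pooled_counts.n_gold,
                "precision": pm.precision,
                "recall": pm.recall,
                "f1": pm.f1,
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")

    def to_json(self) -> str:
        data = {
            "per_type": {
                typ: {
                    "n_correct": c.n_correct,
                    "n_predicted": c.n_predicted,
                    "n_gold": c.n_gold,
                    "precision": self.results[typ].rounded().precision,
                    "recall": self.results[typ].rounded().recall,
                    "f1": self.results[typ].rounded().f1,
                }
                for typ, c in self.counts.items()
            },
            "pooled": {
                "n_correct": self.pooled_counts.n_correct,
                "n_predicted": self.pooled_counts.n_predicted,
                "n_gold": self.pooled_counts.n_gold,
                "precision": self.pooled.rounded().precision,
                "recall": self.pooled.rounded().recall,
                "f1": self.pooled.rounded().f1,
            },
            "coverage": {
                typ: {
                    "n_matched": c.n_matched,
                    "n_total": c.n_total,
                    "percentage": c.percentage,
                }
                for typ, c in self.coverage.items()
            },
        }
        return json.dumps(data, ensure_ascii=False, indent=1, allow_nan=True)


def evaluation_report(
    corpus_pred: Sequence[Sequence[EntitySpan]],
    corpus_gold: Sequence[Sequence[EntitySpan]],
    graph: Optional[TerminologyGraph] = None,
    criterion: str = "exact",
    f1_from_rounded: bool = False,
) -> EvaluationReport:
    """Aggregate span comparison over aligned documents.

    When a terminology graph is given, per-entity-type coverage of the
    gold mention texts is included.
    """
    if len(corpus_pred) != len(corpus_gold):
        raise ValueError(
            f"corpus misalignment: {len(corpus_pred)} predicted documents "
            f"vs {len(corpus_gold)} gold"
        )
    totals: dict[str, EntityCounts] = {}
    for pred, gold in zip(corpus_pred, corpus_gold):
        cmp = compare_spans(pred, gold, criterion=criterion)
        for typ, c in cmp.per_type.items():
            totals[typ] = totals.get(typ, EntityCounts(0, 0, 0)) + c
    results = {
        typ: metrics(c, f1_from_rounded=f1_from_rounded) for typ, c in totals.items()
    }
    pooled_counts = sum(totals.values(), EntityCounts(0, 0, 0))
    report = EvaluationReport(
        counts=totals,
        results=results,
        pooled_counts=pooled_counts,
        pooled=metrics(pooled_counts, f1_from_rounded=f1_from_rounded),
    )
    if graph is not None:
        by_type: dict[str, list[str]] = {}
        for doc in corpus_gold:
            for sp in doc:
                by_type.setdefault(sp.entity_type, []).append(sp.text)
        report.coverage = {
            typ: terminology_coverage(texts, graph)
            for typ, texts in sorted(by_type.items())
        }
    return report
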