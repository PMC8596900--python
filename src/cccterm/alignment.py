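"""Semantic alignment: collapsing surface variants onto standard concepts.

The same clinical notion is written many ways in Chinese records — 血尿
(urine with blood) also appears as 尿血, 小便带血 and 小便时带血; trade
names stand in for generics (艾恒 for 奥沙利铂/oxaliplatin).  Alignment
registers such variants as common terms of one standard concept, after
which normalization maps any of them back to the concept.  The module also
quantifies *mapping rate*: the fraction of an input term list resolvable
against a target terminology (e.g. how many frequently used Chinese terms
have an exact counterpart in another vocabulary).

Matching is exact on normalized surfaces (NFKC, trimmed, Latin
case-folded); fuzzy matching is deliberately out of scope — callers may
pre-expand variants through their own hook.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .terminology import TerminologyGraph


@dataclass(frozen=True)
class SynonymSet:
    canonical: str  # concept_id
    variants: frozenset[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("variant set must be non-empty")


@dataclass
class NormalizationResult:
    """Outcome of single-best normalization.

    ``status`` is ``"matched"`` (exactly one concept), ``"ambiguous"``
    (two or more concepts share the surface) or ``"none"``.
    """

    surface: str
    status: str
    concept_id: Optional[str] = None
    candidates: list[str] = field(default_factory=list)


def percent_1dp(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (35/72 → 48.6)."""
    pct = Decimal(numerator * 100) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MappingReport:
    n_input: int
    n_mapped: int
    unmapped: list[str]

    @property
    def rate(self) -> float:
        return self.n_mapped / self.n_input

    @property
    def percentage(self) -> float:
        return percent_1dp(self.n_mapped, self.n_input)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_mapped": self.n_mapped,
                "rate": self.rate,
                "percentage": self.percentage,
                "unmapped": self.unmapped,
            },
            ensure_ascii=False,
            indent=1,
        )

    def __str__(self) -> str:
        return (
            f"{self.n_mapped} of {self.n_input} terms mapped "
            f"({self.percentage}%); {len(self.unmapped)} unmapped"
        )


def register_synonyms(
    graph: TerminologyGraph,
    concept_id: str,
    variants: Iterable[str],
    source: str = "alignment",
) -> TerminologyGraph:
    """Attach every variant as a common term of ``concept_id``.

    Variants equal to the concept's preferred label are skipped (the
    standard entry already covers them); an empty variant set is a no-op.
    """
    concept = graph.concepts.get(concept_id)
    if concept is None:
        raise ValueError(f"unknown concept: {concept_id!r}")
    for surface in variants:
        if surface == concept.preferred_label:
            continue
        graph.add_common_term(surface, concept_id, source=source)
    return graph


def normalize_term(graph: TerminologyGraph, surface: str) -> NormalizationResult:
    """Single-best wrapper over resolve: unique concept, ambiguity, or none."""
    candidates = graph.resolve(surface)
    if not candidates:
        return NormalizationResult(surface, "none")
    if len(candidates) > 1:
        return NormalizationResult(surface, "ambiguous", candidates=candidates)
    return NormalizationResult(surface, "matched", concept_id=candidates[0])


def mapping_rate(surfaces: Sequence[str], graph: TerminologyGraph) -> MappingReport:
    """How many of ``surfaces`` resolve (to ≥1 concept) in the terminology."""
    if not surfaces:
        raise ValueError("empty surface list")
    unmapped = [s for s in surfaces if not graph.resolve(s)]
    return MappingReport(
        n_input=len(surfaces),
        n_mapped=len(surfaces) - len(unmapped),
        unmapped=unmapped,
    )


# ------------------------------------------------------------------- files


def read_synonym_table(path: str | Path) -> list[SynonymSet]:
    """TSV with columns (canonical_concept_id, variant), one pair per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["canonical", "variant"],
                     dtype=str, keep_default_na=False)
    grouped: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(row.canonical, set()).add(row.variant)
    return [SynonymSet(c, frozenset(v)) for c, v in sorted(grouped.items())]


def write_synonym_table(sets: Sequence[SynonymSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        for v in sorted(s.variants):
            lines.append(f"{s.canonical}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
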