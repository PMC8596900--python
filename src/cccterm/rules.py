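"""Rule-based composition of compound entities.

Chinese clinical entities are often written as a concatenation of two or
more typed parts — e.g. a body part directly followed by a symptom
(阴道 + 出血 → 阴道出血, vaginal bleeding) — which a token-level NER model
recognizes as separate spans.  A :class:`CompoundRule` is an ordered
pattern over entity-type names; applying the rules merges each maximal
match of adjacent spans into one compound span, refining raw NER output.

Matching operates on the entity-type sequence, not on the raw text.
Precedence is deterministic: leftmost match first; among rules matching at
the same left edge the longest pattern wins, then the earlier rule in the
list.  ``max_gap`` tokens may separate consecutive slots (default 0,
contiguous); bridged gap tokens are absorbed into the compound's text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .crf_ner import EntitySpan


@dataclass(frozen=True)
class CompoundRule:
    rule_id: str
    slot_pattern: tuple[str, ...]
    output_type: str
    max_gap: int = 0

    def __post_init__(self) -> None:
        if len(self.slot_pattern) < 2:
            raise ValueError("slot pattern needs at least two entity types")
        if not all(self.slot_pattern) or not self.output_type:
            raise ValueError("entity-type names must be non-empty")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class RuleMatch:
    rule: CompoundRule
    constituents: tuple[EntitySpan, ...]
    result: EntitySpan


def default_rules() -> list[CompoundRule]:
    """The seven default compound patterns.

    Five symptom-style patterns (e.g. body part + symptom → 阴道出血,
    attribute + body part + symptom → 接触性阴道出血) and two
    radiotherapy-style patterns (site/modality + technology →
    盆腔适形放射治疗, 骨盆大野放射治疗).
    """
    sym = "symptom_compound"
    rad = "radiotherapy_compound"
    return [
        CompoundRule("R1", ("body_part", "symptom"), sym),
        CompoundRule("R2", ("attribute", "symptom"), sym),
        CompoundRule("R3", ("body_part", "attribute", "symptom"), sym),
        CompoundRule("R4", ("attribute", "body_part", "symptom"), sym),
        CompoundRule("R5", ("attribute", "body_part", "attribute", "symptom"), sym),
        CompoundRule("R6", ("radiotherapy_site", "radiotherapy_technology"), rad),
        CompoundRule("R7", ("radiation_modality", "radiotherapy_technology"), rad),
    ]


def add_rule(
    rules: list[CompoundRule],
    pattern: Sequence[str],
    output_type: str,
    max_gap: int = 0,
    rule_id: str | None = None,
) -> list[CompoundRule]:
    """Append a user rule; duplicate patterns are rejected."""
    pattern = tuple(pattern)
    if any(r.slot_pattern == pattern for r in rules):
        raise ValueError(f"duplicate pattern: {pattern}")
    if rule_id is None:
        rule_id = f"R{len(rules) + 1}"
    if any(r.rule_id == rule_id for r in rules):
        raise ValueError(f"duplicate rule id: {rule_id!r}")
    rules.append(CompoundRule(rule_id, pattern, output_type, max_gap))
    return rules


def _check_sorted(spans: Sequence[EntitySpan]) -> None:
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping or unsorted spans: {a} / {b}")


def _match_at(
    spans: Sequence[EntitySpan], i: int, rule: CompoundRule
) -> tuple[EntitySpan, ...] | None:
    """Constituents of ``rule`` anchored at span ``i``, or None."""
    out = []
    j = i
    for k, slot in enumerate(rule.slot_pattern):
        if j >= len(spans):
            return None
        sp = spans[j]
        if sp.entity_type != slot:
            return None
        if k > 0 and sp.start - out[-1].end > rule.max_gap:
            return None
        out.append(sp)
        j += 1
    return tuple(out)


def match_rules(
    spans: Sequence[EntitySpan],
    tokens: Sequence[str],
    rules: Sequence[CompoundRule],
) -> tuple[list[EntitySpan], list[RuleMatch]]:
    """Apply rules once, left to right; returns refined spans and matches."""
    spans = sorted(spans, key=lambda s: (s.start, s.end))
    _check_sorted(spans)
    if spans and spans[-1].end > len(tokens):
        raise ValueError("span offsets exceed token sequence")
    result: list[EntitySpan] = []
    matches: list[RuleMatch] = []
    i = 0
    while i < len(spans):
        best: tuple[int, int, int] | None = None  # (-pattern_len, -end, rule_idx)
        best_parts: tuple[EntitySpan, ...] | None = None
        best_rule: CompoundRule | None = None
        for ridx, rule in enumerate(rules):
            parts = _match_at(spans, i, rule)
            if parts is None:
                continue
            key = (-len(rule.slot_pattern), -parts[-1].end, ridx)
            if best is None or key < best:
                best, best_parts, best_rule = key, parts, rule
        if best_parts is None:
            result.append(spans[i])
            i += 1
            continue
        start, end = best_parts[0].start, best_parts[-1].end
        compound = EntitySpan(
            start, end, best_rule.output_type, "".join(tokens[start:end])
        )
        result.append(compound)
        matches.append(RuleMatch(best_rule, best_parts, compound))
        i += len(best_parts)
    return result, matches


def apply_rules(
    spans: Sequence[EntitySpan],
    tokens: Sequence[str],
    rules: Sequence[CompoundRule] | None = None,
) -> list[EntitySpan]:
    """Merge maximal rule matches into compound spans; unmatched spans pass
    through unchanged."""
    if rules is None:
        rules = default_rules()
    refined, _ = match_rules(spans, tokens, rules)
    return refined


# ------------------------------------------------------------------- files


def save_rules(rules: Sequence[CompoundRule], path: str | Path) -> None:
    data = [
        {
            "id": r.rule_id,
            "pattern": list(r.slot_pattern),
            "output": r.output_type,
            "max_gap": r.max_gap,
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(data, ensure_ascii=False, indent=1), "utf-8")


def load_rules(path: str | Path) -> list[CompoundRule]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        CompoundRule(r["id"], tuple(r["pattern"]), r["output"], r.get("max_gap", 0))
        for r in data
    ]
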