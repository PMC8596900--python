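"""Seeded generators for synthetic annotated corpora and toy terminologies.

Real cervical-cancer EMR corpora are not redistributable, so training,
composition, alignment and coverage are exercised on template-generated
clinical-note-like sentences with known gold annotations.  Sentences are
short, character-tokenized Chinese fragments whose entity mentions are
drawn from small typed lexicons seeded with real domain surfaces (阴道,
出血, 接触性, 子宫颈锥形切除术, 血尿 and its variants, ...).  All
randomness flows through one seeded generator; a corpus is a pure function
of (config, seed).

Two knobs shape difficulty: ``noise_rate`` inserts distractor vocabulary
as O-labeled context, and ``variant_rate`` swaps entity mentions for
registered synonym variants (e.g. 血尿 → 小便带血), which lowers
terminology coverage when the variants are not in the terminology.

What this emulates — and what it does not: the generated text has the
local structure of clinical phrases (entity mentions embedded in short
carrier patterns) but none of the long-range discourse, typos, or regional
usage variation of real records; results on it bound what feature
templates can express, not real-world accuracy.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .crf_ner import Corpus, EntitySpan, extract_entities, write_conll
from .rules import CompoundRule, default_rules
from .terminology import DEFAULT_CLASSES, TerminologyGraph

# template parts: ("lit", text) emits O-labeled characters,
# ("ent", type) emits a lexicon mention labeled B-type I-type...
Template = list[tuple[str, str]]

DEFAULT_LEXICONS: dict[str, list[str]] = {
    "body_part": ["阴道", "盆腔", "宫颈", "膀胱"],
    "symptom": ["出血", "疼痛", "瘙痒", "血尿"],
    "attribute": ["接触性", "不规则", "同房后", "持续性"],
    "surgical_procedure": ["子宫颈锥形切除术", "广泛子宫切除术"],
    "negation": ["无", "未见"],
}

DEFAULT_TEMPLATES: list[Template] = [
    [("lit", "患者"), ("ent", "attribute"), ("ent", "body_part"), ("ent", "symptom"), ("lit", "三天")],
    [("lit", "查体见"), ("ent", "body_part"), ("ent", "symptom")],
    [("lit", "行"), ("ent", "surgical_procedure"), ("lit", "恢复良好")],
    [("ent", "negation"), ("ent", "body_part"), ("ent", "symptom")],
    [("lit", "自述"), ("ent", "symptom"), ("lit", "明显")],
    [("lit", "患者伴有"), ("ent", "attribute"), ("ent", "symptom")],
]

DEFAULT_DISTRACTORS: list[str] = ["今日复诊", "门诊记录", "既往体健", "随访中"]

#: surface -> real-world variant spellings (synonyms / abbreviations)
DEFAULT_VARIANTS: dict[str, list[str]] = {
    "血尿": ["尿血", "小便带血", "小便时带血"],
    "子宫颈锥形切除术": ["宫颈锥切"],
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_sentences: int = 200
    lexicons: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LEXICONS.items()}
    )
    templates: list[Template] = field(
        default_factory=lambda: [list(t) for t in DEFAULT_TEMPLATES]
    )
    distractors: list[str] = field(default_factory=lambda: list(DEFAULT_DISTRACTORS))
    noise_rate: float = 0.2
    variant_rate: float = 0.0
    variant_table: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VARIANTS.items()}
    )

    def __post_init__(self) -> None:
        for name in ("noise_rate", "variant_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for tmpl in self.templates:
            for kind, value in tmpl:
                if kind == "ent" and not self.lexicons.get(value):
                    raise ValueError(f"empty lexicon for templated type {value!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), ensure_ascii=False, sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


@dataclass
class SyntheticCorpus:
    sequences: Corpus
    manifest: dict
    #: for compound cases: the compound span expected after rule application
    expected_compounds: Optional[list[list[EntitySpan]]] = None

    def gold_spans(self) -> list[list[EntitySpan]]:
        return [extract_entities(toks, labs) for toks, labs in self.sequences]

    def write(self, corpus_path: str | Path, manifest_path: str | Path) -> None:
        write_conll(self.sequences, corpus_path)
        Path(manifest_path).write_text(
            json.dumps(self.manifest, ensure_ascii=False, indent=1), encoding="utf-8"
        )


def _emit_mention(
    tokens: list[str],
    labels: list[str],
    surface: str,
    etype: str,
) -> None:
    chars = list(surface)
    tokens.extend(chars)
    labels.extend([f"B-{etype}"] + [f"I-{etype}"] * (len(chars) - 1))


def _emit_literal(tokens: list[str], labels: list[str], text: str) -> None:
    tokens.extend(list(text))
    labels.extend(["O"] * len(text))


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate ``n_sentences`` character-tokenized sentences with BIO gold."""
    rng = random.Random(config.seed)
    sequences: Corpus = []
    counts: dict[str, int] = {}
    for _ in range(config.n_sentences):
        template = rng.choice(config.templates)
        tokens: list[str] = []
        labels: list[str] = []
        if config.distractors and rng.random() < config.noise_rate:
            _emit_literal(tokens, labels, rng.choice(config.distractors))
        for kind, value in template:
            if kind == "lit":
                _emit_literal(tokens, labels, value)
            else:
                surface = rng.choice(config.lexicons[value])
                variants = config.variant_table.get(surface)
                if variants and rng.random() < config.variant_rate:
                    surface = rng.choice(variants)
                _emit_mention(tokens, labels, surface, value)
                counts[value] = counts.get(value, 0) + 1
        sequences.append((tokens, labels))
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_sentences": len(sequences),
        "n_tokens": sum(len(t) for t, _ in sequences),
        "entity_counts": dict(sorted(counts.items())),
    }
    return SyntheticCorpus(sequences=sequences, manifest=manifest)


# --------------------------------------------------------------------------
# toy terminology
# --------------------------------------------------------------------------

#: example (standard concept, common-term variants) pairs per class, drawn
#: from real domain usage, used before generated filler concepts
_EXAMPLE_CONCEPTS: dict[str, list[tuple[str, list[str]]]] = {
    "临床表现": [("血尿", ["尿血", "小便带血", "小便时带血"])],
    "治疗": [
        ("子宫颈锥形切除术", ["宫颈锥切"]),
        ("奥沙利铂", ["艾恒"]),
    ],
    "影像学检查": [("盆腔磁共振成像", ["盆腔MRI"])],
    "复发与转移": [("侵犯阴道壁", ["累及阴道壁", "阴道受累", "阴道受侵"])],
}


@dataclass
class ToyTerminologyConfig:
    classes: tuple[str, ...] = DEFAULT_CLASSES
    standard_per_class: int = 3
    common_per_class: int = 3
    max_level: int = 3
    include_examples: bool = True
    include_assertions: bool = True

    def __post_init__(self) -> None:
        if self.standard_per_class < 1:
            raise ValueError("each class needs at least its root concept")
        if not 1 <= self.max_level <= 6:
            raise ValueError("max_level must be within the 6-level bound")


def generate_toy_terminology(
    config: ToyTerminologyConfig | None = None,
) -> TerminologyGraph:
    """Build a small valid terminology with known per-class statistics.

    One root per class (the class name itself is its standard term), then
    ``standard_per_class - 1`` descendants chained up to ``max_level``
    deep, and ``common_per_class`` common terms per class.  Example
    concepts (血尿 with its variants, 宫颈锥切, 盆腔MRI, ...) fill the
    first child slots of their classes when enabled.
    """
    cfg = config or ToyTerminologyConfig()
    graph = TerminologyGraph(classes=cfg.classes)
    for cls in cfg.classes:
        root = graph.add_concept(cls, top_class=cls, source="toy")
        examples = list(_EXAMPLE_CONCEPTS.get(cls, ())) if cfg.include_examples else []
        concepts = [root]
        pending_commons: list[tuple[str, str]] = []  # (concept_id, surface)
        for i in range(cfg.standard_per_class - 1):
            parent = concepts[-1] if concepts[-1].level < cfg.max_level else root
            if examples:
                label, commons = examples.pop(0)
            else:
                label, commons = f"{cls}概念{i + 1}", []
            concept = graph.add_concept(label, parent_id=parent.concept_id, source="toy")
            concepts.append(concept)
            pending_commons.extend((concept.concept_id, s) for s in commons)
        # exactly common_per_class common terms: example variants first,
        # generated fillers after, spread round-robin over the class
        pending_commons = pending_commons[: cfg.common_per_class]
        j = 0
        while len(pending_commons) < cfg.common_per_class:
            target = concepts[j % len(concepts)]
            j += 1
            pending_commons.append((target.concept_id, f"{cls}变体{j}"))
        for cid, surface in pending_commons:
            graph.add_common_term(surface, cid, source="toy")
    if cfg.include_assertions and cfg.standard_per_class >= 2:
        ids = {c.preferred_label: c.concept_id for c in graph.concepts.values()}
        if "血尿" in ids and "奥沙利铂" in ids:
            graph.add_relation(ids["奥沙利铂"], "Drug_therapy_of", ids["血尿"])
            graph.add_attribute(ids["血尿"], "Severity", "中度")
    return graph


# --------------------------------------------------------------------------
# compound-entity cases
# --------------------------------------------------------------------------

COMPOUND_LEXICONS: dict[str, list[str]] = {
    "body_part": ["阴道", "宫颈"],
    "symptom": ["出血", "疼痛"],
    "attribute": ["接触性", "不规则", "同房后"],
    "radiotherapy_site": ["盆腔", "宫旁"],
    "radiotherapy_technology": ["适形放射治疗", "放射治疗"],
    "radiation_modality": ["骨盆大野", "大野"],
}


@dataclass
class CompoundCaseConfig:
    seed: int = 0
    n_sentences: int = 50
    lexicons: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in COMPOUND_LEXICONS.items()}
    )
    #: probability that a 1-token connector is inserted between two slots
    gap_rate: float = 0.0
    gap_connector: str = "伴"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_rate <= 1.0:
            raise ValueError("gap_rate must be in [0, 1]")


def generate_compound_cases(
    config: CompoundCaseConfig | None = None,
    rules: Sequence[CompoundRule] | None = None,
) -> SyntheticCorpus:
    """Sentences whose gold spans are rule constituents, with the expected
    compound span recorded as a side channel.

    When ``gap_rate`` is positive, a connector token may separate two
    slots; the expected compound then assumes a rule with ``max_gap >= 1``
    (the connector is absorbed into the compound text).
    """
    cfg = config or CompoundCaseConfig()
    if rules is None:
        rules = default_rules()
    for rule in rules:
        for slot in rule.slot_pattern:
            if not cfg.lexicons.get(slot):
                raise ValueError(f"empty lexicon for rule slot type {slot!r}")
    rng = random.Random(cfg.seed)
    sequences: Corpus = []
    expected: list[list[EntitySpan]] = []
    counts: dict[str, int] = {}
    for _ in range(cfg.n_sentences):
        rule = rng.choice(list(rules))
        tokens: list[str] = []
        labels: list[str] = []
        _emit_literal(tokens, labels, "出现")
        first_start = len(tokens)
        for k, slot in enumerate(rule.slot_pattern):
            if k > 0 and rng.random() < cfg.gap_rate:
                _emit_literal(tokens, labels, cfg.gap_connector)
            _emit_mention(tokens, labels, rng.choice(cfg.lexicons[slot]), slot)
            counts[slot] = counts.get(slot, 0) + 1
        last_end = len(tokens)
        _emit_literal(tokens, labels, "。")
        sequences.append((tokens, labels))
        expected.append(
            [
                EntitySpan(
                    first_start,
                    last_end,
                    rule.output_type,
                    "".join(tokens[first_start:last_end]),
                )
            ]
        )
    manifest = {
        "seed": cfg.seed,
        "n_sentences": len(sequences),
        "entity_counts": dict(sorted(counts.items())),
    }
    return SyntheticCorpus(
        sequences=sequences, manifest=manifest, expected_compounds=expected
    )
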