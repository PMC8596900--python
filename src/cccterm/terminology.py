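"""Data model for a common clinical terminology.

A :class:`TerminologyGraph` holds *standard concepts* (the canonical,
preferred representation of a clinical notion, e.g. 子宫颈锥形切除术 /
conization of cervix) arranged in a forest of at most six levels under a
configurable set of top-level classes, plus *common terms* — real-world
surface variants, abbreviations and trade names (e.g. 宫颈锥切) mapped onto
standard concepts.  Relations between concepts and concept attributes are
drawn from configurable registries.

Surfaces are indexed after normalization (NFKC, whitespace trim, Latin
case-fold) so that e.g. ``盆腔MRI``, ``盆腔mri`` and the full-width
``盆腔ＭＲＩ`` all resolve to the same concept.  CJK text is unaffected by
case-folding.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

SCHEMA_VERSION = "1.0"

MAX_DEPTH = 6

#: The 11 default top-level classes of the terminology.
DEFAULT_CLASSES: tuple[str, ...] = (
    "临床表现",  # clinical manifestation
    "人口学信息",  # demographic information
    "分期",  # stage
    "复发与转移",  # recurrence and metastasis
    "实验室检查",  # laboratory test
    "宫颈癌筛查",  # cervical cancer screening
    "影像学检查",  # imaging examination
    "治疗",  # treatment
    "病因",  # etiology
    "病理",  # pathology
    "随访",  # follow-up
)

#: Default relation registry (16 names).  Only ``Has_staging`` and
#: ``Drug_therapy_of`` are canonical domain relations; the remaining names
#: are plausible placeholders and are expected to be replaced by a
#: project-specific registry.
DEFAULT_RELATIONS: tuple[str, ...] = (
    "Has_staging",
    "Drug_therapy_of",
    "Has_symptom",
    "Has_body_part",
    "Has_pathology",
    "Has_etiology",
    "Treated_by",
    "Surgery_of",
    "Radiotherapy_of",
    "Chemotherapy_of",
    "Has_lab_test",
    "Has_imaging",
    "Screened_by",
    "Recurrence_of",
    "Metastasis_to",
    "Followed_by",
)

#: Default attribute registry (6 names, placeholders).
DEFAULT_ATTRIBUTES: tuple[str, ...] = (
    "Severity",
    "Laterality",
    "Frequency",
    "Duration",
    "Negation_status",
    "Temporal_status",
)


class TerminologyError(ValueError):
    """Raised on operations that would corrupt the terminology."""


def normalize_surface(surface: str) -> str:
    """Normalize a term surface for indexing and lookup.

    NFKC normalization (folds full-width Latin/digits to ASCII), trims
    surrounding whitespace and case-folds Latin letters.  CJK characters
    are returned unchanged.
    """
    return unicodedata.normalize("NFKC", surface).strip().casefold()


@dataclass
class Concept:
    """A standard concept node in the terminology tree."""

    concept_id: str
    preferred_label: str
    top_class: str
    parent_id: Optional[str] = None
    level: int = 1
    definition: Optional[str] = None


@dataclass(frozen=True)
class TermEntry:
    """A surface form attached to a concept.

    ``term_kind`` is ``"standard"`` for the concept's preferred label and
    ``"common"`` for synonyms, abbreviations and trade names.
    """

    surface: str
    term_kind: str  # "standard" | "common"
    concept_id: str
    source: str = ""


@dataclass(frozen=True)
class RelationAssertion:
    subject_id: str
    relation_type: str
    object_id: str


@dataclass(frozen=True)
class AttributeAssertion:
    concept_id: str
    attribute_name: str
    value: str


@dataclass(frozen=True)
class Violation:
    """A single validation finding (data, not an exception)."""

    kind: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def kinds(self) -> set[str]:
        return {v.kind for v in self.violations}


class TerminologyGraph:
    """Forest of standard concepts with synonym entries, relations, attributes.

    Parameters
    ----------
    classes:
        Names of the top-level classes; each root concept's category must be
        one of these.  Defaults to the 11 cervical-cancer classes but is
        configurable so the model generalizes to other diseases.
    relation_registry, attribute_registry:
        Allowed relation / attribute names.
    """

    def __init__(
        self,
        classes: Iterable[str] = DEFAULT_CLASSES,
        relation_registry: Iterable[str] = DEFAULT_RELATIONS,
        attribute_registry: Iterable[str] = DEFAULT_ATTRIBUTES,
    ) -> None:
        self.classes: list[str] = list(classes)
        self.relation_registry: list[str] = list(relation_registry)
        self.attribute_registry: list[str] = list(attribute_registry)
        self.concepts: dict[str, Concept] = {}
        self.term_entries: list[TermEntry] = []
        self.relations: list[RelationAssertion] = []
        self.attributes: list[AttributeAssertion] = []
        # normalized surface -> set of concept_ids (many-to-many allowed)
        self._index: dict[str, set[str]] = {}
        self._id_counter: dict[str, int] = {}

    # ------------------------------------------------------------------ ids
    def new_concept_id(self, top_class: str) -> str:
        """Generate a fresh concept id from a class prefix and a counter."""
        try:
            prefix = f"C{self.classes.index(top_class):02d}"
        except ValueError:
            prefix = "CXX"
        while True:
            self._id_counter[prefix] = self._id_counter.get(prefix, 0) + 1
            cid = f"{prefix}-{self._id_counter[prefix]:04d}"
            if cid not in self.concepts:
                return cid

    # ------------------------------------------------------------- mutation
    def add_concept(
        self,
        preferred_label: str,
        top_class: Optional[str] = None,
        parent_id: Optional[str] = None,
        concept_id: Optional[str] = None,
        definition: Optional[str] = None,
        source: str = "",
    ) -> Concept:
        """Insert a standard concept.

        Roots sit at level 1 and carry their own category as ``top_class``;
        children inherit the parent's class and sit one level below it.
        A standard :class:`TermEntry` equal to the preferred label is
        created automatically.
        """
        if not preferred_label or not preferred_label.strip():
            raise TerminologyError("preferred_label must be non-empty")
        if parent_id is not None:
            parent = self.concepts.get(parent_id)
            if parent is None:
                raise TerminologyError(f"unknown parent concept: {parent_id!r}")
            level = parent.level + 1
            if level > MAX_DEPTH:
                raise TerminologyError(
                    f"depth {level} exceeds the {MAX_DEPTH}-level bound"
                )
            top_class = parent.top_class
        else:
            level = 1
            if top_class is None:
                raise TerminologyError("a root concept needs a top_class")
            if top_class not in self.classes:
                raise TerminologyError(f"unknown class: {top_class!r}")
        if concept_id is None:
            concept_id = self.new_concept_id(top_class)
        if concept_id in self.concepts:
            raise TerminologyError(f"duplicate concept_id: {concept_id!r}")
        concept = Concept(
            concept_id=concept_id,
            preferred_label=preferred_label,
            top_class=top_class,
            parent_id=parent_id,
            level=level,
            definition=definition,
        )
        self.concepts[concept_id] = concept
        self.term_entries.append(
            TermEntry(preferred_label, "standard", concept_id, source)
        )
        self._index.setdefault(normalize_surface(preferred_label), set()).add(
            concept_id
        )
        return concept

    def add_common_term(
        self, surface: str, concept_id: str, source: str = ""
    ) -> TermEntry:
        """Register ``surface`` as a common term (synonym) of a concept.

        Idempotent: registering the same surface twice for the same concept
        keeps a single entry.
        """
        if not surface or not surface.strip():
            raise TerminologyError("common term surface must be non-empty")
        if concept_id not in self.concepts:
            raise TerminologyError(f"unknown concept: {concept_id!r}")
        entry = TermEntry(surface, "common", concept_id, source)
        key = normalize_surface(surface)
        already = any(
            e.concept_id == concept_id
            and e.term_kind == "common"
            and normalize_surface(e.surface) == key
            for e in self.term_entries
        )
        if not already:
            self.term_entries.append(entry)
        self._index.setdefault(key, set()).add(concept_id)
        return entry

    def add_relation(
        self, subject_id: str, relation_type: str, object_id: str
    ) -> RelationAssertion:
        if relation_type not in self.relation_registry:
            raise TerminologyError(f"unregistered relation: {relation_type!r}")
        for cid in (subject_id, object_id):
            if cid not in self.concepts:
                raise TerminologyError(f"unknown concept: {cid!r}")
        rel = RelationAssertion(subject_id, relation_type, object_id)
        self.relations.append(rel)
        return rel

    def add_attribute(
        self, concept_id: str, attribute_name: str, value: str
    ) -> AttributeAssertion:
        if attribute_name not in self.attribute_registry:
            raise TerminologyError(f"unregistered attribute: {attribute_name!r}")
        if concept_id not in self.concepts:
            raise TerminologyError(f"unknown concept: {concept_id!r}")
        att = AttributeAssertion(concept_id, attribute_name, value)
        self.attributes.append(att)
        return att

    # --------------------------------------------------------------- lookup
    def resolve(self, surface: str) -> list[str]:
        """All concept ids whose standard or common surface matches.

        Matching is exact on the normalized surface; the result is sorted
        for determinism and empty when the surface is unknown.
        """
        return sorted(self._index.get(normalize_surface(surface), ()))

    def concepts_in_class(self, top_class: str) -> list[Concept]:
        return [c for c in self.concepts.values() if c.top_class == top_class]

    # ----------------------------------------------------------- validation
    def validate(self) -> ValidationReport:
        """Check structural invariants; violations are reported, not raised."""
        report = ValidationReport()
        add = lambda kind, msg: report.violations.append(Violation(kind, msg))

        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            if c.parent_id is not None:
                if c.parent_id not in self.concepts:
                    add("orphan_parent", f"{c.concept_id} -> missing {c.parent_id}")
                else:
                    g.add_edge(c.parent_id, c.concept_id)
        for cycle in nx.simple_cycles(g):
            add("cycle", " -> ".join(cycle))

        for c in self.concepts.values():
            if c.parent_id is None:
                if c.level != 1:
                    add("level", f"root {c.concept_id} at level {c.level} != 1")
                if c.top_class not in self.classes:
                    add("class", f"root {c.concept_id} class {c.top_class!r} unknown")
            else:
                parent = self.concepts.get(c.parent_id)
                if parent is not None and c.level != parent.level + 1:
                    add(
                        "level",
                        f"{c.concept_id} level {c.level} != parent level "
                        f"{parent.level} + 1",
                    )
            if c.level > MAX_DEPTH:
                add("depth", f"{c.concept_id} at level {c.level} > {MAX_DEPTH}")

        roots = [c for c in self.concepts.values() if c.parent_id is None]
        if self.concepts and len(roots) != len(self.classes):
            add(
                "root_count",
                f"{len(roots)} roots != {len(self.classes)} configured classes",
            )

        for e in self.term_entries:
            if e.concept_id not in self.concepts:
                add("dangling_term", f"{e.surface!r} -> missing {e.concept_id}")
        standard_by_concept: dict[str, list[str]] = {}
        for e in self.term_entries:
            if e.term_kind == "standard":
                standard_by_concept.setdefault(e.concept_id, []).append(e.surface)
        for cid, c in self.concepts.items():
            surfaces = standard_by_concept.get(cid, [])
            if surfaces != [c.preferred_label]:
                add(
                    "standard_entry",
                    f"{cid} standard entries {surfaces!r} != [{c.preferred_label!r}]",
                )
        for r in self.relations:
            if r.relation_type not in self.relation_registry:
                add("relation_name", r.relation_type)
            for cid in (r.subject_id, r.object_id):
                if cid not in self.concepts:
                    add("dangling_relation", f"{r.relation_type} -> {cid}")
        for a in self.attributes:
            if a.attribute_name not in self.attribute_registry:
                add("attribute_name", a.attribute_name)
            if a.concept_id not in self.concepts:
                add("dangling_attribute", f"{a.attribute_name} -> {a.concept_id}")

        # index consistency
        expected: dict[str, set[str]] = {}
        for e in self.term_entries:
            expected.setdefault(normalize_surface(e.surface), set()).add(e.concept_id)
        if expected != {k: v for k, v in self._index.items() if v}:
            add("index", "surface index out of sync with term entries")
        return report

    # ------------------------------------------------------------ statistics
    def stats(self) -> pd.DataFrame:
        """Per-class counts of standard and common terms, plus a total row."""
        kinds = {"standard": {}, "common": {}}
        for e in self.term_entries:
            concept = self.concepts.get(e.concept_id)
            if concept is None:
                continue
            kinds[e.term_kind][concept.top_class] = (
                kinds[e.term_kind].get(concept.top_class, 0) + 1
            )
        rows = []
        for cls in self.classes:
            s = kinds["standard"].get(cls, 0)
            c = kinds["common"].get(cls, 0)
            rows.append({"class": cls, "standard": s, "common": c, "total": s + c})
        df = pd.DataFrame(rows).set_index("class")
        df.loc["Total"] = df.sum()
        return df

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "classes": self.classes,
            "relation_registry": self.relation_registry,
            "attribute_registry": self.attribute_registry,
            "concepts": [
                {
                    "id": c.concept_id,
                    "label": c.preferred_label,
                    "class": c.top_class,
                    "parent": c.parent_id,
                    "level": c.level,
                    "definition": c.definition,
                }
                for c in self.concepts.values()
            ],
            "terms": [
                {
                    "surface": e.surface,
                    "kind": e.term_kind,
                    "concept": e.concept_id,
                    "source": e.source,
                }
                for e in self.term_entries
            ],
            "relations": [
                {"subject": r.subject_id, "type": r.relation_type, "object": r.object_id}
                for r in self.relations
            ],
            "attributes": [
                {"concept": a.concept_id, "name": a.attribute_name, "value": a.value}
                for a in self.attributes
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), ensure_ascii=False, indent=1),
            encoding="utf-8",
        )

    @classmethod
    def from_dict(cls, data: dict) -> "TerminologyGraph":
        if not isinstance(data, dict) or "schema_version" not in data:
            raise TerminologyError("not a terminology file (missing schema_version)")
        if data["schema_version"] != SCHEMA_VERSION:
            raise TerminologyError(
                f"schema version {data['schema_version']!r} != {SCHEMA_VERSION!r}"
            )
        graph = cls(
            classes=data.get("classes", DEFAULT_CLASSES),
            relation_registry=data.get("relation_registry", DEFAULT_RELATIONS),
            attribute_registry=data.get("attribute_registry", DEFAULT_ATTRIBUTES),
        )
        for c in data.get("concepts", ()):
            graph.concepts[c["id"]] = Concept(
                concept_id=c["id"],
                preferred_label=c["label"],
                top_class=c["class"],
                parent_id=c.get("parent"),
                level=c["level"],
                definition=c.get("definition"),
            )
        for t in data.get("terms", ()):
            entry = TermEntry(t["surface"], t["kind"], t["concept"], t.get("source", ""))
            graph.term_entries.append(entry)
            graph._index.setdefault(normalize_surface(entry.surface), set()).add(
                entry.concept_id
            )
        for r in data.get("relations", ()):
            graph.relations.append(
                RelationAssertion(r["subject"], r["type"], r["object"])
            )
        for a in data.get("attributes", ()):
            graph.attributes.append(
                AttributeAssertion(a["concept"], a["name"], a["value"])
            )
        return graph

    @classmethod
    def load(cls, path: str | Path) -> "TerminologyGraph":
        try:
            data = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise TerminologyError(f"malformed terminology file: {exc}") from exc
        return cls.from_dict(data)

    def to_tsv(self, path: str | Path) -> None:
        """Export one term per line: surface, kind, concept_id, class, level."""
        rows = []
        for e in self.term_entries:
            c = self.concepts.get(e.concept_id)
            rows.append(
                {
                    "surface": e.surface,
                    "kind": e.term_kind,
                    "concept_id": e.concept_id,
                    "class": c.top_class if c else "",
                    "level": c.level if c else "",
                }
            )
        pd.DataFrame(
            rows, columns=["surface", "kind", "concept_id", "class", "level"]
        ).to_csv(path, sep="\t", index=False, encoding="utf-8")
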