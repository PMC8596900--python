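"""End-to-end orchestration: generate → train → tag → compose → align →
evaluate/coverage, with a run manifest for reproducibility.

Each stage reads and writes files inside one self-describing output
directory; ``manifest.json`` at its root records the configuration hash
and every stage's inputs and outputs, so a run can be audited and repeated
exactly.  Stage outputs are deterministic functions of (config, seed);
wall-clock timestamps are off by default so that identical runs produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import crf_ner, evaluation, rules as rules_mod
from .alignment import mapping_rate, read_synonym_table, register_synonyms
from .crf_ner import extract_entities
from .synthetic import (
    GeneratorConfig,
    ToyTerminologyConfig,
    generate_corpus,
    generate_toy_terminology,
)
from .terminology import TerminologyGraph

logger = logging.getLogger("cccterm")

TOOLKIT_VERSION = "0.1.0"

STAGES = ("gen", "train", "tag", "compose", "align", "eval", "coverage", "stats")

#: which terminology class each synthetic entity type files under
_TYPE_TO_CLASS = {
    "body_part": "临床表现",
    "symptom": "临床表现",
    "attribute": "临床表现",
    "negation": "临床表现",
    "surgical_procedure": "治疗",
}


class PipelineError(RuntimeError):
    """A stage dependency or configuration problem."""


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    n_sentences: int = 200
    test_fraction: float = 0.2
    noise_rate: float = 0.2
    variant_rate: float = 0.0
    sigma2: float = 10.0
    max_iter: int = 200
    tol: float = 1e-5
    criterion: str = "exact"
    rules_path: Optional[str] = None  # extra rules merged with the defaults
    synonyms_path: Optional[str] = None
    log_level: str = "INFO"
    timestamps: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise PipelineError(f"config file {path} must hold a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            seed=self.seed,
            n_sentences=self.n_sentences,
            noise_rate=self.noise_rate,
            variant_rate=self.variant_rate,
        )

    def as_manifest_dict(self) -> dict:
        # out_dir is where the run lives, not what the run is; leaving it
        # out keeps manifests byte-identical across relocated reruns
        data = dataclasses.asdict(self)
        data.pop("out_dir")
        return data

    def hash(self) -> str:
        import hashlib

        payload = json.dumps(self.as_manifest_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class Pipeline:
    """Stage runner bound to one output directory."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=config.log_level)

    # ------------------------------------------------------------ manifest
    @property
    def manifest_path(self) -> Path:
        return self.out / "manifest.json"

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text(encoding="utf-8"))
        return {
            "toolkit_version": TOOLKIT_VERSION,
            "config": self.config.as_manifest_dict(),
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "stages": {},
        }

    def _record(self, stage: str, inputs: list[str], outputs: list[str],
                summary: dict) -> dict:
        manifest = self._load_manifest()
        entry = {"inputs": inputs, "outputs": outputs, "summary": summary}
        if self.config.timestamps:
            entry["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest["stages"][stage] = entry
        self.manifest_path.write_text(
            json.dumps(manifest, ensure_ascii=False, indent=1), encoding="utf-8"
        )
        return entry

    def _require(self, *names: str) -> list[Path]:
        paths = [self.out / n for n in names]
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise PipelineError(
                f"missing stage dependency: {missing}; run the earlier "
                f"stages (gen/train/tag) first"
            )
        return paths

    # -------------------------------------------------------------- stages
    def run_stage(self, name: str) -> dict:
        if name not in STAGES:
            raise PipelineError(f"unknown stage {name!r}; stages are {STAGES}")
        return getattr(self, f"stage_{name}")()

    def run_all(self) -> dict:
        for name in STAGES:
            self.run_stage(name)
        return self._load_manifest()

    def stage_gen(self) -> dict:
        cfg = self.config.generator_config()
        corpus = generate_corpus(cfg)
        n_test = max(1, int(round(len(corpus.sequences) * self.config.test_fraction)))
        test, train = corpus.sequences[:n_test], corpus.sequences[n_test:]
        if not train:
            raise PipelineError("corpus too small to split into train and test")
        crf_ner.write_conll(train, self.out / "corpus_train.tsv")
        crf_ner.write_conll(test, self.out / "corpus_test.tsv")
        (self.out / "corpus_manifest.json").write_text(
            json.dumps(corpus.manifest, ensure_ascii=False, indent=1), "utf-8"
        )
        graph = generate_toy_terminology(ToyTerminologyConfig())
        for etype, surfaces in cfg.lexicons.items():
            cls = _TYPE_TO_CLASS.get(etype, graph.classes[0])
            root = next(
                c for c in graph.concepts.values()
                if c.parent_id is None and c.top_class == cls
            )
            for surface in surfaces:
                if not graph.resolve(surface):
                    graph.add_concept(
                        surface, parent_id=root.concept_id, source="corpus-lexicon"
                    )
        graph.save(self.out / "terminology.json")
        logger.info(
            "gen: %d train / %d test sentences, %d entities, %d concepts",
            len(train), len(test),
            sum(corpus.manifest["entity_counts"].values()), len(graph.concepts),
        )
        return self._record(
            "gen",
            inputs=[],
            outputs=["corpus_train.tsv", "corpus_test.tsv",
                     "corpus_manifest.json", "terminology.json"],
            summary={"n_train": len(train), "n_test": len(test),
                     "entity_counts": corpus.manifest["entity_counts"]},
        )

    def stage_train(self) -> dict:
        (train_path,) = self._require("corpus_train.tsv")
        corpus = crf_ner.read_conll(train_path)
        if not corpus:
            raise PipelineError("empty training corpus")
        lexicon = [s for surfs in self.config.generator_config().lexicons.values()
                   for s in surfs]
        model = crf_ner.train(
            corpus,
            templates=crf_ner.default_templates(lexicon=lexicon),
            sigma2=self.config.sigma2,
            max_iter=self.config.max_iter,
            tol=self.config.tol,
        )
        crf_ner.save_model(model, self.out / "model.json")
        logger.info("train: %d sentences, %d features", len(corpus), model.n_features)
        return self._record(
            "train", ["corpus_train.tsv"], ["model.json"],
            {"n_sentences": len(corpus), "n_features": model.n_features},
        )

    def stage_tag(self) -> dict:
        model_path, test_path = self._require("model.json", "corpus_test.tsv")
        model = crf_ner.load_model(model_path)
        corpus = crf_ner.read_conll(test_path)
        tagged = [(tokens, crf_ner.decode(model, tokens)) for tokens, _ in corpus]
        crf_ner.write_conll(tagged, self.out / "predicted.tsv")
        n_ent = sum(len(extract_entities(t, l)) for t, l in tagged)
        logger.info("tag: %d sentences, %d predicted entities", len(tagged), n_ent)
        return self._record(
            "tag", ["model.json", "corpus_test.tsv"], ["predicted.tsv"],
            {"n_sentences": len(tagged), "n_entities": n_ent},
        )

    def _rules(self) -> list[rules_mod.CompoundRule]:
        rules = rules_mod.default_rules()
        if self.config.rules_path:
            for r in rules_mod.load_rules(self.config.rules_path):
                rules_mod.add_rule(
                    rules, r.slot_pattern, r.output_type, r.max_gap, r.rule_id
                )
        return rules

    def stage_compose(self) -> dict:
        (pred_path,) = self._require("predicted.tsv")
        corpus = crf_ner.read_conll(pred_path)
        rules = self._rules()
        composed = []
        n_compounds = 0
        for tokens, labels in corpus:
            spans = extract_entities(tokens, labels)
            refined, matches = rules_mod.match_rules(spans, tokens, rules)
            n_compounds += len(matches)
            composed.append(
                [
                    {"start": s.start, "end": s.end, "type": s.entity_type,
                     "text": s.text}
                    for s in refined
                ]
            )
        (self.out / "composed.json").write_text(
            json.dumps(composed, ensure_ascii=False, indent=1), "utf-8"
        )
        logger.info("compose: %d compound matches", n_compounds)
        return self._record(
            "compose", ["predicted.tsv"], ["composed.json"],
            {"n_rules": len(rules), "n_compounds": n_compounds},
        )

    def stage_align(self) -> dict:
        (term_path,) = self._require("terminology.json")
        graph = TerminologyGraph.load(term_path)
        n_registered = 0
        if self.config.synonyms_path:
            for syn in read_synonym_table(self.config.synonyms_path):
                register_synonyms(graph, syn.canonical, syn.variants)
                n_registered += len(syn.variants)
        graph.save(self.out / "terminology_aligned.json")
        test = crf_ner.read_conll(self._require("corpus_test.tsv")[0])
        texts = [sp.text for t, l in test for sp in extract_entities(t, l)]
        report = mapping_rate(texts, graph) if texts else None
        if report is not None:
            (self.out / "mapping_report.json").write_text(report.to_json(), "utf-8")
            logger.info("align: %s", report)
        return self._record(
            "align", ["terminology.json", "corpus_test.tsv"],
            ["terminology_aligned.json", "mapping_report.json"],
            {"n_synonyms_registered": n_registered,
             "mapping_percentage": report.percentage if report else None},
        )

    def stage_eval(self) -> dict:
        pred_path, gold_path = self._require("predicted.tsv", "corpus_test.tsv")
        pred = crf_ner.read_conll(pred_path)
        gold = crf_ner.read_conll(gold_path)
        report = evaluation.evaluation_report(
            [extract_entities(t, l) for t, l in pred],
            [extract_entities(t, l) for t, l in gold],
            criterion=self.config.criterion,
        )
        (self.out / "eval_report.json").write_text(report.to_json(), "utf-8")
        report.to_tsv(self.out / "eval_report.tsv")
        pm = report.pooled.rounded()
        logger.info("eval: P=%.3f R=%.3f F1=%.3f", pm.precision, pm.recall, pm.f1)
        return self._record(
            "eval", ["predicted.tsv", "corpus_test.tsv"],
            ["eval_report.json", "eval_report.tsv"],
            {"precision": pm.precision, "recall": pm.recall, "f1": pm.f1},
        )

    def stage_coverage(self) -> dict:
        gold_path, term_path = self._require("corpus_test.tsv", "terminology.json")
        graph = TerminologyGraph.load(
            self.out / "terminology_aligned.json"
            if (self.out / "terminology_aligned.json").exists()
            else term_path
        )
        gold = crf_ner.read_conll(gold_path)
        by_type: dict[str, list[str]] = {}
        for tokens, labels in gold:
            for sp in extract_entities(tokens, labels):
                by_type.setdefault(sp.entity_type, []).append(sp.text)
        rows = {
            typ: evaluation.terminology_coverage(texts, graph)
            for typ, texts in sorted(by_type.items())
        }
        all_texts = [t for texts in by_type.values() for t in texts]
        overall = evaluation.terminology_coverage(all_texts, graph)
        data = {
            "per_type": {
                typ: {"n_matched": c.n_matched, "n_total": c.n_total,
                      "percentage": c.percentage}
                for typ, c in rows.items()
            },
            "overall": {"n_matched": overall.n_matched, "n_total": overall.n_total,
                        "percentage": overall.percentage},
        }
        (self.out / "coverage.json").write_text(
            json.dumps(data, ensure_ascii=False, indent=1), "utf-8"
        )
        logger.info("coverage: %.1f%% overall", overall.percentage)
        return self._record(
            "coverage", ["corpus_test.tsv", "terminology.json"], ["coverage.json"],
            {"overall_percentage": overall.percentage},
        )

    def stage_stats(self) -> dict:
        (term_path,) = self._require("terminology.json")
        graph = TerminologyGraph.load(term_path)
        graph.stats().to_csv(self.out / "terminology_stats.tsv", sep="\t")
        graph.to_tsv(self.out / "terms.tsv")
        return self._record(
            "stats", ["terminology.json"], ["terminology_stats.tsv", "terms.tsv"],
            {"n_concepts": len(graph.concepts), "n_terms": len(graph.term_entries)},
        )


def run_stage(name: str, config: PipelineConfig) -> dict:
    return Pipeline(config).run_stage(name)


def run_all(config: PipelineConfig) -> dict:
    return Pipeline(config).run_all()
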