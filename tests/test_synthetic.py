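import pytest

from cccterm.crf_ner import extract_entities
from cccterm.evaluation import terminology_coverage
from cccterm.rules import apply_rules, default_rules
from cccterm.synthetic import (
    CompoundCaseConfig,
    GeneratorConfig,
    ToyTerminologyConfig,
    generate_compound_cases,
    generate_corpus,
    generate_toy_terminology,
)
from cccterm.terminology import DEFAULT_CLASSES


class TestGenerateCorpus:
    def test_same_config_same_seed_is_byte_identical(self):
        cfg = GeneratorConfig(seed=5, n_sentences=30, noise_rate=0.3)
        a, b = generate_corpus(cfg), generate_corpus(cfg)
        assert a.sequences == b.sequences
        assert a.manifest == b.manifest
        c = generate_corpus(GeneratorConfig(seed=6, n_sentences=30, noise_rate=0.3))
        assert c.sequences != a.sequences

    def test_manifest_counts_match_realized_corpus(self):
        cfg = GeneratorConfig(seed=2, n_sentences=100)
        corpus = generate_corpus(cfg)
        realized: dict[str, int] = {}
        for spans in corpus.gold_spans():
            for s in spans:
                realized[s.entity_type] = realized.get(s.entity_type, 0) + 1
        assert realized == corpus.manifest["entity_counts"]
        assert corpus.manifest["n_sentences"] == 100

    def test_single_entity_template_yields_one_entity_per_sentence(self):
        cfg = GeneratorConfig(
            seed=0,
            n_sentences=100,
            templates=[[("lit", "自述"), ("ent", "symptom"), ("lit", "明显")]],
        )
        corpus = generate_corpus(cfg)
        assert sum(corpus.manifest["entity_counts"].values()) == 100

    def test_zero_noise_has_only_template_tokens(self):
        cfg = GeneratorConfig(seed=0, n_sentences=50, noise_rate=0.0)
        corpus = generate_corpus(cfg)
        distractor_chars = set("".join(cfg.distractors))
        template_chars = {
            ch
            for tmpl in cfg.templates
            for kind, value in tmpl
            if kind == "lit"
            for ch in value
        }
        entity_chars = {
            ch for surfaces in cfg.lexicons.values() for s in surfaces for ch in s
        }
        for tokens, _ in corpus.sequences:
            assert set(tokens) <= template_chars | entity_chars
            assert not (set(tokens) & (distractor_chars - template_chars - entity_chars))

    def test_gold_span_text_matches_tokens(self):
        corpus = generate_corpus(GeneratorConfig(seed=3, n_sentences=40))
        for (tokens, _), spans in zip(corpus.sequences, corpus.gold_spans()):
            for s in spans:
                assert s.text == "".join(tokens[s.start : s.end])

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError, match="empty lexicon"):
            GeneratorConfig(lexicons={"symptom": []},
                            templates=[[("ent", "symptom")]])

    def test_variant_rate_lowers_coverage_monotonically(self):
        """Unregistered spelling variants reduce terminology coverage."""
        graph = generate_toy_terminology()
        # terminology knows the canonical surfaces but not these variants
        table = {"出血": ["流血不止"], "疼痛": ["隐隐作痛"]}
        lex = {"symptom": ["出血", "疼痛"]}
        for s in lex["symptom"]:
            if not graph.resolve(s):
                root = next(c for c in graph.concepts.values()
                            if c.parent_id is None and c.top_class == "临床表现")
                graph.add_concept(s, parent_id=root.concept_id)
        coverages = []
        for rate in (0.0, 0.5, 1.0):
            cfg = GeneratorConfig(
                seed=7, n_sentences=120, variant_rate=rate,
                lexicons=lex, variant_table=table,
                templates=[[("lit", "自述"), ("ent", "symptom")]],
            )
            texts = [s.text for spans in generate_corpus(cfg).gold_spans()
                     for s in spans]
            coverages.append(terminology_coverage(texts, graph).coverage)
        assert coverages[0] == 1.0
        assert coverages[0] > coverages[1] > coverages[2]
        assert coverages[2] == 0.0


class TestToyTerminology:
    def test_default_has_eleven_valid_roots(self):
        graph = generate_toy_terminology()
        roots = [c for c in graph.concepts.values() if c.parent_id is None]
        assert sorted(c.top_class for c in roots) == sorted(DEFAULT_CLASSES)
        assert graph.validate().ok

    def test_requested_counts_show_up_in_stats(self):
        cfg = ToyTerminologyConfig(standard_per_class=2, common_per_class=3)
        stats = generate_toy_terminology(cfg).stats().drop("Total")
        assert (stats["standard"] == 2).all()
        assert (stats["common"] == 3).all()
        assert (stats["total"] == 5).all()

    def test_depth_respects_requested_level_and_bound(self):
        cfg = ToyTerminologyConfig(standard_per_class=8, max_level=6)
        graph = generate_toy_terminology(cfg)
        assert max(c.level for c in graph.concepts.values()) == 6
        assert graph.validate().ok
        with pytest.raises(ValueError):
            ToyTerminologyConfig(max_level=7)

    def test_example_variants_are_registered(self):
        graph = generate_toy_terminology()
        assert graph.resolve("尿血") == graph.resolve("血尿")
        assert graph.resolve("宫颈锥切") == graph.resolve("子宫颈锥形切除术")
        assert graph.resolve("盆腔MRI") == graph.resolve("盆腔磁共振成像")


class TestCompoundCases:
    def test_expected_compound_matches_rule_application(self):
        corpus = generate_compound_cases(CompoundCaseConfig(seed=4, n_sentences=40))
        rules = default_rules()
        for (tokens, labels), expected in zip(
            corpus.sequences, corpus.expected_compounds
        ):
            spans = extract_entities(tokens, labels)
            out = apply_rules(spans, tokens, rules)
            compounds = [s for s in out if s.entity_type.endswith("_compound")]
            assert compounds == expected

    def test_expected_compound_text_is_concatenated_constituents(self):
        corpus = generate_compound_cases(CompoundCaseConfig(seed=1, n_sentences=20))
        for (tokens, labels), expected in zip(
            corpus.sequences, corpus.expected_compounds
        ):
            constituents = extract_entities(tokens, labels)
            assert expected[0].text == "".join(s.text for s in constituents)

    def test_gap_connector_bridged_by_max_gap_rules(self):
        from cccterm.rules import CompoundRule

        cfg = CompoundCaseConfig(seed=2, n_sentences=30, gap_rate=1.0)
        gap_rules = [
            CompoundRule(r.rule_id, r.slot_pattern, r.output_type, max_gap=1)
            for r in default_rules()
        ]
        corpus = generate_compound_cases(cfg, rules=gap_rules)
        for (tokens, labels), expected in zip(
            corpus.sequences, corpus.expected_compounds
        ):
            out = apply_rules(extract_entities(tokens, labels), tokens, gap_rules)
            compounds = [s for s in out if s.entity_type.endswith("_compound")]
            assert compounds == expected

    def test_deterministic(self):
        cfg = CompoundCaseConfig(seed=9, n_sentences=15)
        a, b = generate_compound_cases(cfg), generate_compound_cases(cfg)
        assert a.sequences == b.sequences
        assert a.expected_compounds == b.expected_compounds

    def test_corpus_files_round_trip(self, tmp_path):
        from cccterm.crf_ner import read_conll

        corpus = generate_corpus(GeneratorConfig(seed=1, n_sentences=10))
        corpus.write(tmp_path / "c.tsv", tmp_path / "m.json")
        assert read_conll(tmp_path / "c.tsv") == corpus.sequences
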