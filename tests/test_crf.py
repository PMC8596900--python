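import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cccterm import crf_ner as C
from conftest import (
    brute_force_decode,
    brute_force_log_partition,
    enumerate_labelings,
    make_random_model,
)


@pytest.fixture()
def tiny_model():
    return make_random_model(np.random.default_rng(7), n_labels=3, tokens="abcab")


class TestScoring:
    def test_zero_weights_score_zero_for_every_labeling(self, tiny_model):
        tiny_model.weights = np.zeros_like(tiny_model.weights)
        toks = list("abc")
        for lab in enumerate_labelings(tiny_model.labels, 3):
            assert C.unnormalized_score(tiny_model, toks, list(lab)) == 0.0

    def test_single_feature_score_is_weight_times_fires(self):
        model = make_random_model(np.random.default_rng(0), tokens="aaa")
        model.weights = np.zeros_like(model.weights)
        # state feature (w0=a, label A) fires at all 3 positions of "aaa"
        k = model.attr_index["w0=a"] * model.n_labels + 0
        model.weights[k] = 2.0
        assert C.unnormalized_score(model, list("aaa"), ["A"] * 3) == pytest.approx(6.0)

    def test_length_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            C.unnormalized_score(tiny_model, list("ab"), ["A"])


class TestPartition:
    def test_uniform_lattice_gives_T_log_L(self, tiny_model):
        tiny_model.weights = np.zeros_like(tiny_model.weights)
        assert C.partition(tiny_model, list("abca")) == pytest.approx(4 * math.log(3))

    def test_matches_enumeration_on_random_models(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            model = make_random_model(rng, n_labels=3, tokens="abcab")
            toks = list("abca")
            assert C.partition(model, toks) == pytest.approx(
                brute_force_log_partition(model, toks), abs=1e-9
            )

    def test_constant_transition_shift_scales_partition(self, tiny_model):
        toks = list("abca")
        base = C.partition(tiny_model, toks)
        c = 0.7
        L = tiny_model.n_labels
        tiny_model.transition_weights[:] += c  # every step's potential shifts by c
        assert C.partition(tiny_model, toks) == pytest.approx(base + c * 4)


class TestConditionalProbability:
    def test_uniform_under_zero_weights(self, tiny_model):
        tiny_model.weights = np.zeros_like(tiny_model.weights)
        assert C.conditional_probability(
            tiny_model, list("abc"), ["A", "B", "C"]
        ) == pytest.approx(1 / 27)

    def test_sums_to_one_over_all_labelings(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            model = make_random_model(rng, n_labels=3, tokens="abcab")
            toks = list("abca")
            total = sum(
                C.conditional_probability(model, toks, list(lab))
                for lab in enumerate_labelings(model.labels, 4)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_raising_a_private_feature_weight_raises_probability(self, tiny_model):
        toks = list("aba")
        labs = ["B", "A", "B"]
        # transition feature (start -> B) is active under labs
        L = tiny_model.n_labels
        p0 = C.conditional_probability(tiny_model, toks, labs)
        tiny_model.transition_weights[L, 1] += 1.0
        p1 = C.conditional_probability(tiny_model, toks, labs)
        assert p1 > p0


class TestLikelihoodAndGradient:
    def test_uniform_likelihood_is_minus_NT_logL(self, tiny_model):
        tiny_model.weights = np.zeros_like(tiny_model.weights)
        corpus = [(list("abc"), ["A", "B", "C"]), (list("bca"), ["B", "C", "A"])]
        assert C.penalized_log_likelihood(tiny_model, corpus) == pytest.approx(
            -2 * 3 * math.log(3)
        )

    def test_matches_brute_force_likelihood(self):
        rng = np.random.default_rng(5)
        model = make_random_model(rng, n_labels=3, tokens="abcab")
        corpus = [(list("abca"), ["A", "C", "B", "A"])]
        direct = (
            C.unnormalized_score(model, *corpus[0])
            - brute_force_log_partition(model, corpus[0][0])
            - float(np.sum(model.weights**2)) / (2 * model.sigma2)
        )
        assert C.penalized_log_likelihood(model, corpus) == pytest.approx(direct)

    def test_shrinking_sigma2_decreases_objective_when_weights_nonzero(self, tiny_model):
        corpus = [(list("abc"), ["A", "B", "C"])]
        loose = C.penalized_log_likelihood(tiny_model, corpus)
        tiny_model.sigma2 = 0.1
        assert C.penalized_log_likelihood(tiny_model, corpus) < loose

    def test_penalty_gradient_vanishes_at_zero_weights(self, tiny_model):
        tiny_model.weights = np.zeros_like(tiny_model.weights)
        corpus = [(list("aa"), ["A", "A"]), (list("aa"), ["B", "B"])]
        g = C.gradient(tiny_model, corpus)
        # symmetric data at the uniform model: A/B state counts cancel,
        # and the penalty contributes nothing at the origin
        kA = tiny_model.attr_index["w0=a"] * 3 + 0
        kB = tiny_model.attr_index["w0=a"] * 3 + 1
        assert g[kA] == pytest.approx(g[kB])

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(9)
        model = make_random_model(rng, n_labels=3, tokens="abcab")
        corpus = [(list("abca"), ["A", "B", "C", "A"]), (list("bc"), ["C", "B"])]
        g = C.gradient(model, corpus)
        eps = 1e-6
        base = model.weights.copy()

        def value_at(k, delta):
            w = base.copy()
            w[k] += delta
            model.weights = w
            return C.penalized_log_likelihood(model, corpus)

        for k in rng.choice(len(base), size=12, replace=False):
            numeric = (value_at(k, eps) - value_at(k, -eps)) / (2 * eps)
            assert abs(numeric - g[k]) <= 1e-5
        model.weights = base

    def test_empty_corpus_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            C.penalized_log_likelihood(tiny_model, [])
        with pytest.raises(ValueError):
            C.gradient(tiny_model, [])


class TestTraining:
    def test_single_binary_feature_matches_scalar_maximization(self):
        """One length-1 sequence with labels {A, B}: the penalized objective
        depends on the weights only through the score margin d, so its
        optimum is recoverable by 1-D numeric maximization over d."""
        from scipy.optimize import minimize_scalar

        corpus = [(["x"], ["A"])]
        templates = [C.FeatureTemplate("token[0]")]
        sigma2 = 2.0
        model = C.train(corpus, templates, ["A", "B"], sigma2=sigma2, max_iter=500)
        trained_obj = C.penalized_log_likelihood(model, corpus)

        # four weights are active (state w0=x and start transition, for each
        # label); for a fixed margin d the prior is minimized by splitting d
        # evenly over them (±d/4 each), giving penalty d²/(8σ²)
        def neg(d):
            return math.log(1 + math.exp(-d)) + d**2 / (8 * sigma2)

        best = minimize_scalar(neg, bounds=(0.0, 10.0), method="bounded")
        assert trained_obj == pytest.approx(-best.fun, abs=1e-6)

    def test_duplicated_corpus_reaches_same_optimum_without_prior(self):
        corpus = [(list("ab"), ["A", "B"]), (list("ba"), ["B", "A"])]
        templates = [C.FeatureTemplate("token[0]")]
        m1 = C.train(corpus, templates, ["A", "B"], sigma2=1e8)
        m2 = C.train(corpus * 2, templates, ["A", "B"], sigma2=1e8)
        p1 = [C.decode(m1, list("ab")), C.decode(m1, list("ba"))]
        p2 = [C.decode(m2, list("ab")), C.decode(m2, list("ba"))]
        assert p1 == p2
        assert C.penalized_log_likelihood(m1, corpus) == pytest.approx(
            C.penalized_log_likelihood(m2, corpus), abs=1e-4
        )

    def test_two_initializations_reach_the_same_objective(self):
        corpus = [(list("abcab"), ["A", "B", "A", "A", "B"]),
                  (list("bacba"), ["B", "A", "A", "B", "A"])]
        templates = C.default_templates()
        m_zero = C.train(corpus, templates, ["A", "B"], seed=None)
        m_rand = C.train(corpus, templates, ["A", "B"], seed=123)
        o1 = C.penalized_log_likelihood(m_zero, corpus)
        o2 = C.penalized_log_likelihood(m_rand, corpus)
        assert o1 == pytest.approx(o2, abs=1e-5)

    def test_training_rejects_empty_corpus_and_foreign_labels(self):
        with pytest.raises(ValueError):
            C.train([])
        with pytest.raises(ValueError):
            C.train([(["a"], ["Z"])], label_set=["A", "B"])


class TestDecode:
    def test_zero_weights_return_first_label_everywhere(self, tiny_model):
        tiny_model.weights = np.zeros_like(tiny_model.weights)
        assert C.decode(tiny_model, list("abca")) == ["A"] * 4

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            model = make_random_model(rng, n_labels=3, tokens="abcab")
            toks = list("abcab")
            got = C.decode(model, toks)
            best, best_score = brute_force_decode(model, toks)
            assert C.unnormalized_score(model, toks, got) == pytest.approx(best_score)

    def test_decode_score_dominates_every_labeling(self, tiny_model):
        toks = list("abc")
        got_score = C.unnormalized_score(tiny_model, toks, C.decode(tiny_model, toks))
        for lab in enumerate_labelings(tiny_model.labels, 3):
            assert got_score >= C.unnormalized_score(tiny_model, toks, list(lab)) - 1e-9


class TestEntityExtraction:
    def test_basic_span_and_all_O(self):
        spans = C.extract_entities(list("阴道出"), ["B-symptom", "I-symptom", "O"])
        assert spans == [C.EntitySpan(0, 2, "symptom", "阴道")]
        assert C.extract_entities(list("abc"), ["O"] * 3) == []

    def test_stray_I_is_repaired_to_B(self):
        spans = C.extract_entities(
            list("xy出血"), ["O", "I-symptom", "I-symptom", "I-symptom"]
        )
        assert spans == [C.EntitySpan(1, 4, "symptom", "y出血")]

    def test_type_change_without_B_opens_new_span(self):
        spans = C.extract_entities(list("abcd"), ["B-x", "I-y", "I-y", "O"])
        assert [(s.start, s.end, s.entity_type) for s in spans] == [
            (0, 1, "x"), (1, 3, "y")
        ]

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            C.extract_entities(["a"], ["Q-x"])

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(1, 3), st.sampled_from("st")),
            max_size=4,
        )
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_spans_to_bio_round_trip(self, raw):
        # build well-formed, non-overlapping spans from (gap, length, type)
        spans, pos = [], 0
        for gap, length, typ in raw:
            pos += gap
            spans.append(C.EntitySpan(pos, pos + length, typ, "x" * length))
            pos += length
        tokens = ["x"] * max(pos, 1)
        labels = C.spans_to_bio(spans, len(tokens))
        assert C.extract_entities(tokens, labels) == spans


class TestIO:
    def test_conll_round_trip_and_trailing_whitespace(self, tmp_path):
        corpus = [(list("阴道出血"), ["B-bp", "I-bp", "B-sy", "I-sy"]),
                  (["无"], ["O"])]
        path = tmp_path / "c.tsv"
        C.write_conll(corpus, path)
        text = path.read_text(encoding="utf-8")
        assert "\t" in text and not any(
            line != line.rstrip() for line in text.splitlines()
        )
        path.write_text(text.replace("B-sy", "B-sy  "), encoding="utf-8")
        assert C.read_conll(path)[0][1][2] == "B-sy"

    def test_model_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(2)
        model = make_random_model(rng, tokens="abcab")
        C.save_model(model, tmp_path / "m.json")
        loaded = C.load_model(tmp_path / "m.json")
        toks = list("cabba")
        assert C.decode(loaded, toks) == C.decode(model, toks)
        assert C.partition(loaded, toks) == pytest.approx(C.partition(model, toks))
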