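import itertools
import math

import numpy as np
import pytest

from cccterm import crf_ner as C
from cccterm.evaluation import evaluation_report
from cccterm.synthetic import GeneratorConfig, generate_corpus, generate_toy_terminology


@pytest.fixture()
def toy_graph():
    return generate_toy_terminology()


def make_random_model(rng, n_labels=3, tokens="abcab", scale=1.0):
    """A small hand-built CRF over character tokens with random weights."""
    labels = [chr(ord("A") + i) for i in range(n_labels)]
    templates = [C.FeatureTemplate("token[0]"), C.FeatureTemplate("token[-1]")]
    vocab = sorted(set(tokens))
    corpus = [(list(tokens), [labels[0]] * len(tokens))]
    attr_index = C.build_attr_index(templates, corpus)
    n = len(attr_index) * n_labels + (n_labels + 1) * n_labels
    return C.CrfModel(
        labels, templates, attr_index, rng.normal(0.0, scale, n), sigma2=10.0
    )


def enumerate_labelings(labels, T):
    return itertools.product(labels, repeat=T)


def brute_force_log_partition(model, tokens):
    scores = [
        C.unnormalized_score(model, tokens, list(lab))
        for lab in enumerate_labelings(model.labels, len(tokens))
    ]
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def brute_force_decode(model, tokens):
    """Argmax labeling with the same tie-break as Viterbi (first in
    lexicographic label-index order)."""
    best, best_score = None, -math.inf
    for lab in enumerate_labelings(model.labels, len(tokens)):
        s = C.unnormalized_score(model, tokens, list(lab))
        if s > best_score + 1e-12:
            best, best_score = list(lab), s
    return best, best_score


@pytest.fixture(scope="session")
def separable_corpus_config():
    """Study conditions for parameter recovery: 500 training sentences with
    lexically separable entity lexicons and no synonym variation."""
    return GeneratorConfig(seed=11, n_sentences=625, variant_rate=0.0)


@pytest.fixture(scope="session")
def trained_crf(separable_corpus_config):
    """CRF trained on the 500-sentence synthetic corpus plus its held-out
    span-level evaluation (125 sentences)."""
    cfg = separable_corpus_config
    corpus = generate_corpus(cfg).sequences
    test, train = corpus[:125], corpus[125:]
    lexicon = [s for surfaces in cfg.lexicons.values() for s in surfaces]
    model = C.train(train, templates=C.default_templates(lexicon=lexicon))
    pred = [C.extract_entities(t, C.decode(model, t)) for t, _ in test]
    gold = [C.extract_entities(t, l) for t, l in test]
    report = evaluation_report(pred, gold)
    return {"model": model, "train": train, "test": test, "report": report}
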