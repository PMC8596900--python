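"""Linear-chain conditional random field for BIO named-entity recognition.

The model assigns to a label sequence ``s = <s_1..s_T>`` given an
observation sequence ``o = <o_1..o_T>`` the probability

    P_λ(s|o) = (1/Z_0) exp( Σ_t Σ_k λ_k f_k(s_{t-1}, s_t, o, t) )

where the ``f_k`` are binary feature functions and ``Z_0`` is the partition
function, computed by the forward recursion in log space.  Features come in
two families:

* **state features** — an observation attribute extracted at position ``t``
  (current/neighbour token identity, character-type class, lexicon
  membership) conjoined with the label ``s_t``;
* **transition features** — the label pair ``(s_{t-1}, s_t)``, with a
  virtual start label feeding ``s_0``.

Training maximizes the log-likelihood with a Gaussian prior penalty
``- Σ_k λ_k² / (2σ²)`` by L-BFGS; the objective is concave so any
stationary point is the global optimum.  Tokenization is character-level by
default, the standard choice for Chinese clinical text; callers may supply
word-level tokens instead.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

MODEL_FORMAT_VERSION = "1.0"

Corpus = list[tuple[list[str], list[str]]]  # (tokens, gold BIO labels) pairs


# --------------------------------------------------------------------------
# entity spans
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EntitySpan:
    """A typed mention covering tokens ``[start, end)``."""

    start: int
    end: int
    entity_type: str
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span offsets [{self.start}, {self.end})")


def extract_entities(tokens: Sequence[str], labels: Sequence[str]) -> list[EntitySpan]:
    """Turn a BIO labeling into a sorted list of non-overlapping spans.

    A stray ``I-t`` with no preceding ``B-t``/``I-t`` of the same type is
    repaired to ``B-t`` (it opens a new span).
    """
    if len(tokens) != len(labels):
        raise ValueError("tokens and labels differ in length")
    spans: list[EntitySpan] = []
    start: Optional[int] = None
    cur_type: Optional[str] = None

    def close(upto: int) -> None:
        nonlocal start, cur_type
        if start is not None:
            spans.append(
                EntitySpan(start, upto, cur_type, "".join(tokens[start:upto]))
            )
        start, cur_type = None, None

    for t, tag in enumerate(labels):
        if tag == "O":
            close(t)
            continue
        if len(tag) < 3 or tag[1] != "-" or tag[0] not in "BI":
            raise ValueError(f"unknown tag format: {tag!r}")
        marker, etype = tag[0], tag[2:]
        if marker == "B" or cur_type != etype:
            close(t)
            start, cur_type = t, etype
    close(len(labels))
    return spans


def spans_to_bio(spans: Iterable[EntitySpan], length: int) -> list[str]:
    """Inverse of :func:`extract_entities` for well-formed span lists."""
    labels = ["O"] * length
    for sp in spans:
        if sp.end > length:
            raise ValueError("span exceeds sequence length")
        labels[sp.start] = f"B-{sp.entity_type}"
        for i in range(sp.start + 1, sp.end):
            labels[i] = f"I-{sp.entity_type}"
    return labels


def bio_label_set(entity_types: Iterable[str]) -> list[str]:
    """``O`` first, then ``B-t``/``I-t`` per type in the given order."""
    labels = ["O"]
    for t in entity_types:
        labels += [f"B-{t}", f"I-{t}"]
    return labels


# --------------------------------------------------------------------------
# feature templates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureTemplate:
    """A named extractor of observation attributes at one position.

    ``template_id`` selects the extractor; ``params`` carries extractor
    configuration (the lexicon surfaces for ``"lexicon"``).  Extractors are
    deterministic and look at a bounded window around ``t``.
    """

    template_id: str
    params: tuple[str, ...] = ()


def default_templates(lexicon: Iterable[str] | None = None) -> list[FeatureTemplate]:
    """Token identity in a ±1 window, character-type class, and optional
    lexicon membership against a terminology word list."""
    templates = [
        FeatureTemplate("token[0]"),
        FeatureTemplate("token[-1]"),
        FeatureTemplate("token[+1]"),
        FeatureTemplate("chartype[0]"),
    ]
    if lexicon is not None:
        templates.append(FeatureTemplate("lexicon", tuple(sorted(set(lexicon)))))
    return templates


def _chartype(token: str) -> str:
    ch = token[0]
    if ch.isdigit():
        return "digit"
    if "a" <= ch.lower() <= "z":
        return "latin"
    cat = unicodedata.category(ch)
    if cat.startswith("P") or cat.startswith("S"):
        return "punct"
    if "一" <= ch <= "鿿":
        return "cjk"
    return "other"


def _lexicon_tags(tokens: Sequence[str], surfaces: tuple[str, ...]) -> list[str]:
    """Per-token B/I/O flags for occurrences of lexicon surfaces.

    Works on the concatenated surface string with a token-offset map, so it
    behaves identically for character and word tokenization.
    """
    offsets = [0]
    for tok in tokens:
        offsets.append(offsets[-1] + len(tok))
    text = "".join(tokens)
    starts = {off: i for i, off in enumerate(offsets[:-1])}
    covered = ["O"] * len(tokens)
    for surf in surfaces:
        pos = text.find(surf)
        while pos >= 0:
            i = starts.get(pos)
            if i is not None and (pos + len(surf)) in set(offsets):
                j = offsets.index(pos + len(surf))
                covered[i] = "B" if covered[i] == "O" else covered[i]
                for k in range(i + 1, j):
                    if covered[k] == "O":
                        covered[k] = "I"
            pos = text.find(surf, pos + 1)
    return covered


def sequence_attrs(
    templates: Sequence[FeatureTemplate], tokens: Sequence[str]
) -> list[list[str]]:
    """Observation attribute strings active at each position."""
    T = len(tokens)
    attrs: list[list[str]] = [[] for _ in range(T)]
    for tmpl in templates:
        tid = tmpl.template_id
        if tid == "token[0]":
            for t in range(T):
                attrs[t].append(f"w0={tokens[t]}")
        elif tid == "token[-1]":
            for t in range(T):
                attrs[t].append(f"w-1={tokens[t - 1] if t > 0 else '<BOS>'}")
        elif tid == "token[+1]":
            for t in range(T):
                attrs[t].append(f"w+1={tokens[t + 1] if t + 1 < T else '<EOS>'}")
        elif tid == "chartype[0]":
            for t in range(T):
                attrs[t].append(f"ct0={_chartype(tokens[t])}")
        elif tid == "lexicon":
            for t, tag in enumerate(_lexicon_tags(tokens, tmpl.params)):
                attrs[t].append(f"lex={tag}")
        else:
            raise ValueError(f"unknown template: {tid!r}")
    return attrs


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


@dataclass
class CrfModel:
    """A trained or hand-built linear-chain CRF.

    The weight vector ``λ`` concatenates state weights — one per
    (observation attribute, label) pair, row-major over the attribute
    index — and transition weights, one per (previous label, label) pair
    where the extra previous-label row is the virtual start state.
    """

    labels: list[str]
    templates: list[FeatureTemplate]
    attr_index: dict[str, int]
    weights: np.ndarray
    sigma2: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if len(self.weights) != self.n_features:
            raise ValueError(
                f"weight vector length {len(self.weights)} != "
                f"feature count {self.n_features}"
            )
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_attrs(self) -> int:
        return len(self.attr_index)

    @property
    def n_features(self) -> int:
        L = self.n_labels
        return self.n_attrs * L + (L + 1) * L

    @property
    def state_weights(self) -> np.ndarray:
        """(n_attrs, L) view of the state-feature block."""
        L = self.n_labels
        return self.weights[: self.n_attrs * L].reshape(self.n_attrs, L)

    @property
    def transition_weights(self) -> np.ndarray:
        """(L+1, L) view; the last row is the virtual start state."""
        L = self.n_labels
        return self.weights[self.n_attrs * L :].reshape(L + 1, L)

    # ---------------------------------------------------------------- setup
    def attr_ids(self, tokens: Sequence[str]) -> list[list[int]]:
        """Indices of active attributes per position; unseen attrs dropped."""
        out = []
        for position_attrs in sequence_attrs(self.templates, tokens):
            ids = [self.attr_index[a] for a in position_attrs if a in self.attr_index]
            out.append(ids)
        return out

    def state_scores(self, tokens: Sequence[str]) -> np.ndarray:
        """(T, L) matrix of summed state-feature weights."""
        W = self.state_weights
        rows = []
        for ids in self.attr_ids(tokens):
            rows.append(W[ids].sum(axis=0) if ids else np.zeros(self.n_labels))
        return np.array(rows)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------


def unnormalized_score(
    model: CrfModel, tokens: Sequence[str], labels: Sequence[str]
) -> float:
    """The exponent Σ_t Σ_k λ_k f_k(s_{t-1}, s_t, o, t); linear in λ."""
    if len(tokens) != len(labels):
        raise ValueError("sequence and labels differ in length")
    idx = {lab: i for i, lab in enumerate(model.labels)}
    try:
        y = [idx[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(f"label {exc} not in model label set") from exc
    S = model.state_scores(tokens)
    trans = model.transition_weights
    L = model.n_labels
    score = S[0, y[0]] + trans[L, y[0]]
    for t in range(1, len(y)):
        score += S[t, y[t]] + trans[y[t - 1], y[t]]
    return float(score)


def _forward(S: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Forward log-messages; alpha[t, j] = log Σ over prefixes ending in j."""
    T, L = S.shape
    alpha = np.empty((T, L))
    alpha[0] = trans[L] + S[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + trans[:L], axis=0) + S[t]
    return alpha


def _backward(S: np.ndarray, trans: np.ndarray) -> np.ndarray:
    T, L = S.shape
    beta = np.zeros((T, L))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(trans[:L] + (S[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def partition(model: CrfModel, tokens: Sequence[str]) -> float:
    """log Z_0 by the forward recursion (log-sum-exp; Z_0 itself is never
    materialized)."""
    S = model.state_scores(tokens)
    alpha = _forward(S, model.transition_weights)
    return float(logsumexp(alpha[-1]))


def conditional_probability(
    model: CrfModel, tokens: Sequence[str], labels: Sequence[str]
) -> float:
    """P_λ(s|o) = exp(score - log Z_0); sums to 1 over all labelings."""
    return float(
        np.exp(unnormalized_score(model, tokens, labels) - partition(model, tokens))
    )


def decode(model: CrfModel, tokens: Sequence[str]) -> list[str]:
    """Viterbi argmax labeling; ties broken toward the lowest label index."""
    S = model.state_scores(tokens)
    trans = model.transition_weights
    T, L = S.shape
    delta = trans[L] + S[0]
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + trans[:L] + S[t][None, :]
        back[t] = np.argmax(cand, axis=0)  # first max = lowest index on ties
        delta = cand[back[t], np.arange(L)]
    path = [int(np.argmax(delta))]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return [model.labels[i] for i in path]


# --------------------------------------------------------------------------
# training objective
# --------------------------------------------------------------------------


def _empirical_counts(
    model: CrfModel, corpus: Corpus, cache: list[list[list[int]]]
) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(model.labels)}
    L = model.n_labels
    state = np.zeros((model.n_attrs, L))
    trans = np.zeros((L + 1, L))
    for (tokens, labels), ids in zip(corpus, cache):
        y = [idx[lab] for lab in labels]
        trans[L, y[0]] += 1
        for t, yt in enumerate(y):
            for a in ids[t]:
                state[a, yt] += 1
            if t > 0:
                trans[y[t - 1], yt] += 1
    return np.concatenate([state.ravel(), trans.ravel()])


def _expected_counts_and_ll(
    model: CrfModel, corpus: Corpus, cache: list[list[list[int]]]
) -> tuple[np.ndarray, float]:
    """Model-expected feature counts via forward-backward, plus Σ log P."""
    idx = {lab: i for i, lab in enumerate(model.labels)}
    L = model.n_labels
    trans = model.transition_weights
    Wstate = model.state_weights
    exp_state = np.zeros((model.n_attrs, L))
    exp_trans = np.zeros((L + 1, L))
    ll = 0.0
    for (tokens, labels), ids in zip(corpus, cache):
        T = len(tokens)
        S = np.zeros((T, L))
        for t, row in enumerate(ids):
            if row:
                S[t] = Wstate[row].sum(axis=0)
        alpha = _forward(S, trans)
        beta = _backward(S, trans)
        logZ = logsumexp(alpha[-1])
        # gold log-probability
        y = [idx[lab] for lab in labels]
        gold = S[0, y[0]] + trans[L, y[0]]
        for t in range(1, T):
            gold += S[t, y[t]] + trans[y[t - 1], y[t]]
        ll += gold - logZ
        # unary marginals -> state and start counts
        unary = np.exp(alpha + beta - logZ)
        for t, row in enumerate(ids):
            for a in row:
                exp_state[a] += unary[t]
        exp_trans[L] += unary[0]
        # pairwise marginals -> transition counts
        for t in range(1, T):
            pair = alpha[t - 1][:, None] + trans[:L] + (S[t] + beta[t])[None, :] - logZ
            exp_trans[:L] += np.exp(pair)
    return np.concatenate([exp_state.ravel(), exp_trans.ravel()]), float(ll)


def penalized_log_likelihood(model: CrfModel, corpus: Corpus) -> float:
    """Σ_i log P_λ(s⁽ⁱ⁾|o⁽ⁱ⁾) − Σ_k λ_k²/(2σ²); concave in λ."""
    if not corpus:
        raise ValueError("empty corpus")
    ll = 0.0
    for tokens, labels in corpus:
        ll += unnormalized_score(model, tokens, labels) - partition(model, tokens)
    return ll - float(np.sum(model.weights**2)) / (2.0 * model.sigma2)


def gradient(model: CrfModel, corpus: Corpus) -> np.ndarray:
    """∂/∂λ of the penalized log-likelihood: empirical − expected − λ/σ²."""
    if not corpus:
        raise ValueError("empty corpus")
    cache = [model.attr_ids(tokens) for tokens, _ in corpus]
    emp = _empirical_counts(model, corpus, cache)
    exp, _ = _expected_counts_and_ll(model, corpus, cache)
    return emp - exp - model.weights / model.sigma2


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


def build_attr_index(
    templates: Sequence[FeatureTemplate], corpus: Corpus
) -> dict[str, int]:
    """Index every observation attribute seen in the corpus (sorted for
    determinism)."""
    seen: set[str] = set()
    for tokens, _ in corpus:
        for row in sequence_attrs(templates, tokens):
            seen.update(row)
    return {a: i for i, a in enumerate(sorted(seen))}


def train(
    corpus: Corpus,
    templates: Sequence[FeatureTemplate] | None = None,
    label_set: Sequence[str] | None = None,
    sigma2: float = 10.0,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> CrfModel:
    """Fit CRF weights by maximizing the Gaussian-penalized likelihood.

    Deterministic given the inputs and ``seed`` (the seed only perturbs the
    all-zero initial point; the objective is concave, so every start reaches
    the same optimum up to the tolerance).
    """
    if not corpus:
        raise ValueError("empty corpus")
    if templates is None:
        templates = default_templates()
    if label_set is None:
        label_set = sorted({lab for _, labels in corpus for lab in labels})
        if "O" in label_set:  # conventional: O first
            label_set = ["O"] + [l for l in label_set if l != "O"]
    for _, labels in corpus:
        for lab in labels:
            if lab not in label_set:
                raise ValueError(f"gold label {lab!r} not in label set")
    attr_index = build_attr_index(templates, corpus)
    model = CrfModel(
        labels=list(label_set),
        templates=list(templates),
        attr_index=attr_index,
        weights=np.zeros(
            len(attr_index) * len(label_set) + (len(label_set) + 1) * len(label_set)
        ),
        sigma2=sigma2,
    )
    if seed is not None:
        rng = np.random.default_rng(seed)
        model.weights = rng.normal(0.0, 0.01, size=model.n_features)

    cache = [model.attr_ids(tokens) for tokens, _ in corpus]
    emp = _empirical_counts(model, corpus, cache)

    def neg_objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        model.weights = w
        exp, ll = _expected_counts_and_ll(model, corpus, cache)
        penalty = float(np.sum(w**2)) / (2.0 * sigma2)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite training objective")
        grad = emp - exp - w / sigma2
        return -(ll - penalty), -grad

    result = minimize(
        neg_objective,
        model.weights,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    model.weights = result.x
    return model


# --------------------------------------------------------------------------
# I/O: CoNLL corpus and model files
# --------------------------------------------------------------------------


def read_conll(path: str | Path) -> Corpus:
    """Read a CoNLL-style two-column TSV (token<TAB>tag, blank-line-separated
    sequences); tolerates trailing whitespace."""
    corpus: Corpus = []
    tokens: list[str] = []
    labels: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.rstrip()
        if not line:
            if tokens:
                corpus.append((tokens, labels))
                tokens, labels = [], []
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed CoNLL line: {raw!r}")
        tokens.append(parts[0])
        labels.append(parts[1])
    if tokens:
        corpus.append((tokens, labels))
    return corpus


def write_conll(corpus: Corpus, path: str | Path) -> None:
    lines = []
    for tokens, labels in corpus:
        for tok, lab in zip(tokens, labels):
            lines.append(f"{tok}\t{lab}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def save_model(model: CrfModel, path: str | Path) -> None:
    attrs = sorted(model.attr_index, key=model.attr_index.get)
    data = {
        "format_version": MODEL_FORMAT_VERSION,
        "labels": model.labels,
        "templates": [
            {"id": t.template_id, "params": list(t.params)} for t in model.templates
        ],
        "attrs": attrs,
        "weights": model.weights.tolist(),
        "sigma2": model.sigma2,
    }
    Path(path).write_text(json.dumps(data, ensure_ascii=False), encoding="utf-8")


def load_model(path: str | Path) -> CrfModel:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return CrfModel(
        labels=data["labels"],
        templates=[
            FeatureTemplate(t["id"], tuple(t["params"])) for t in data["templates"]
        ],
        attr_index={a: i for i, a in enumerate(data["attrs"])},
        weights=np.array(data["weights"], dtype=float),
        sigma2=data["sigma2"],
    )
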