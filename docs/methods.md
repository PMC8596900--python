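# Methods

## Problem setting

Chinese clinical records write the same notion many ways: standard
procedure names are abbreviated (子宫颈锥形切除术 → 宫颈锥切), findings
are paraphrased (血尿 / 尿血 / 小便带血 / 小便时带血), trade names stand
in for generics (艾恒 for 奥沙利铂). A *common terminology* pairs a tree
of standard concepts with the common terms observed in practice, so that
free-text mentions can be normalized and clinical data pooled across
sites. This package implements the computational side of building and
evaluating such a terminology: a concept/synonym data model, a
named-entity recognizer, rule-based compound-entity composition, synonym
alignment, and the accuracy/coverage metrics.

## Terminology model

Concepts form a forest under a configurable set of top-level classes
(default: the 11 cervical-cancer classes — clinical manifestation,
demographic information, stage, recurrence and metastasis, laboratory
test, cervical cancer screening, imaging examination, treatment, etiology,
pathology, follow-up), with depth capped at six levels. Each concept owns
exactly one *standard* term (its preferred label) and any number of
*common* terms. Relations and attributes come from registries (16 and 6
names by default; only `Has_staging` and `Drug_therapy_of` are canonical
domain relations, the rest are placeholders meant to be replaced).

Surfaces are indexed under NFKC normalization with whitespace trimming and
Latin case-folding, so 盆腔MRI, 盆腔mri and full-width 盆腔ＭＲＩ
coincide while CJK text is untouched. A surface may map to several
concepts; `resolve` returns all of them and `normalize_term` distinguishes
unique matches from ambiguity and from no-match. Validation reports
violations (cycles, orphan parents, depth > 6, root-count mismatches,
dangling references, index drift) as data rather than exceptions; the
root-count check is skipped for an empty graph, which is trivially valid.

## Linear-chain CRF

The recognizer is a from-scratch linear-chain conditional random field
over BIO tags:

    P_λ(s|o) = Z₀⁻¹ exp( Σ_t Σ_k λ_k f_k(s_{t−1}, s_t, o, t) )

with binary features split into state features (an observation attribute
at position *t* conjoined with the label) and transition features (label
pairs, with a virtual start label feeding s₀ and no stop potential).
Default attributes: token identity in a ±1 window, a character-type class
(CJK/Latin/digit/punct), and optional B/I/O lexicon-membership flags
computed against a terminology word list. Tokenization is character-level,
the standard choice for Chinese clinical text; word-level tokens can be
supplied directly.

All lattice computations run in log space. The partition function uses
the forward recursion with log-sum-exp; Z₀ is never materialized.
Training maximizes the penalized likelihood Σᵢ log P_λ(sⁱ|oⁱ) −
Σ_k λ_k²/(2σ²) with L-BFGS (scipy), using analytic gradients
(empirical − expected counts − λ/σ²) from forward–backward marginals.
The objective is concave, so the optimizer and the initial point do not
affect the optimum beyond the tolerance; `seed` only perturbs the
all-zero start and exists to exercise that property. Defaults: σ² = 10,
`tol` = 1e−5 (projected-gradient tolerance), `max_iter` = 200. Viterbi
decoding breaks ties toward the lowest label index, making outputs fully
deterministic. Correctness is guarded by exhaustive-enumeration oracles
(partition, probabilities, decoding) and central-finite-difference
gradient checks on tiny random models.

## Compound-entity rules

Compound mentions such as 阴道出血 (body part + symptom) or 盆腔适形放射治疗
(radiotherapy site + technology) are assembled from adjacent typed spans
by ordered type-sequence patterns. Seven default rules cover the
documented patterns; users can append rules (duplicates rejected).
Matching is over entity types, not surface text. Precedence is leftmost
first, then longest pattern, then earliest rule — fully ordered, so
output is deterministic. Slots must be contiguous by default; a per-rule
`max_gap` allows connector tokens between slots, which are absorbed into
the compound's text when bridged. One composition pass is performed;
compound output types are fresh names (`symptom_compound`,
`radiotherapy_compound`) so provenance is preserved and accidental
recursion is impossible.

## Metrics

Precision = correct/recognized-by-system, recall = correct/in-reference,
F1 = 2PR/(P+R), computed from unrounded intermediates and rounded
half-up to three decimals only for display. `f1(..., from_rounded=True)`
instead derives F1 from the 3-decimal displayed P and R — published
tables often do this, and e.g. counts (116, 122, 126) yield 0.935
unrounded but 0.936 via the display route. Span matching is exact on
(start, end, type) by default with a lenient same-type-overlap option.
Zero denominators produce NaN, never a silent 0. Terminology coverage is
the fraction of corpus terms that resolve in the terminology; mapping
rates display as percentages rounded half-up to one decimal
(35/72 → 48.6%).

## Synthetic data

Because real EMR corpora cannot be redistributed, corpora are generated
from sentence templates: literal carrier text plus typed entity slots
filled from small lexicons seeded with real domain surfaces (阴道, 出血,
接触性, 子宫颈锥形切除术, 血尿 and its variants, 艾恒, 盆腔MRI, ...).
Gold BIO labels are exact by construction. `noise_rate` (default 0.2)
prepends distractor vocabulary as O-labeled context; `variant_rate`
(default 0) swaps mentions for synonym variants, which lowers coverage
monotonically when the variants are not registered. All randomness flows
through one `random.Random(seed)`; corpora are pure functions of
(config, seed).

The toy terminology generator builds one root per class, chains
descendants to a requested depth (≤ 6), and registers the example
synonym sets, yielding exact per-class statistics for tests. Its counts
are deliberately small and self-consistent rather than matching any
published distribution table.

Study conditions for the recovery experiment: 625 generated sentences
split 500 train / 125 held-out, separable lexicons, `variant_rate` 0.
With deterministic templates and small vocabularies the trained model
reaches held-out span F1 of 1.0; real clinical text, with segmentation
ambiguity, typos and regional variation, would not — passing this check
shows the estimator and features work, not that real-world F1 is high.

## Pipeline

`cccterm` exposes stages gen → train → tag → compose → align → eval /
coverage / stats, each writing into one run directory with a
`manifest.json` recording config hash, seed and per-stage inputs/outputs.
Stage outputs are deterministic given (config, seed); wall-clock
timestamps are opt-in (`timestamps: true`) precisely so that identical
runs are byte-identical, and the output directory path is excluded from
the recorded config for the same reason. Missing dependencies (e.g.
`tag` before `train`) fail fast with an actionable message and exit
status 1.

## Known limitations

- No relation extraction, part-of-speech features, word clustering, or
  neural models; the feature set is the documented hook surface.
- Alignment is exact-match only; fuzzy matching is a caller-side hook.
- Dense (attribute × label) state features keep the code simple and
  vectorizable but grow memory linearly in label-set size; very large
  tag sets would want sparse feature storage.
- The training loop is optimized for clarity; hundreds of sentences train
  in well under a minute, but corpora orders of magnitude larger would
  need batching or a compiled inner loop.
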