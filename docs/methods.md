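# Methods

This note documents the statistical machinery in `emrcase`, the design
choices made where the procedure is genuinely open, what the synthetic
corpus generator does and does not emulate, and the problem sizes the
shipped tests and acceptance script use.

## Data model

The unit of labeling and of cross-validation is the **patient**: a binary
gold label (case / non-case) plus one or more free-text **entries**. One
entry per patient is the **seen** entry — the evidence entry for a
positive case, a randomly chosen entry for a negative case. All other
entries are **implicit** (negative patients; the whole record was reviewed
and found negative, so they are safe extra negative examples) or
**unseen** (positive patients; evidence status unknown, unusable for
training). Corpora are stored as JSON lines, one patient per line, UTF-8;
a generated corpus carries a ground-truth sidecar (evidence location,
negation/misspelling flags, label-error flag) that drives the error
analysis.

## Assertion filter

Keyword lexicons (negation, speculation, alternatives; single lowercase
tokens, pairwise disjoint) and a sentence-terminator set, default
`. ! ? : ;`. Commas are not terminators: clinical phrasing like
"cholelithiasis, schrompelnier li?" must stay one sentence for the
question-mark rule to remove the whole claim. The filter: (1) split on
terminators, (2) drop sentences containing an alternatives keyword,
(3) drop sentences terminated by `?` (attributed to the speculation
filter), (4) truncate the rest after the *first* negation/speculation
keyword — the keyword itself is retained, which also leaves classifiers a
usable negative-context token, (5) rejoin and lowercase. Keyword matching
is on whole tokens, not substrings. The filter is idempotent and can only
remove tokens, never add them. Deliberately out of scope: negation scope
resolution, double negations, and dependency-based approaches — the
method is a keyword heuristic and its failure mode (evidence inside a
questioned or negated span) is one of the four audited error categories.

Order of operations is not dictated by the procedure itself; whole-sentence
rules run before span truncation so that a span rule never edits a
sentence that is discarded anyway.

## Features and the χ² screen

Tokenization splits on any non-alphanumeric character, keeps
single-character tokens and duplicates, drops empties. Features are
binary presence indicators. Each token is screened by a Pearson χ² test
(1 df, no continuity correction) on the 2×2 table of token presence
versus class over the **training examples of the current fold** (entries,
after set expansion, before sampling — the vocabulary is a property of the
assembled fold, not of the sampled subset); tokens with *p* < α = 0.05
are kept. Degenerate margins give statistic 0, *p* = 1. No
multiple-testing correction and no minimum-expected-count guard: the
screen is a heuristic dimensionality filter, not an inferential claim.
Document frequency counts an example once however often the token repeats.

## Rebalancing

The imbalance ratio is n⁻/n⁺ over training *entries*; displayed rounded
to the nearest integer at ≥ 1 and one decimal below 1 (the convention
that reproduces every printed study ratio from the patient/entry counts:
42, 16, 1363, 0.5, …). Under-sampling removes `round(pct% · pool)`
examples uniformly at random, where the pool is the implicit entries when
the set is expanded (each negative patient keeps its seen entry) and the
seen negative entries otherwise (removing whole negative patients);
removal counts round half away from zero — at study sizes the displayed
ratios are insensitive to the rounding rule. Positives are never removed.
Over-sampling appends `d ∈ [0, 10]` copies of every positive entry,
deterministically. The two strategies are mutually exclusive within one
sampling plan, matching how they are swept.

## MyC

A greedy binary decision tree in the ID3 family over binary features: at
each node the unused feature with the largest χ² statistic (presence vs
label, same uncorrected statistic as the feature screen) is chosen,
provided it is significant at α = 0.05 (statistic above the 1-df critical
value); recursion stops on purity, non-significance, or feature
exhaustion. No feature repeats on a path, so depth ≤ d. Leaf labels are
the node majority with ties toward positive — every tie in the package
resolves toward the positive class, consistent with the sensitivity-first
objective. Ties between equal χ² scores break toward the lower feature
index, making training invariant to example order.

Class-probability estimates use Laplace-corrected leaf frequencies
(n⁺+1)/(n+2). Raw frequencies give every pure leaf probability exactly
0 or 1 regardless of leaf size; the correction — the standard choice for
probability-estimation trees — makes a large pure negative leaf more
confidently negative than a small one, which is what the conditional-risk
relabeling below needs to respond gradually across the cost grid.

## MetaCost

Costs: C(pred, actual) with zero diagonal, C(−,+) = cost_fn the swept
parameter over {1, 10, 25, 50, 100, 200, 400, 800, 1000}, C(+,−) = 1.
Training draws `n_resamples = 10` bootstrap samples of size n, fits the
base learner on each, scores **all** training examples with **all**
models (no out-of-bag restriction — the simpler documented variant), and
averages the models' class-probability estimates into P(+|x). Learners
without a probability contract contribute hard 0/1 votes. Each example is
relabeled to the class minimizing conditional risk — positive iff
(1 − p)·C(+,−) ≤ p·C(−,+), i.e. p ≥ 1/(1+cost_fn), ties positive — and
the final base model is trained on the relabeled data. Averaged
probabilities rather than hard vote fractions are essential: hard votes
quantize P(+|x) to multiples of 1/n_resamples and concentrate at 0/1 as n
grows, which collapses the nine-step cost grid to about two effective
levels and makes the high-cost saturation regime unreachable except
through bootstrap noise. With probability averaging the relabeled-positive
set grows monotonically in cost_fn, reaching the saturation regime
(sensitivity 1.0, specificity ≈ 0) at the top of the grid.

C4.5-, RIPPER-, and SVM-class learners are deliberately not
re-implemented; `decision_tree`, `rule_inducer` (a CART tree read as an
ordered rule set), and `linear_margin` (linear kernel, soft margin
c = 4) are scikit-learn-backed stand-ins behind the same trained-model
contract.

## Evaluation

Folds partition patients (k = 5 by default, sizes differing by at most
one), never entries, so no patient's text spans training and test. Per
fold: filter and tokenize, assemble the training set per the sampling
plan, build the χ² vocabulary on the training fold only, sample, train
(wrapped in MetaCost when a cost matrix is present), then classify every
test-fold patient using **all** of their entries; the patient is positive
iff any entry is — the unique aggregation rule consistent with a gold
label defined as "evidence anywhere in the record". Sensitivity and
specificity are computed on confusion counts pooled over folds
(micro-average); pooling matches reporting a single number per
configuration and the difference from fold-averaging is second order.
Cohen's κ uses marginal-product expected agreement and the large-sample
standard error √(p₀(1−p₀)/(n(1−p_e)²)) for its 95% CI.

False negatives are attributed by a fixed cascade against the generator's
sidecar: labeling error → evidence removed by the filter (token present
in the evidence entry before filtering, absent after) → spelling variant
→ evidence not in the model. The categories are mutually exclusive; the
cascade checks the cheapest certain causes first. How ties were resolved
in a manual analysis is unknowable, so the order is a convention.

## Synthetic corpus generator

The generator produces token-level structure, not clinical prose: the
pipeline is purely lexical after filtering, so token sequences in
terminator-delimited sentences suffice and keep every mechanism
auditable. Entries draw body tokens from a Zipf-weighted background
vocabulary (300 types by default); counts per entry and entries per
patient follow negative-binomial models (defaults: 12 ± dispersion 3
tokens, 4 ± dispersion 2 entries).

The central realism choice: negative patients are *not* lexically clean.
They stand for records retrieved by a disease-specific broad query, so
their entries contain (i) evidence-adjacent work-up terms at
`circumstantial_rate` per entry (default 0.10), (ii) negated/questioned
disease mentions at half that rate — the assertion filter's reason to
exist — and (iii) a per-patient Poisson(3 × circumstantial_rate) number
of *non-convincing unnegated* disease mentions that the (notional)
reviewer judged insufficient, concentrated on a few evidence tokens by a
geometric tilt (one data set in the motivating setting was dominated by
chronic mentions of a few terms). Positive patients get exactly one
evidence-bearing seen entry — the mention negated (keyword prefix or
`?`-terminated sentence, 50/50) with probability `negation_rate` = 0.15
and realized as a fixed misspelled variant with probability
`misspelling_rate` = 0.10 — plus a per-patient Poisson(1) number of extra
mentions scattered over unseen entries, and work-up terms at rate 0.5 per
entry. `label_error_rate` (default 0) makes a positive-labeled patient's
content negative-like, for error-analysis tests. Defaults model a rare
outcome: 50 positives among 500 patients.

These choices make the class overlap graded: some evidence tokens are
clean separators, others are contaminated enough that their tree leaves
are majority-negative at high imbalance and flip as under-sampling,
duplication, or cost-relabeling shifts the ratio — which is exactly the
mechanism by which rebalancing trades specificity for sensitivity in the
real task. What the generator does **not** emulate: natural-language
syntax, coded fields, entry dates, inter-annotator disagreement
structure, realistic misspelling processes (variants are fixed alternate
surface forms), or the broad-query retrieval step itself. Passing tests
therefore demonstrate the pipeline's mechanics and its qualitative
response to imbalance handling on data with the assumed lexical
structure — not clinical-grade performance on real records.

`shape_preset` returns configs whose patient counts and corpus-wide entry
totals match the two study data sets exactly (hepatobiliary:
656/317 patients, 61,179 unseen + 27,276 implicit entries; renal:
237/3,751 patients, 58,022 + 319,204); per-patient counts are drawn from
the dispersion model and then adjusted by ±1 steps to hit the totals. A
`scale` parameter shrinks patients and totals proportionally while
preserving the class mix and per-patient entry load.

## Numerical conventions and degenerate inputs

* Removal counts, ratio display: round half away from zero.
* χ²: closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); degenerate margins →
  (0, 1); negative counts or an empty table are errors.
* Single-class training folds: the χ² screen raises; base learners
  degenerate to a constant predictor when asked directly.
* Sensitivity/specificity with empty denominators raise rather than
  return a silent 0.
* All randomness (fold assignment, under-sampling, bootstrap resamples,
  generation) flows from explicit integer seeds through NumPy
  generators; every documented operation is bit-reproducible given its
  seed.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the ratio arithmetic at
the full study shapes (up to ~381,000 generated entries; token counts are
kept minimal there since ratios depend only on counts), the trend checks
on 500-patient default-noise corpora averaged over 10 seeds (test suite)
or endpoint plans over 3 seeds (acceptance script), and the MetaCost
saturation check on a renal-shaped corpus at scale 0.05 (200 patients,
~19,000 entries, preserving the ~95-entries-per-patient record load that
makes any-entry-positive aggregation collapse specificity at saturating
cost). The complete suite runs in about a minute on one CPU.

## Known limitations

* The assertion filter's span rule always truncates to the sentence end;
  intervening conjunctions are not handled.
* MetaCost's probability estimates are uncalibrated leaf frequencies;
  the cost grid's effective resolution depends on leaf sizes.
* The patient-level any-positive rule means one noisy entry flips a
  whole patient; with very long records specificity is the fragile
  metric (this is faithful to the task, not an artifact).
* Error-analysis categories depend on a ground-truth sidecar and are
  therefore only available for synthetic corpora.
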