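"""Subject-level cross-validation and patient-level evaluation.

Folds are assigned to *patients*, never to entries, so no patient's text
ever spans a training and a test set.  Within each fold the pipeline is:
assertion-filter and tokenize every entry; assemble the training set
(seen entries, plus implicit entries under set expansion); build the
chi-square feature vocabulary on that training fold only; apply the
sampling plan; train the learner (wrapped in MetaCost when a cost matrix
is given); then classify every patient of the test fold.

A patient is predicted positive iff at least one of their entries —
seen, implicit, or unseen — is classified positive, mirroring how the
gold label is defined (evidence anywhere in the record).  Sensitivity and
specificity are computed on confusion counts pooled over folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assertion import KeywordLexicon, apply_assertion_filter
from .corpus import Corpus, GroundTruthRecord, PatientRecord
from .features import FeatureVocabulary, build_vocabulary, tokenize, vectorize_many
from .learners import (
    POSITIVE,
    BaseLearnerSpec,
    CostMatrix,
    TrainedModel,
    metacost_train,
    train_base,
)
from .rebalance import (
    SamplingPlan,
    apply_plan,
    assemble_training_set,
    imbalance_ratio,
)


class MetricError(ValueError):
    """A metric's denominator is empty."""


@dataclass(frozen=True)
class FoldAssignment:
    """Patient -> fold-index map for k-fold subject-level cross-validation."""

    assignment: Mapping[str, int]
    k: int
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.assignment[patient_id]

    def patients_in(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == fold]


def make_folds(corpus: Corpus, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Randomly partition patients into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, have {len(corpus)}")
    rng = np.random.default_rng(seed)
    pids = [p.patient_id for p in corpus]
    order = rng.permutation(len(pids))
    assignment = {pids[int(i)]: (pos % k) + 1 for pos, i in enumerate(order)}
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


@dataclass(frozen=True)
class ConfusionCounts:
    """Patient-level confusion counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def sensitivity(counts: ConfusionCounts) -> float:
    """True-positive recognition rate tp / (tp + fn)."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise MetricError("sensitivity undefined: no positive patients evaluated")
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """True-negative recognition rate tn / (tn + fp)."""
    denom = counts.tn + counts.fp
    if denom == 0:
        raise MetricError("specificity undefined: no negative patients evaluated")
    return counts.tn / denom


def cohen_kappa(agreement_table: Sequence[Sequence[float]]) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa for a 2x2 inter-annotator agreement table, with 95% CI.

    Expected agreement uses marginal products; the confidence interval is
    kappa +/- 1.96 * SE with the large-sample standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    t = np.asarray(agreement_table, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("agreement table must be 2x2 with non-negative counts")
    n = t.sum()
    if n == 0:
        raise ValueError("agreement table is empty")
    p_o = np.trace(t) / n
    row = t.sum(axis=1) / n
    col = t.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e == 1.0:
        raise MetricError("kappa undefined: chance agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    return float(kappa), (float(kappa - 1.96 * se), float(kappa + 1.96 * se))


def filtered_tokens(corpus: Corpus, lexicon: KeywordLexicon) -> dict[tuple[str, str], tuple[str, ...]]:
    """Assertion-filter and tokenize every entry once, keyed by (patient, entry)."""
    cache: dict[tuple[str, str], tuple[str, ...]] = {}
    for p in corpus:
        for e in p.entries:
            cache[(p.patient_id, e.entry_id)] = tuple(
                tokenize(apply_assertion_filter(e.text, lexicon))
            )
    return cache


def classify_patient(
    model: TrainedModel,
    patient: PatientRecord,
    vocab: FeatureVocabulary,
    lexicon: KeywordLexicon,
    _tokens_cache: Mapping[tuple[str, str], tuple[str, ...]] | None = None,
) -> str:
    """Predict a patient label from all of their entries (any-positive rule)."""
    token_lists = []
    for e in patient.entries:
        if _tokens_cache is not None:
            token_lists.append(list(_tokens_cache[(patient.patient_id, e.entry_id)]))
        else:
            token_lists.append(tokenize(apply_assertion_filter(e.text, lexicon)))
    X = vectorize_many(token_lists, vocab)
    preds = model.predict(X)
    return "positive" if (preds == POSITIVE).any() else "negative"


@dataclass
class EvalResult:
    """Pooled and per-fold outcome of one pipeline configuration."""

    pooled: ConfusionCounts
    per_fold: list[ConfusionCounts]
    sensitivity: float
    specificity: float
    plan: SamplingPlan
    learner: BaseLearnerSpec
    cost: CostMatrix | None
    imbalance: float
    predictions: dict[str, str] = field(default_factory=dict)
    vocab_sizes: list[tuple[int, int]] = field(default_factory=list)  # (total, selected) per fold


def run_experiment(
    corpus: Corpus,
    folds: FoldAssignment,
    plan: SamplingPlan,
    learner: BaseLearnerSpec,
    cost: CostMatrix | None,
    lexicon: KeywordLexicon,
    n_resamples: int = 10,
    alpha: float = 0.05,
    _tokens_cache: Mapping[tuple[str, str], tuple[str, ...]] | None = None,
) -> EvalResult:
    """Run one configuration through subject-level k-fold cross-validation.

    ``_tokens_cache`` (from :func:`filtered_tokens`) lets sweeps reuse the
    fold-independent filter/tokenize work.
    """
    cache = _tokens_cache if _tokens_cache is not None else filtered_tokens(corpus, lexicon)
    tokens_of = lambda e: cache[(e.patient_id, e.entry_id)]
    by_fold: dict[int, list[PatientRecord]] = {f: [] for f in range(1, folds.k + 1)}
    for p in corpus:
        by_fold[folds.fold_of(p.patient_id)].append(p)

    per_fold: list[ConfusionCounts] = []
    predictions: dict[str, str] = {}
    vocab_sizes: list[tuple[int, int]] = []
    ratios: list[float] = []
    for f in range(1, folds.k + 1):
        test_patients = by_fold[f]
        train_patients = [p for g, ps in by_fold.items() if g != f for p in ps]
        try:
            examples = assemble_training_set(
                train_patients, plan.use_set_expansion, tokens_of=tokens_of
            )
            vocab = build_vocabulary(
                [(list(ex.tokens), ex.label) for ex in examples], alpha=alpha
            )
            sampled = apply_plan(examples, plan)
            ratios.append(imbalance_ratio(sampled))
            X = vectorize_many([list(ex.tokens) for ex in sampled], vocab)
            y = np.array([ex.label for ex in sampled], dtype=np.int64)
            if cost is not None:
                model: TrainedModel = metacost_train(
                    learner, X, y, cost, n_resamples=n_resamples, rng=plan.seed + f
                )
            else:
                model = train_base(learner, X, y)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in fold {f}") from exc
        vocab_sizes.append((vocab.n_tokens, vocab.n_selected))
        tp = fp = tn = fn = 0
        for p in test_patients:
            pred = classify_patient(model, p, vocab, lexicon, _tokens_cache=cache)
            predictions[p.patient_id] = pred
            if p.is_positive:
                tp += pred == "positive"
                fn += pred == "negative"
            else:
                fp += pred == "positive"
                tn += pred == "negative"
        per_fold.append(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))

    pooled = ConfusionCounts()
    for c in per_fold:
        pooled = pooled + c
    return EvalResult(
        pooled=pooled,
        per_fold=per_fold,
        sensitivity=sensitivity(pooled),
        specificity=specificity(pooled),
        plan=plan,
        learner=learner,
        cost=cost,
        imbalance=float(np.mean(ratios)),
        predictions=predictions,
        vocab_sizes=vocab_sizes,
    )


ERROR_CATEGORIES = (
    "evidence_not_in_model",
    "evidence_removed_by_filter",
    "spelling_variant",
    "labeling_error",
)


@dataclass(frozen=True)
class ErrorBreakdown:
    """False-negative counts in the four diagnostic categories."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        n = self.total
        return {k: (100.0 * v / n if n else 0.0) for k, v in self.counts.items()}


def categorize_false_negatives(
    fn_patients: Sequence[PatientRecord],
    model: TrainedModel,
    vocab: FeatureVocabulary,
    lexicon: KeywordLexicon,
    truth: Mapping[str, GroundTruthRecord],
) -> ErrorBreakdown:
    """Assign each missed positive patient to one error category.

    Decision cascade: (1) ``labeling_error`` if the sidecar marks the gold
    label erroneous; (2) ``evidence_removed_by_filter`` if the evidence
    token is present in the evidence entry before filtering but absent
    after; (3) ``spelling_variant`` if the sidecar marks the evidence
    misspelled; (4) otherwise ``evidence_not_in_model``.
    """
    counts = {cat: 0 for cat in ERROR_CATEGORIES}
    for p in fn_patients:
        rec = truth.get(p.patient_id)
        if rec is None:
            raise KeyError(f"no ground-truth sidecar record for patient {p.patient_id!r}")
        if rec.label_is_error or rec.evidence_entry_id is None:
            counts["labeling_error"] += 1
            continue
        entry = next(e for e in p.entries if e.entry_id == rec.evidence_entry_id)
        pre = tokenize(entry.text.lower())
        post = tokenize(apply_assertion_filter(entry.text, lexicon))
        if rec.evidence_token in pre and rec.evidence_token not in post:
            counts["evidence_removed_by_filter"] += 1
        elif rec.evidence_misspelled:
            counts["spelling_variant"] += 1
        else:
            counts["evidence_not_in_model"] += 1
    return ErrorBreakdown(counts=counts)
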