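"""Model/Results front end for the case-identification pipeline.

:class:`CaseIdentificationModel` bundles a labeled corpus with one pipeline
configuration (lexicon, sampling plan, learner, optional cost matrix) and
``fit()`` runs subject-level cross-validation, returning a
:class:`CaseIdentificationResults` that carries the patient-level confusion
counts, sensitivity/specificity, per-fold diagnostics, and a ``summary()``
table.  Grid sweeps over sampling percentages, duplication counts, or
misclassification costs hang off the model as ``sweep()``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assertion import KeywordLexicon, default_lexicon
from .corpus import Corpus, read_corpus
from .evaluation import (
    EvalResult,
    FoldAssignment,
    filtered_tokens,
    make_folds,
    run_experiment,
)
from .learners import COST_GRID, BaseLearnerSpec, CostMatrix
from .rebalance import SamplingPlan, format_ratio

UNDERSAMPLE_GRID = tuple(range(0, 101, 10))
OVERSAMPLE_GRID = tuple(range(0, 11))


class CaseIdentificationModel:
    """A case-identification experiment over one labeled corpus.

    Parameters
    ----------
    corpus
        Labeled patient records.
    lexicon
        Assertion-filter keywords; defaults to the packaged Dutch lexicon.
    plan
        Set-expansion and sampling settings (default: seen entries only,
        no resampling).
    learner
        Base-learner family (default MyC).
    cost
        Optional cost matrix; when given, training is wrapped in MetaCost.
    k, seed
        Cross-validation fold count and fold/sampling seed.
    """

    def __init__(
        self,
        corpus: Corpus,
        lexicon: KeywordLexicon | None = None,
        plan: SamplingPlan | None = None,
        learner: BaseLearnerSpec | None = None,
        cost: CostMatrix | None = None,
        k: int = 5,
        seed: int = 0,
        n_resamples: int = 10,
        alpha: float = 0.05,
    ):
        self.corpus = corpus
        self.lexicon = lexicon if lexicon is not None else default_lexicon()
        self.plan = plan if plan is not None else SamplingPlan(seed=seed)
        self.learner = learner if learner is not None else BaseLearnerSpec("myc")
        self.cost = cost
        self.k = k
        self.seed = seed
        self.n_resamples = n_resamples
        self.alpha = alpha
        self._folds: FoldAssignment | None = None
        self._tokens_cache = None

    @classmethod
    def from_jsonl(cls, path, **kwargs) -> "CaseIdentificationModel":
        """Build a model from a JSON-lines corpus file."""
        return cls(read_corpus(path), **kwargs)

    @property
    def folds(self) -> FoldAssignment:
        if self._folds is None:
            self._folds = make_folds(self.corpus, k=self.k, seed=self.seed)
        return self._folds

    def _cache(self):
        if self._tokens_cache is None:
            self._tokens_cache = filtered_tokens(self.corpus, self.lexicon)
        return self._tokens_cache

    def fit(self) -> "CaseIdentificationResults":
        """Run cross-validation for the configured pipeline."""
        res = run_experiment(
            self.corpus,
            self.folds,
            self.plan,
            self.learner,
            self.cost,
            self.lexicon,
            n_resamples=self.n_resamples,
            alpha=self.alpha,
            _tokens_cache=self._cache(),
        )
        return CaseIdentificationResults(model=self, result=res)

    def sweep(self, mode: str, grid=None) -> pd.DataFrame:
        """Evaluate a grid of one rebalancing knob.

        ``mode`` is ``"undersample"`` (percentages 0–100), ``"oversample"``
        (duplication counts 0–10), or ``"cost"`` (the 9-step
        misclassification-cost grid).  Returns one row per grid point with
        sensitivity, specificity, and the realized imbalance ratio.
        """
        rows = []
        if mode == "undersample":
            grid = UNDERSAMPLE_GRID if grid is None else grid
            configs = [
                (g, replace(self.plan, undersample_pct=g, oversample_duplications=0), self.cost)
                for g in grid
            ]
        elif mode == "oversample":
            grid = OVERSAMPLE_GRID if grid is None else grid
            configs = [
                (g, replace(self.plan, oversample_duplications=g, undersample_pct=0), self.cost)
                for g in grid
            ]
        elif mode == "cost":
            grid = COST_GRID if grid is None else grid
            configs = [(g, self.plan, CostMatrix(cost_fn=float(g))) for g in grid]
        else:
            raise ValueError("mode must be 'undersample', 'oversample', or 'cost'")
        for g, plan, cost in configs:
            res = run_experiment(
                self.corpus, self.folds, plan, self.learner, cost, self.lexicon,
                n_resamples=self.n_resamples, alpha=self.alpha,
                _tokens_cache=self._cache(),
            )
            rows.append(
                {
                    mode: g,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "imbalance_ratio": res.imbalance,
                    "imbalance_display": format_ratio(res.imbalance),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CaseIdentificationResults:
    """Fitted-pipeline results with summary and diagnostic accessors."""

    model: CaseIdentificationModel
    result: EvalResult

    @property
    def sensitivity(self) -> float:
        return self.result.sensitivity

    @property
    def specificity(self) -> float:
        return self.result.specificity

    @property
    def confusion(self):
        return self.result.pooled

    @property
    def imbalance_ratio(self) -> float:
        return self.result.imbalance

    @property
    def predictions(self) -> dict[str, str]:
        return self.result.predictions

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"fold": i + 1, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                for i, c in enumerate(self.result.per_fold)
            ]
        )

    def summary(self) -> str:
        """Human-readable report of the fitted configuration and metrics."""
        r = self.result
        c = r.pooled
        mean_vocab = np.mean([t for t, _ in r.vocab_sizes]) if r.vocab_sizes else 0
        mean_sel = np.mean([s for _, s in r.vocab_sizes]) if r.vocab_sizes else 0
        lines = [
            "Case identification results (subject-level cross-validation)",
            "=" * 62,
            f"patients: {len(self.model.corpus)}   folds: {self.model.k}   seed: {self.model.seed}",
            f"learner: {r.learner.family}   set expansion: {r.plan.use_set_expansion}",
            f"undersample: {r.plan.undersample_pct:g}%   "
            f"oversample duplications: {r.plan.oversample_duplications}",
            f"cost (fn): {r.cost.cost_fn:g}" if r.cost else "cost-sensitive: no",
            f"mean vocabulary: {mean_vocab:.0f} tokens, {mean_sel:.0f} selected (alpha={self.model.alpha:g})",
            f"realized imbalance ratio: {format_ratio(r.imbalance)} ({r.imbalance:.3f})",
            "-" * 62,
            f"confusion (patients): tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}",
            f"sensitivity: {r.sensitivity:.2f}",
            f"specificity: {r.specificity:.2f}",
        ]
        return "\n".join(lines)
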