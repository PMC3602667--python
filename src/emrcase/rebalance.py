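"""Training-set assembly, set expansion, and class rebalancing.

Training examples are entries, not patients.  Without *set expansion* only
the seen entries are used (one example per patient, labeled by the patient
label).  With set expansion every implicit entry of a negative patient is
added as an extra negative example; unseen entries of positive patients are
never trained on.

Two rebalancing strategies shift the imbalance ratio (negatives per
positive example):

* **under-sampling** removes a percentage of negative examples at random —
  only implicit entries when the set is expanded (each negative patient
  keeps its seen entry), seen negative entries otherwise;
* **over-sampling** duplicates every positive entry a fixed number of times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

PROVENANCES = ("seen_pos", "seen_neg", "implicit", "duplicate")


@dataclass(frozen=True)
class TrainingExample:
    """One entry prepared for training: filtered tokens plus a binary label."""

    patient_id: str
    entry_id: str
    tokens: tuple[str, ...]
    label: int  # 1 = positive, 0 = negative
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        positive_prov = self.provenance in ("seen_pos", "duplicate")
        if (self.label == 1) != positive_prov:
            raise ValueError(
                f"label {self.label} inconsistent with provenance {self.provenance!r}"
            )


@dataclass(frozen=True)
class SamplingPlan:
    """Rebalancing knobs for one experiment configuration.

    Under- and over-sampling are alternative strategies and are never both
    active in one plan.
    """

    use_set_expansion: bool = False
    undersample_pct: float = 0.0
    oversample_duplications: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.undersample_pct <= 100:
            raise ValueError("undersample_pct must be in [0, 100]")
        if not 0 <= self.oversample_duplications <= 10:
            raise ValueError("oversample_duplications must be in [0, 10]")
        if self.undersample_pct > 0 and self.oversample_duplications > 0:
            raise ValueError("under- and over-sampling are mutually exclusive in a plan")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def assemble_training_set(
    train_patients: Sequence, use_set_expansion: bool,
    tokens_of=None,
) -> list[TrainingExample]:
    """Build the entry-level training set for a fold.

    ``tokens_of(entry)`` maps an entry to its (post-filter) token list; by
    default the entry text is split on whitespace, which suits text that is
    already filtered and tokenizable.  Unseen entries are never included.
    """
    if tokens_of is None:
        tokens_of = lambda e: tuple(e.text.split())
    out: list[TrainingExample] = []
    for p in train_patients:
        for e in p.entries:
            if e.role == "seen":
                out.append(
                    TrainingExample(
                        patient_id=p.patient_id,
                        entry_id=e.entry_id,
                        tokens=tuple(tokens_of(e)),
                        label=1 if p.gold_label == "positive" else 0,
                        provenance="seen_pos" if p.gold_label == "positive" else "seen_neg",
                    )
                )
            elif e.role == "implicit" and use_set_expansion:
                out.append(
                    TrainingExample(
                        patient_id=p.patient_id,
                        entry_id=e.entry_id,
                        tokens=tuple(tokens_of(e)),
                        label=0,
                        provenance="implicit",
                    )
                )
    return out


def undersample(
    examples: Sequence[TrainingExample],
    pct: float,
    use_set_expansion: bool,
    rng: np.random.Generator,
) -> list[TrainingExample]:
    """Randomly remove ``pct`` percent of the eligible negative examples.

    With set expansion the eligible pool is the implicit entries, so every
    negative patient keeps at least its seen entry; without expansion the
    pool is the seen negative entries, effectively removing negative
    patients.  Positive examples are never removed.  The removal count is
    ``pct% * pool size`` rounded half away from zero.
    """
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    pool_prov = "implicit" if use_set_expansion else "seen_neg"
    pool_idx = [i for i, ex in enumerate(examples) if ex.provenance == pool_prov]
    n_remove = _round_half_away(pct / 100.0 * len(pool_idx))
    removed = set(rng.choice(pool_idx, size=n_remove, replace=False)) if n_remove else set()
    return [ex for i, ex in enumerate(examples) if i not in removed]


def oversample(
    examples: Sequence[TrainingExample], duplications: int
) -> list[TrainingExample]:
    """Append ``duplications`` copies of every positive example.

    Deterministic: each positive entry ends up ``duplications + 1`` times in
    the output, copies carrying provenance ``"duplicate"``.
    """
    if not 0 <= duplications <= 10:
        raise ValueError("duplications must be in [0, 10]")
    out = list(examples)
    for ex in examples:
        if ex.label == 1 and ex.provenance != "duplicate":
            dup = TrainingExample(
                patient_id=ex.patient_id,
                entry_id=ex.entry_id,
                tokens=ex.tokens,
                label=1,
                provenance="duplicate",
            )
            out.extend([dup] * duplications)
    return out


def apply_plan(
    examples: Sequence[TrainingExample], plan: SamplingPlan
) -> list[TrainingExample]:
    """Apply a sampling plan's under- or over-sampling to an assembled set."""
    if plan.undersample_pct > 0:
        rng = np.random.default_rng(plan.seed)
        return undersample(examples, plan.undersample_pct, plan.use_set_expansion, rng)
    if plan.oversample_duplications > 0:
        return oversample(examples, plan.oversample_duplications)
    return list(examples)


def imbalance_ratio(examples: Sequence[TrainingExample]) -> float:
    """Negative examples divided by positive examples (exact quotient)."""
    n_pos = sum(1 for ex in examples if ex.label == 1)
    n_neg = len(examples) - n_pos
    if n_pos == 0:
        raise ZeroDivisionError("imbalance ratio undefined without positive examples")
    return n_neg / n_pos


def format_ratio(ratio: float) -> str:
    """Display convention: nearest integer when >= 1, one decimal below 1."""
    if ratio >= 1:
        return str(_round_half_away(ratio))
    return f"{ratio:.1f}"
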