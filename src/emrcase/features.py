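"""Binary bag-of-words featurization with per-fold chi-square selection.

Filtered entry text is tokenized into lowercase alphanumeric tokens and
represented as binary presence/absence vectors.  Each token is screened by
a Pearson chi-square test (2x2 table of token presence vs class, 1 df, no
continuity correction) on the training examples of the current fold, and
kept when p < alpha (default 0.05).  The screen is a heuristic filter, so
no multiple-testing correction is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05

_SPLIT_RE = re.compile(r"[\W_]+", re.UNICODE)


def tokenize(filtered_text: str) -> list[str]:
    """Split lowercase text on any non-alphanumeric character.

    Empty fragments are dropped; single-character tokens and duplicates
    are kept; order is preserved.
    """
    return [t for t in _SPLIT_RE.split(filtered_text) if t]


def chi_square_statistic(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], 1 df.

    ``a``/``b`` count positive/negative examples containing the token and
    ``c``/``d`` those lacking it.  No continuity correction.  Degenerate
    margins (an empty row or column) return (0.0, 1.0).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass
class FeatureVocabulary:
    """Token universe of a training fold with chi-square selection flags.

    Tokens appear in first-occurrence order; ``selected[i]`` is true exactly
    when ``p_value[i] < alpha``.
    """

    tokens: list[str]
    chi2_stat: np.ndarray
    p_value: np.ndarray
    selected: np.ndarray
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.tokens)}
        sel = np.flatnonzero(self.selected)
        self._selected_col = {self.tokens[i]: j for j, i in enumerate(sel)}

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_tokens(self) -> list[str]:
        return [t for t, keep in zip(self.tokens, self.selected) if keep]

    def stat_of(self, token: str) -> float:
        return float(self.chi2_stat[self._index[token]])

    def is_selected(self, token: str) -> bool:
        return token in self._selected_col

    def to_table(self) -> str:
        """Tab-separated dump: token, statistic, p_value, selected."""
        lines = ["token\tchi2\tp_value\tselected"]
        for i, t in enumerate(self.tokens):
            lines.append(
                f"{t}\t{self.chi2_stat[i]:.6g}\t{self.p_value[i]:.6g}"
                f"\t{int(self.selected[i])}"
            )
        return "\n".join(lines) + "\n"


def build_vocabulary(
    training_examples: list[tuple[list[str], int]],
    alpha: float = DEFAULT_ALPHA,
) -> FeatureVocabulary:
    """Score every distinct training token by chi-square association with the label.

    ``training_examples`` pairs a token list with a binary label (1 =
    positive).  Document frequency is presence-based: a token counts once
    per example.  Requires at least one example of each class.
    """
    labels = [lab for _, lab in training_examples]
    n_pos = sum(1 for lab in labels if lab == 1)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("chi-square selection needs both classes in the training set")

    tokens: list[str] = []
    index: dict[str, int] = {}
    df_pos: list[int] = []
    df_neg: list[int] = []
    for toks, lab in training_examples:
        for t in dict.fromkeys(toks):  # presence-based, first-occurrence order
            i = index.get(t)
            if i is None:
                index[t] = len(tokens)
                tokens.append(t)
                df_pos.append(0)
                df_neg.append(0)
                i = index[t]
            if lab == 1:
                df_pos[i] += 1
            else:
                df_neg[i] += 1

    a = np.asarray(df_pos, dtype=np.float64)
    b = np.asarray(df_neg, dtype=np.float64)
    c = n_pos - a
    d = n_neg - b
    n = float(len(labels))
    r1, r2 = a + b, c + d
    c1, c2 = float(n_pos), float(n_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    stat = np.where(degenerate, 0.0, stat)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(degenerate, 1.0, p)
    return FeatureVocabulary(
        tokens=tokens,
        chi2_stat=stat,
        p_value=p,
        selected=p < alpha,
        alpha=alpha,
    )


def vectorize(tokens: list[str], vocab: FeatureVocabulary) -> np.ndarray:
    """Binary presence vector over the vocabulary's selected tokens.

    Out-of-vocabulary and unselected tokens are ignored; repeated tokens
    still yield 1.
    """
    x = np.zeros(vocab.n_selected, dtype=np.int8)
    col = vocab._selected_col
    for t in tokens:
        j = col.get(t)
        if j is not None:
            x[j] = 1
    return x


def vectorize_many(token_lists: list[list[str]], vocab: FeatureVocabulary) -> np.ndarray:
    """Stack :func:`vectorize` over many token lists into an (n, d) matrix."""
    X = np.zeros((len(token_lists), vocab.n_selected), dtype=np.int8)
    col = vocab._selected_col
    for i, toks in enumerate(token_lists):
        for t in toks:
            j = col.get(t)
            if j is not None:
                X[i, j] = 1
    return X
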