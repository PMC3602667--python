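"""Synthetic EMR corpus generator with ground-truth sidecar.

The generator emulates the *lexical* structure the case-identification
pipeline assumes, not clinical prose: entries are synthetic token
sequences grouped into terminator-delimited sentences.  Its central
realism choice is that negative patients are not lexically clean — they
were (notionally) retrieved by a broad disease query, so their records
contain negated/speculative disease mentions, evidence-adjacent work-up
terms, and occasional *non-convincing* unnegated disease mentions that a
human reviewer judged insufficient.  Those shared tokens are what makes
the sensitivity/specificity trade-off under rebalancing real.

Per patient:

* positive — exactly one evidence-bearing seen entry (the evidence token
  possibly negated, speculated away behind a '?', or realized as a fixed
  misspelled variant), plus unseen entries; a small per-patient number of
  extra evidence mentions is scattered over the unseen entries (a disease
  episode yields a few mentions regardless of record length);
* negative — one seen entry plus implicit entries from a Zipf-weighted
  background vocabulary, with work-up terms at ``circumstantial_rate``
  per entry, negated disease mentions, and a per-patient Poisson number
  of non-convincing unnegated disease mentions.

A ground-truth sidecar records, per patient, where the evidence sits and
whether it was negated, misspelled, or the label itself is wrong, which
makes the four-way false-negative error analysis checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, Entry, GroundTruthRecord, PatientRecord

#: Canonical evidence tokens with their fixed misspelled surface variants,
#: loosely modeled on hepatobiliary disease vocabulary.
DEFAULT_EVIDENCE_LEXICON: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("cholelithiasis", ("cholelitiasis",)),
    ("cholecystitis", ("cholesystitis",)),
    ("hepatitis", ("hepatitus",)),
    ("levercirrose", ("levercirrhose",)),
    ("cholestase", ("colestase",)),
    ("hepatomegalie", ("hepatomegali",)),
)

#: Evidence-adjacent work-up terms (imaging, anatomy, complaints) that occur
#: in both classes with a positive tilt — weak signal.
DEFAULT_CIRCUMSTANTIAL_TERMS: tuple[str, ...] = (
    "echo", "galblaas", "leverfunctie", "icterus", "buikpijn",
)

# Negation surface forms used when planting negated mentions; covered by
# the default Dutch lexicon so the assertion filter removes these spans.
_NEGATION_PREFIXES = ("geen", "niet")

# Fixed realization constants (documented generator behavior, not knobs):
POS_CIRCUMSTANTIAL_RATE = 0.5     # work-up term rate in positive entries
POS_EXTRA_EVIDENCE_LAMBDA = 1.0   # mean extra evidence mentions per positive patient
NEG_CONFUSER_LAMBDA_FACTOR = 3.0  # per-patient non-convincing mentions, x circumstantial_rate
NEG_NEGATED_EVIDENCE_FACTOR = 0.5  # per-entry negated mentions, x circumstantial_rate
# Non-convincing mentions concentrate on a few disease terms (the way
# chronic-condition vocabulary dominated one study data set), so some
# evidence tokens are much more contaminated than others:
CONFUSER_TILT = 0.5  # geometric decay over the evidence lexicon order

_SENTENCE_LEN = 8


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults are a small realistic screening sample.

    ``entries_per_patient`` and ``tokens_per_entry`` are (mean, dispersion)
    pairs of a negative-binomial count model; ``exact_total_unseen`` /
    ``exact_total_implicit``, when set, pin the corpus-wide entry totals
    exactly (per-patient draws are adjusted to match).
    """

    n_positive: int = 50
    n_negative: int = 450
    entries_per_patient: tuple[float, float] = (4.0, 2.0)
    evidence_lexicon: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_EVIDENCE_LEXICON
    background_vocab_size: int = 300
    tokens_per_entry: tuple[float, float] = (12.0, 3.0)
    negation_rate: float = 0.15
    misspelling_rate: float = 0.10
    circumstantial_rate: float = 0.10
    label_error_rate: float = 0.0
    seed: int = 0
    circumstantial_terms: tuple[str, ...] = DEFAULT_CIRCUMSTANTIAL_TERMS
    exact_total_unseen: int | None = None
    exact_total_implicit: int | None = None
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("need at least one patient of each class")
        for rate_name in ("negation_rate", "misspelling_rate", "circumstantial_rate", "label_error_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1], got {r}")
        if self.background_vocab_size < 10:
            raise ValueError("background_vocab_size must be >= 10")
        if not self.evidence_lexicon:
            raise ValueError("evidence_lexicon must be non-empty")
        for pair in (self.entries_per_patient, self.tokens_per_entry):
            if pair[0] < 1 or pair[1] <= 0:
                raise ValueError("count distributions need mean >= 1 and dispersion > 0")


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int, low: int) -> np.ndarray:
    """Negative-binomial draws with the given mean, clipped below at ``low``."""
    if mean <= 0:
        return np.full(size, low, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=size), low)


def _match_total(rng: np.random.Generator, counts: np.ndarray, target: int, low: int) -> np.ndarray:
    """Adjust integer draws by +/-1 steps until they sum to ``target`` exactly."""
    counts = counts.copy()
    diff = int(target - counts.sum())
    while diff != 0:
        i = int(rng.integers(0, len(counts)))
        if diff > 0:
            counts[i] += 1
            diff -= 1
        elif counts[i] > low:
            counts[i] -= 1
            diff += 1
    return counts


class _TokenPool:
    """Pre-drawn Zipf-weighted background tokens, consumed sequentially."""

    def __init__(self, rng: np.random.Generator, vocab_size: int):
        self._rng = rng
        ranks = np.arange(1, vocab_size + 1, dtype=np.float64)
        weights = 1.0 / (ranks + 2.7)
        self._probs = weights / weights.sum()
        self._vocab = np.array([f"t{i:03d}" for i in range(vocab_size)])
        self._buf = np.empty(0, dtype=np.int64)
        self._cursor = 0

    def take(self, k: int) -> list[str]:
        if self._cursor + k > len(self._buf):
            n = max(k, 4096)
            self._buf = self._rng.choice(len(self._vocab), size=n, p=self._probs)
            self._cursor = 0
        out = self._vocab[self._buf[self._cursor:self._cursor + k]]
        self._cursor += k
        return list(out)


def _render_entry(
    rng: np.random.Generator,
    body: list[str],
    insertions: list[tuple[str, str | None]],
) -> str:
    """Assemble sentences from body tokens plus (token, mode) insertions.

    ``mode`` is ``None`` (plain mention), a negation keyword (placed
    immediately before the token, so span truncation removes the token), or
    ``"?"`` (the sentence is terminated by a question mark).
    """
    sentences = [body[i:i + _SENTENCE_LEN] for i in range(0, len(body), _SENTENCE_LEN)]
    if not sentences:
        sentences = [["status"]]
    terminators = ["."] * len(sentences)
    for token, mode in insertions:
        s = int(rng.integers(0, len(sentences)))
        pos = int(rng.integers(0, len(sentences[s]) + 1))
        sentences[s].insert(pos, token)
        if mode == "?":
            terminators[s] = "?"
        elif mode is not None:  # negation keyword directly before the mention
            sentences[s].insert(pos, mode)
    return " ".join(" ".join(s) + t for s, t in zip(sentences, terminators))


def generate(config: SyntheticConfig) -> tuple[Corpus, list[GroundTruthRecord]]:
    """Generate a labeled corpus and its ground-truth sidecar.

    Deterministic given the config (including its seed).  The output always
    satisfies the corpus invariants: one seen entry per patient, unseen
    entries only on positives, implicit entries only on negatives.
    """
    rng = np.random.default_rng(config.seed)
    pool = _TokenPool(rng, config.background_vocab_size)
    ev_mean, ev_disp = config.entries_per_patient
    tk_mean, tk_disp = config.tokens_per_entry

    n_pos, n_neg = config.n_positive, config.n_negative
    extra_pos = _nb_counts(rng, ev_mean - 1, ev_disp, n_pos, 0)
    extra_neg = _nb_counts(rng, ev_mean - 1, ev_disp, n_neg, 0)
    if config.exact_total_unseen is not None:
        extra_pos = _match_total(rng, extra_pos, config.exact_total_unseen, 0)
    if config.exact_total_implicit is not None:
        extra_neg = _match_total(rng, extra_neg, config.exact_total_implicit, 0)

    evidence = config.evidence_lexicon
    circ = config.circumstantial_terms

    def realize_evidence() -> tuple[str, bool, bool, tuple[str, str | None]]:
        canonical, variants = evidence[int(rng.integers(0, len(evidence)))]
        misspelled = bool(variants) and rng.random() < config.misspelling_rate
        surface = variants[int(rng.integers(0, len(variants)))] if misspelled else canonical
        negated = rng.random() < config.negation_rate
        if negated:
            mode = "?" if rng.random() < 0.5 else _NEGATION_PREFIXES[int(rng.integers(0, 2))]
        else:
            mode = None
        return surface, negated, misspelled, (surface, mode)

    def circ_insertion(p_circ: float) -> list[tuple[str, str | None]]:
        if circ and rng.random() < p_circ:
            return [(circ[int(rng.integers(0, len(circ)))], None)]
        return []

    def negated_mention() -> tuple[str, str | None]:
        canonical, _ = evidence[int(rng.integers(0, len(evidence)))]
        mode = "?" if rng.random() < 0.5 else _NEGATION_PREFIXES[int(rng.integers(0, 2))]
        return (canonical, mode)

    def body() -> list[str]:
        k = int(_nb_counts(rng, tk_mean, tk_disp, 1, 3)[0])
        return pool.take(k)

    patients: list[PatientRecord] = []
    sidecar: list[GroundTruthRecord] = []
    eid = 0

    def next_eid() -> str:
        nonlocal eid
        eid += 1
        return f"e{eid:06d}"

    neg_negated_rate = config.circumstantial_rate * NEG_NEGATED_EVIDENCE_FACTOR
    confuser_lambda = config.circumstantial_rate * NEG_CONFUSER_LAMBDA_FACTOR
    confuser_w = CONFUSER_TILT ** np.arange(len(evidence))
    confuser_w = confuser_w / confuser_w.sum()

    def confuser_token() -> str:
        canonical, _ = evidence[int(rng.choice(len(evidence), p=confuser_w))]
        return canonical

    for i in range(n_pos):
        pid = f"pos{i + 1:05d}"
        label_error = rng.random() < config.label_error_rate
        n_unseen = int(extra_pos[i])
        # insertion lists per entry: index 0 is the seen entry
        ins: list[list[tuple[str, str | None]]] = [[] for _ in range(1 + n_unseen)]
        if label_error:
            # content generated like a negative record, but labeled positive
            for j in range(1 + n_unseen):
                ins[j] += circ_insertion(config.circumstantial_rate)
                if rng.random() < neg_negated_rate:
                    ins[j].append(negated_mention())
            sidecar.append(GroundTruthRecord(pid, None, None, False, False, True))
        else:
            surface, negated, misspelled, mention = realize_evidence()
            ins[0].append(mention)
            # a few more mentions of the episode, scattered over unseen entries
            if n_unseen > 0:
                for _ in range(int(rng.poisson(POS_EXTRA_EVIDENCE_LAMBDA))):
                    j = 1 + int(rng.integers(0, n_unseen))
                    _, _, _, extra_mention = realize_evidence()
                    ins[j].append(extra_mention)
            for j in range(1 + n_unseen):
                ins[j] += circ_insertion(POS_CIRCUMSTANTIAL_RATE)
        entries = []
        for j in range(1 + n_unseen):
            entry_id = next_eid()
            if j == 0 and not label_error:
                sidecar.append(
                    GroundTruthRecord(pid, entry_id, surface, negated, misspelled, False)
                )
            entries.append(
                Entry(pid, entry_id, _render_entry(rng, body(), ins[j]),
                      "seen" if j == 0 else "unseen")
            )
        patients.append(PatientRecord(pid, "positive", tuple(entries)))

    for i in range(n_neg):
        pid = f"neg{i + 1:05d}"
        n_entries = 1 + int(extra_neg[i])
        ins = [[] for _ in range(n_entries)]
        for j in range(n_entries):
            ins[j] += circ_insertion(config.circumstantial_rate)
            if rng.random() < neg_negated_rate:
                ins[j].append(negated_mention())
        # non-convincing unnegated disease mentions a reviewer judged negative
        for _ in range(int(rng.poisson(confuser_lambda))):
            j = int(rng.integers(0, n_entries))
            ins[j].append((confuser_token(), None))
        entries = [
            Entry(pid, next_eid(), _render_entry(rng, body(), ins[j]),
                  "seen" if j == 0 else "implicit")
            for j in range(n_entries)
        ]
        patients.append(PatientRecord(pid, "negative", tuple(entries)))
        sidecar.append(GroundTruthRecord(pid, None, None, False, False, False))

    return Corpus(patients=patients, name=config.name), sidecar


#: Patient and entry totals of the two study data sets this generator can
#: mimic: (n_positive, n_negative, total_unseen, total_implicit).
PRESET_SHAPES = {
    "hepatobiliary": (656, 317, 61_179, 27_276),
    "renal": (237, 3_751, 58_022, 319_204),
}


def shape_preset(name: str, scale: float = 1.0, seed: int = 0, **overrides) -> SyntheticConfig:
    """Config whose patient counts and entry totals match a study data set.

    ``scale`` shrinks patients and entry totals proportionally (minimum one
    patient per class), preserving the class mix and per-patient entry
    load for quick experiments.  Extra keyword arguments override config
    fields (e.g. noise rates).
    """
    if name not in PRESET_SHAPES:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESET_SHAPES)}")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    n_pos, n_neg, total_unseen, total_implicit = PRESET_SHAPES[name]
    sc_pos = max(1, round(n_pos * scale))
    sc_neg = max(1, round(n_neg * scale))
    mean_entries = 1 + (total_unseen + total_implicit) / (n_pos + n_neg)
    defaults = dict(
        n_positive=sc_pos,
        n_negative=sc_neg,
        entries_per_patient=(mean_entries, 2.0),
        exact_total_unseen=round(total_unseen * scale),
        exact_total_implicit=round(total_implicit * scale),
        seed=seed,
        name=f"{name}-shaped" + (f"-x{scale:g}" if scale != 1 else ""),
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
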