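"""Keyword-driven assertion filter for clinical free text.

Medical notes mix positive statements with negations ("geen hepatitis"),
speculations ("mogelijk cirrose", or a sentence ending in '?'), and
differential alternatives ("cholecystitis of cholelithiasis").  Left in
place, such mentions teach a bag-of-words classifier that disease terms
occur in non-cases.  The filter removes them before featurization:

1. split the text into sentences on terminator punctuation;
2. drop every sentence containing an *alternatives* keyword;
3. drop every sentence terminated by ``?`` (treated as speculation);
4. in the remaining sentences, remove all words after the first *negation*
   or *speculation* keyword (the keyword itself is retained);
5. rejoin and lowercase.

Keyword matching is on whole lowercase tokens, not substrings.  The shipped
default lexicons are Dutch (the language of the records this method was
developed for); the mechanism is language-agnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

DEFAULT_TERMINATORS = frozenset(".!?:;")

# Tokens for keyword *matching* inside a sentence: runs of non-space,
# stripped of leading/trailing punctuation so "geen," still matches "geen".
_WORD_RE = re.compile(r"\S+")
_STRIP_RE = re.compile(r"^\W+|\W+$", re.UNICODE)


class LexiconError(ValueError):
    """A keyword lexicon violates its invariants."""


def _check_keywords(name: str, words) -> frozenset[str]:
    out = frozenset(words)
    for w in out:
        if not w or w != w.lower() or any(ch.isspace() for ch in w):
            raise LexiconError(
                f"{name} keyword {w!r} must be a single non-empty lowercase token"
            )
    return out


@dataclass(frozen=True)
class KeywordLexicon:
    """Negation / speculation / alternatives keywords plus sentence terminators.

    The three keyword sets must be pairwise disjoint and contain only
    single lowercase tokens.
    """

    negation_keywords: frozenset[str]
    speculation_keywords: frozenset[str]
    alternatives_keywords: frozenset[str]
    sentence_terminators: frozenset[str] = field(default=DEFAULT_TERMINATORS)

    def __post_init__(self) -> None:
        neg = _check_keywords("negation", self.negation_keywords)
        spec = _check_keywords("speculation", self.speculation_keywords)
        alt = _check_keywords("alternatives", self.alternatives_keywords)
        object.__setattr__(self, "negation_keywords", neg)
        object.__setattr__(self, "speculation_keywords", spec)
        object.__setattr__(self, "alternatives_keywords", alt)
        object.__setattr__(
            self, "sentence_terminators", frozenset(self.sentence_terminators)
        )
        if (neg & spec) or (neg & alt) or (spec & alt):
            raise LexiconError("keyword sets must be pairwise disjoint")
        for t in self.sentence_terminators:
            if len(t) != 1:
                raise LexiconError(f"terminator {t!r} must be a single character")

    @property
    def truncation_keywords(self) -> frozenset[str]:
        """Keywords that truncate a sentence: negation plus speculation."""
        return self.negation_keywords | self.speculation_keywords


def load_keyword_file(path) -> frozenset[str]:
    """Read one keyword per line; '#' starts a comment, blanks ignored."""
    words = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            words.append(line.lower())
    return frozenset(words)


def load_lexicon(
    negation_path, speculation_path, alternatives_path,
    terminators: frozenset[str] = DEFAULT_TERMINATORS,
) -> KeywordLexicon:
    """Build a lexicon from three plain-text keyword files."""
    return KeywordLexicon(
        negation_keywords=load_keyword_file(negation_path),
        speculation_keywords=load_keyword_file(speculation_path),
        alternatives_keywords=load_keyword_file(alternatives_path),
        sentence_terminators=terminators,
    )


def default_lexicon(language: str = "nl") -> KeywordLexicon:
    """The packaged lexicon: ``"nl"`` (default, Dutch) or ``"en"``."""
    base = resources.files("emrcase") / "lexicons"
    suffix = "" if language == "nl" else f"_{language}"
    paths = [base / f"{kind}{suffix}.txt" for kind in ("negation", "speculation", "alternatives")]
    for p in paths:
        if not p.is_file():
            raise LexiconError(f"no packaged lexicon for language {language!r}")
    return load_lexicon(*paths)


def split_sentences(
    text: str, terminators: frozenset[str] = DEFAULT_TERMINATORS
) -> list[tuple[str, str | None]]:
    """Split text into (sentence, terminator) pairs.

    Concatenating each sentence with its terminator reproduces the input
    exactly; no sentence contains a terminator character.  The final
    fragment has terminator ``None`` unless the text ends on a terminator.
    """
    sentences: list[tuple[str, str | None]] = []
    current: list[str] = []
    for ch in text:
        if ch in terminators:
            sentences.append(("".join(current), ch))
            current = []
        else:
            current.append(ch)
    if current:
        sentences.append(("".join(current), None))
    return sentences


def _sentence_tokens(sentence: str) -> list[str]:
    return [_STRIP_RE.sub("", w) for w in _WORD_RE.findall(sentence)]


def apply_assertion_filter(text: str, lexicon: KeywordLexicon) -> str:
    """Remove negated, speculative, and alternative assertions; lowercase.

    Idempotent, and the output token multiset is always a sub-multiset of
    the lowercased input's.
    """
    lowered = text.lower()
    kept: list[str] = []
    for sentence, term in split_sentences(lowered, lexicon.sentence_terminators):
        tokens = _sentence_tokens(sentence)
        if any(t in lexicon.alternatives_keywords for t in tokens):
            continue
        if term == "?":
            continue
        truncate = lexicon.truncation_keywords
        cut_end: int | None = None
        for m, tok in zip(_WORD_RE.finditer(sentence), tokens):
            if tok in truncate:
                cut_end = m.end()
                break
        if cut_end is not None:
            sentence = sentence[:cut_end]
        kept.append(sentence + (term if term is not None else ""))
    return "".join(kept)
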