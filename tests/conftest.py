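import numpy as np
import pytest

from emrcase import (
    Corpus,
    Entry,
    KeywordLexicon,
    PatientRecord,
    default_lexicon,
)


@pytest.fixture(scope="session")
def nl_lexicon() -> KeywordLexicon:
    return default_lexicon("nl")


@pytest.fixture(scope="session")
def en_lexicon() -> KeywordLexicon:
    return default_lexicon("en")


def make_patient(pid: str, label: str, texts: list[str]) -> PatientRecord:
    """First text becomes the seen entry; the rest get the role the label implies."""
    other = "unseen" if label == "positive" else "implicit"
    entries = tuple(
        Entry(pid, f"{pid}-e{i}", t, "seen" if i == 0 else other)
        for i, t in enumerate(texts)
    )
    return PatientRecord(pid, label, entries)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """2 positives (1 seen + 2 unseen each), 1 negative (1 seen + 3 implicit)."""
    return Corpus(
        patients=[
            make_patient("p1", "positive", ["galstenen aanwezig", "controle", "nabespreking"]),
            make_patient("p2", "positive", ["hepatitis vastgesteld", "lab ok", "herhaling"]),
            make_patient("n1", "negative", ["verkoudheid", "knie klacht", "griep", "vaccinatie"]),
        ],
        name="tiny",
    )


def random_corpus(rng: np.random.Generator, n_patients: int = 10) -> Corpus:
    """Small random valid corpus with Dutch-ish unicode text."""
    words = ["pijn", "koorts", "echo", "géén", "laesie", "naïef", "bloedbeeld", "kuur"]
    patients = []
    for i in range(n_patients):
        label = "positive" if rng.random() < 0.4 else "negative"
        n_entries = int(rng.integers(1, 5))
        texts = [
            " ".join(rng.choice(words, size=rng.integers(1, 6)))
            for _ in range(n_entries)
        ]
        patients.append(make_patient(f"p{i:03d}", label, texts))
    return Corpus(patients=patients, name="random")
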