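"""Data model for labeled EMR patient records with role-tagged free-text entries.

A patient record bundles a binary gold label (case / non-case) with one or
more free-text entries, each entry tagged with a role:

``seen``
    the single entry examined during manual labeling — the evidence entry
    for a positive case, a randomly chosen entry for a negative case;
``implicit``
    any other entry of a *negative* patient (usable as an additional
    negative training example, because the whole record was reviewed);
``unseen``
    any other entry of a *positive* patient (evidence status unknown, never
    used for training but included at test time).

Corpora are stored as JSON lines, one patient per line, UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

ROLES = ("seen", "implicit", "unseen")
LABELS = ("positive", "negative")


class CorpusError(Exception):
    """Base class for corpus reading/validation failures."""


class CorpusParseError(CorpusError):
    """A line in a corpus file is not valid JSON or misses required keys."""


class CorpusValidationError(CorpusError):
    """A structurally valid record violates a corpus invariant."""


@dataclass(frozen=True)
class Entry:
    """One free-text record in a patient's chart (visit note or letter)."""

    patient_id: str
    entry_id: str
    text: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CorpusValidationError(
                f"entry {self.entry_id!r} of patient {self.patient_id!r}: "
                f"role must be one of {ROLES}, got {self.role!r}"
            )
        if not self.text.strip():
            raise CorpusValidationError(
                f"entry {self.entry_id!r} of patient {self.patient_id!r}: "
                "text is empty after whitespace trimming"
            )


@dataclass(frozen=True)
class PatientRecord:
    """A patient's gold label plus all of their role-tagged entries.

    Invariants: exactly one ``seen`` entry; every other entry is ``unseen``
    for a positive patient and ``implicit`` for a negative patient; all
    entries carry this record's ``patient_id``.
    """

    patient_id: str
    gold_label: str
    entries: tuple[Entry, ...]

    def __post_init__(self) -> None:
        pid = self.patient_id
        if self.gold_label not in LABELS:
            raise CorpusValidationError(
                f"patient {pid!r}: gold_label must be one of {LABELS}, "
                f"got {self.gold_label!r}"
            )
        object.__setattr__(self, "entries", tuple(self.entries))
        n_seen = sum(1 for e in self.entries if e.role == "seen")
        if n_seen != 1:
            raise CorpusValidationError(
                f"patient {pid!r}: expected exactly one seen entry, found {n_seen}"
            )
        expected_other = "unseen" if self.gold_label == "positive" else "implicit"
        for e in self.entries:
            if e.patient_id != pid:
                raise CorpusValidationError(
                    f"patient {pid!r}: entry {e.entry_id!r} carries patient_id "
                    f"{e.patient_id!r}"
                )
            if e.role != "seen" and e.role != expected_other:
                raise CorpusValidationError(
                    f"patient {pid!r} ({self.gold_label}): entry {e.entry_id!r} "
                    f"has role {e.role!r}, expected {expected_other!r}"
                )
        entry_ids = [e.entry_id for e in self.entries]
        if len(set(entry_ids)) != len(entry_ids):
            raise CorpusValidationError(f"patient {pid!r}: duplicate entry_id")

    @property
    def seen_entry(self) -> Entry:
        return next(e for e in self.entries if e.role == "seen")

    @property
    def is_positive(self) -> bool:
        return self.gold_label == "positive"


@dataclass
class Corpus:
    """A collection of patient records with unique patient ids."""

    patients: list[PatientRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate patient_id values: {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.patients == other.patients and self.name == other.name

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass(frozen=True)
class CorpusSummary:
    """Patient and entry tallies by label and role.

    ``n_seen_pos == n_positive`` and ``n_seen_neg == n_negative`` always hold
    (one seen entry per patient).
    """

    n_positive: int
    n_negative: int
    n_seen_pos: int
    n_seen_neg: int
    n_implicit: int
    n_unseen: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_seen_pos": self.n_seen_pos,
            "n_seen_neg": self.n_seen_neg,
            "n_implicit": self.n_implicit,
            "n_unseen": self.n_unseen,
        }


def summarize(corpus: Corpus) -> CorpusSummary:
    """Tally patients and entries by gold label and role."""
    n_pos = n_neg = n_seen_pos = n_seen_neg = n_implicit = n_unseen = 0
    for p in corpus:
        if p.is_positive:
            n_pos += 1
        else:
            n_neg += 1
        for e in p.entries:
            if e.role == "seen":
                if p.is_positive:
                    n_seen_pos += 1
                else:
                    n_seen_neg += 1
            elif e.role == "implicit":
                n_implicit += 1
            else:
                n_unseen += 1
    return CorpusSummary(n_pos, n_neg, n_seen_pos, n_seen_neg, n_implicit, n_unseen)


def _patient_from_obj(obj: dict, where: str) -> PatientRecord:
    try:
        pid = obj["patient_id"]
        label = obj["gold_label"]
        raw_entries = obj["entries"]
    except (KeyError, TypeError) as exc:
        raise CorpusParseError(f"{where}: missing key {exc}") from exc
    entries = []
    for raw in raw_entries:
        try:
            entries.append(
                Entry(
                    patient_id=pid,
                    entry_id=raw["entry_id"],
                    text=raw["text"],
                    role=raw["role"],
                )
            )
        except (KeyError, TypeError) as exc:
            raise CorpusParseError(f"{where}: malformed entry object ({exc})") from exc
    return PatientRecord(patient_id=pid, gold_label=label, entries=tuple(entries))


def read_corpus(path, name: str | None = None) -> Corpus:
    """Read a JSON-lines corpus file (one patient object per line, UTF-8).

    Raises :class:`CorpusParseError` naming the offending line number on
    malformed JSON, and :class:`CorpusValidationError` naming the patient on
    an invariant violation.
    """
    patients = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {lineno}: invalid JSON ({exc})") from exc
            patients.append(_patient_from_obj(obj, where=f"line {lineno}"))
    return Corpus(patients=patients, name=name if name is not None else str(path))


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus as JSON lines; ``read_corpus`` round-trips exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus:
            obj = {
                "patient_id": p.patient_id,
                "gold_label": p.gold_label,
                "entries": [
                    {"entry_id": e.entry_id, "role": e.role, "text": e.text}
                    for e in p.entries
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-patient generation truth written by the synthetic generator.

    ``evidence_token`` is the realized surface form planted in the evidence
    entry (the misspelled variant when ``evidence_misspelled`` is true);
    ``label_is_error`` marks patients whose gold label contradicts their
    generated content (an emulated annotator mistake).
    """

    patient_id: str
    evidence_entry_id: str | None
    evidence_token: str | None
    evidence_negated: bool
    evidence_misspelled: bool
    label_is_error: bool


def read_sidecar(path) -> dict[str, GroundTruthRecord]:
    """Read a JSON-lines ground-truth sidecar into a patient_id-keyed map."""
    records: dict[str, GroundTruthRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                rec = GroundTruthRecord(
                    patient_id=obj["patient_id"],
                    evidence_entry_id=obj["evidence_entry_id"],
                    evidence_token=obj["evidence_token"],
                    evidence_negated=obj["evidence_negated"],
                    evidence_misspelled=obj["evidence_misspelled"],
                    label_is_error=obj["label_is_error"],
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CorpusParseError(f"line {lineno}: bad sidecar record ({exc})") from exc
            records[rec.patient_id] = rec
    return records


def write_sidecar(records: Iterable[GroundTruthRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "patient_id": r.patient_id,
                "evidence_entry_id": r.evidence_entry_id,
                "evidence_token": r.evidence_token,
                "evidence_negated": r.evidence_negated,
                "evidence_misspelled": r.evidence_misspelled,
                "label_is_error": r.label_is_error,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def concat(corpora: Iterable[Corpus], name: str = "") -> Corpus:
    """Concatenate corpora with disjoint patient ids into one corpus."""
    patients: list[PatientRecord] = []
    for c in corpora:
        patients.extend(c.patients)
    return Corpus(patients=patients, name=name)
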