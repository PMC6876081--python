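"""Q&A corpus data model, JSON-lines I/O, and record filtering/labeling.

A corpus holds question-answer pairs from an online health-care community
(OHC): a patient posts a question, several doctors answer, and the patient
may adopt one answer or inquire after it again.  An answer is *accepted*
(label 1) when the patient adopted it or followed it up; the remaining
answers under a responded question are negatives (label 0).  Questions the
patient never responded to carry no acceptance information and are dropped.

Records also carry the tabular attributes used by the downstream numeric
encoder: patient age/gender, doctor title/reputation/patients-helped/
gratitude-count, answer length in characters, question-to-answer delay,
and answer order.
"""

from __future__ import annotations

import dataclasses
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator

__all__ = [
    "QARecord",
    "Corpus",
    "TABULAR_FIELDS",
    "read_corpus",
    "write_corpus",
    "filter_and_label",
]

#: The nine tabular features; a record missing any of them is excluded
#: by :func:`filter_and_label`.
TABULAR_FIELDS = (
    "patient_age",
    "patient_gender",
    "doctor_title",
    "doctor_reputation",
    "patients_helped",
    "gratitude_count",
    "answer_char_count",
    "time_diff_seconds",
    "answer_order",
)

#: Raw patient-behaviour values that make an answer the positive class.
POSITIVE_RESPONSES = frozenset({"adopted", "inquired_after"})

GENDER_LEVELS = ("male", "female")
TITLE_LEVELS = ("chief", "attending", "assistant")
REPUTATION_LEVELS = ("level1", "level2", "level3")


@dataclass
class QARecord:
    """One question-answer pair with label and tabular attributes.

    ``label`` may be missing (``None``) before filtering.  The raw patient
    behaviour, when known, is kept in ``patient_response`` with values
    ``adopted`` / ``inquired_after`` / ``none``; :func:`filter_and_label`
    maps it to the binary label.
    """

    question_id: str = ""
    answer_id: str = ""
    question_text: str = ""
    answer_text: str = ""
    label: int | None = None
    patient_response: str | None = None
    patient_age: int | None = None
    patient_gender: str | None = None
    doctor_title: str | None = None
    doctor_reputation: str | None = None
    patients_helped: int | None = None
    gratitude_count: int | None = None
    answer_char_count: int | None = None
    time_diff_seconds: float | None = None
    answer_order: int | None = None
    disease: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def has_complete_tabular(self) -> bool:
        """True when all nine tabular features are present."""
        return all(getattr(self, f) is not None for f in TABULAR_FIELDS)

    def to_dict(self) -> dict[str, Any]:
        d = OrderedDict()
        for f in dataclasses.fields(self):
            if f.name == "extras":
                continue
            v = getattr(self, f.name)
            if v is not None:
                d[f.name] = v
        d.update(self.extras)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "QARecord":
        known = {f.name for f in dataclasses.fields(cls)} - {"extras"}
        kwargs = {k: v for k, v in d.items() if k in known}
        extras = {k: v for k, v in d.items() if k not in known}
        return cls(extras=extras, **kwargs)


@dataclass
class Corpus:
    """An ordered collection of :class:`QARecord` plus free-text provenance."""

    records: list[QARecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[QARecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def by_question(self) -> "OrderedDict[str, list[QARecord]]":
        """Group records by question_id, preserving first-seen order."""
        groups: OrderedDict[str, list[QARecord]] = OrderedDict()
        for r in self.records:
            groups.setdefault(r.question_id, []).append(r)
        return groups

    def labels(self) -> list[int | None]:
        return [r.label for r in self.records]


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files; message names the line number."""


def read_corpus(path: str | Path) -> Corpus:
    """Read a UTF-8 JSON-lines corpus, one record per line.

    Unknown keys are preserved in ``QARecord.extras``.  Raises
    :class:`CorpusFormatError` naming the offending line for malformed JSON
    or a missing mandatory key (``question_text`` / ``answer_text``).
    """
    path = Path(path)
    records: list[QARecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}: malformed JSON on line {lineno}: {exc.msg}"
                ) from exc
            for key in ("question_text", "answer_text"):
                if key not in obj:
                    raise CorpusFormatError(
                        f"{path}: line {lineno} is missing mandatory key {key!r}"
                    )
            rec = QARecord.from_dict(obj)
            rec.extras.setdefault("_line", lineno)
            records.append(rec)
    return Corpus(records=records, provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as UTF-8 JSON-lines; round-trips losslessly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus.records:
            d = rec.to_dict()
            d.pop("_line", None)
            fh.write(json.dumps(d, ensure_ascii=False) + "\n")


def _effective_label(rec: QARecord) -> int | None:
    """Binary label from raw behaviour, falling back to an explicit label."""
    if rec.patient_response is not None:
        return 1 if rec.patient_response in POSITIVE_RESPONSES else 0
    return rec.label


def _question_responded(answers: Iterable[QARecord]) -> bool:
    # Acceptance is observable only when the patient reacted to some answer;
    # an explicit 0/1 label on any sibling also certifies observability.
    for a in answers:
        if a.patient_response in POSITIVE_RESPONSES:
            return True
        if a.label is not None:
            return True
    return False


def filter_and_label(
    corpus: Corpus,
    disease: str | None = None,
) -> Corpus:
    """Apply the corpus filtering and labeling rules.

    Keeps only records where (a) the question received some patient
    response, so the acceptance label is determinable, and (b) none of the
    nine tabular features is missing.  Surviving records get label 1 when
    the patient adopted or inquired after the answer, 0 otherwise.
    Questions whose answers are all negative are retained (all-negative
    groups still carry ranking information).  Idempotent.

    ``disease`` optionally restricts the output to records whose
    ``disease`` tag equals the given value.
    """
    groups = corpus.by_question()
    out: list[QARecord] = []
    for qid, answers in groups.items():
        if not _question_responded(answers):
            continue
        for a in answers:
            if disease is not None and a.disease != disease:
                continue
            if not a.has_complete_tabular():
                continue
            lab = _effective_label(a)
            if lab is None:
                # sibling of a responded answer with no recorded behaviour:
                # the patient passed over it, so it is a negative
                lab = 0
            rec = dataclasses.replace(a, label=int(lab))
            rec.extras = dict(a.extras)
            out.append(rec)
    return Corpus(records=out, provenance=corpus.provenance)
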