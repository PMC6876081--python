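import numpy as np
import pytest

from ohc_accept.corpus import Corpus, QARecord


def make_record(qid="q1", aid=None, order=1, label=None, response=None, **over):
    """A fully-populated record; override any field via kwargs."""
    fields = dict(
        question_id=qid,
        answer_id=aid or f"{qid}a{order}",
        question_text="mouth ulcer hurts badly",
        answer_text="rinse with salt water",
        label=label,
        patient_response=response,
        patient_age=34,
        patient_gender="female",
        doctor_title="attending",
        doctor_reputation="level2",
        patients_helped=120,
        gratitude_count=8,
        answer_char_count=40,
        time_diff_seconds=360.0,
        answer_order=order,
    )
    fields.update(over)
    return QARecord(**fields)


@pytest.fixture
def small_corpus():
    """Three questions: one adopted answer, one all-negative, one unanswered."""
    records = [
        make_record("q1", order=1, response="adopted"),
        make_record("q1", order=2, response="none"),
        make_record("q1", order=3, response="none"),
        make_record("q2", order=1, label=0),
        make_record("q2", order=2, label=0),
        make_record("q3", order=1),  # never responded
    ]
    return Corpus(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
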