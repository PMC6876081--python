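"""Seeded generator of OHC-like Q&A corpora with plantable signals.

The real corpora this package targets are private, so every stage is
exercised on synthetic data that emulates their structure: ~2.36 answers
per question, ~60% positive labels, long-tailed doctor statistics inside
the documented attribute ranges, and question/answer lengths matching
the reported character means at ~1.7 characters per word (token means
43 / 55).

The generative model plants both signals the method is meant to pick up:

* textual — each question draws a topic and a bag of topic words; each
  answer mixes the question's topic distribution (weight = relevance r)
  with a background distribution.  The overlap o (fraction of answer
  tokens also present in the question) is the planted textual mechanism,
  chosen because the co-attention encoder can learn it by construction.
* numerical — a linear predictor over standardised doctor/answer
  covariates x_num.

Labels are Bernoulli(logistic(eta)) with
eta = alpha + beta_text * o + beta_num . x_num + Normal(0, noise_sd);
alpha is calibrated by bisection so the expected positive rate hits the
target.  The latent truth (topic, r, o, x_num, eta, p) is returned as a
DataFrame for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, QARecord, TABULAR_FIELDS

__all__ = ["GeneratorConfig", "generate", "summarize"]

_COVARIATE_NAMES = ("z_patients_helped", "z_gratitude", "z_time_diff", "z_answer_order")

# standardisation constants for the numeric covariates, matching the
# generating distributions below (log1p of log-normals is ~normal)
_COV_MU = np.array([6.2, 3.9, 5.7, 2.36])
_COV_SD = np.array([1.5, 1.5, 1.0, 1.4])


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults emulate a real OHC corpus."""

    n_questions: int = 1000
    answers_per_question_mean: float = 2.36
    vocab_size: int = 600
    topic_count: int = 20
    tokens_per_topic: int = 30
    q_len_mean: float = 43.0
    a_len_mean: float = 55.0
    positive_rate_target: float = 0.60
    beta_text: float = 5.0
    beta_num: Sequence[float] = (0.8, 0.4, -0.5, -0.8)
    noise_sd: float = 0.5
    relevance_low: float = 0.05
    relevance_high: float = 0.95
    chars_per_token: float = 1.7
    disease_tags: Sequence[str] = ("hypertension", "oral_ulcer")
    disease_ratio: float = 0.9
    missing_rate: float = 0.0      # corruption: null a random tabular field
    no_response_rate: float = 0.0  # corruption: question with no patient response
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_questions <= 0 or self.answers_per_question_mean <= 1.0:
            raise ValueError("need n_questions > 0 and answers/question mean > 1")
        if not (0.0 < self.positive_rate_target < 1.0):
            raise ValueError("positive_rate_target must be in (0, 1)")
        if self.beta_text < 0 or self.noise_sd < 0:
            raise ValueError("beta_text and noise_sd must be nonnegative")
        if self.topic_count * self.tokens_per_topic > self.vocab_size:
            raise ValueError("vocab too small for topic_count * tokens_per_topic")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_num"] = list(self.beta_num)
        d["disease_tags"] = list(self.disease_tags)
        return d


def _geometric_len(rng: np.random.Generator, mean: float, minimum: int = 3) -> int:
    # minimum + geometric tail reproducing the target mean
    tail = max(mean - minimum + 1.0, 1.0)
    return minimum - 1 + int(rng.geometric(1.0 / tail))


def _topic_distributions(cfg: GeneratorConfig) -> np.ndarray:
    """Zipf-weighted distribution over each topic's disjoint token block."""
    probs = np.zeros((cfg.topic_count, cfg.vocab_size))
    ranks = 1.0 / np.arange(1, cfg.tokens_per_topic + 1)
    ranks /= ranks.sum()
    for t in range(cfg.topic_count):
        lo = t * cfg.tokens_per_topic
        probs[t, lo : lo + cfg.tokens_per_topic] = ranks
    return probs


def _calibrate_alpha(eta0: np.ndarray, target: float, max_iter: int = 200) -> float:
    """Bisection on alpha so that mean(logistic(alpha + eta0)) = target."""
    lo, hi = -30.0, 30.0

    def rate(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta0)))))

    if not (rate(lo) <= target <= rate(hi)):
        raise ValueError("positive_rate_target unattainable under this signal config")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(config: GeneratorConfig) -> tuple[Corpus, pd.DataFrame]:
    """Generate a corpus and its latent truth table, fully seeded."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    topic_probs = _topic_distributions(cfg)
    vocab_words = np.array([f"w{i:04d}" for i in range(cfg.vocab_size)])
    n_doctors = max(2, round(0.22 * cfg.n_questions))

    doctors = []
    titles = ("chief", "attending", "assistant")
    reps = ("level1", "level2", "level3")
    for d in range(n_doctors):
        doctors.append({
            "doctor_id": f"d{d:05d}",
            "doctor_title": titles[rng.choice(3, p=[0.25, 0.45, 0.30])],
            "doctor_reputation": reps[rng.choice(3, p=[0.35, 0.40, 0.25])],
            "patients_helped": int(np.clip(np.exp(rng.normal(6.2, 1.5)), 0, 406342)),
            "gratitude_count": int(np.clip(np.exp(rng.normal(3.9, 1.5)), 0, 13883)),
        })

    records: list[QARecord] = []
    rows: list[dict] = []
    for q in range(cfg.n_questions):
        qid = f"q{q:06d}"
        topic = int(rng.integers(cfg.topic_count))
        q_len = _geometric_len(rng, cfg.q_len_mean)
        q_token_ids = rng.choice(cfg.vocab_size, size=q_len, p=topic_probs[topic])
        q_tokens = vocab_words[q_token_ids]
        q_set = set(q_token_ids.tolist())
        question_text = " ".join(q_tokens)
        age = int(np.clip(round(rng.normal(45, 20)), 0, 98))
        gender = "male" if rng.random() < 0.5 else "female"
        disease = cfg.disease_tags[0] if rng.random() < cfg.disease_ratio else cfg.disease_tags[-1]
        k = 1 + int(rng.poisson(cfg.answers_per_question_mean - 1.0))
        for order in range(1, k + 1):
            doc = doctors[int(rng.integers(n_doctors))]
            a_len = _geometric_len(rng, cfg.a_len_mean)
            relevance = float(rng.uniform(cfg.relevance_low, cfg.relevance_high))
            from_topic = rng.random(a_len) < relevance
            a_token_ids = np.where(
                from_topic,
                rng.choice(cfg.vocab_size, size=a_len, p=topic_probs[topic]),
                rng.integers(cfg.vocab_size, size=a_len),
            )
            overlap = float(np.mean([t in q_set for t in a_token_ids]))
            answer_text = " ".join(vocab_words[a_token_ids])
            time_diff = float(np.clip(np.exp(rng.normal(5.7, 1.0)), 0.0, 8005.37))
            char_count = int(np.clip(round(a_len * cfg.chars_per_token), 12, 734))
            raw = np.array([
                np.log1p(doc["patients_helped"]),
                np.log1p(doc["gratitude_count"]),
                np.log1p(time_diff),
                float(order),
            ])
            x_num = (raw - _COV_MU) / _COV_SD
            eta0 = (
                cfg.beta_text * overlap
                + float(np.dot(np.asarray(cfg.beta_num), x_num))
                + rng.normal(0.0, cfg.noise_sd)
            )
            rec = QARecord(
                question_id=qid,
                answer_id=f"{qid}a{order}",
                question_text=question_text,
                answer_text=answer_text,
                patient_age=age,
                patient_gender=gender,
                doctor_title=doc["doctor_title"],
                doctor_reputation=doc["doctor_reputation"],
                patients_helped=doc["patients_helped"],
                gratitude_count=doc["gratitude_count"],
                answer_char_count=char_count,
                time_diff_seconds=time_diff,
                answer_order=order,
                disease=disease,
                extras={"patient_id": f"p{q:06d}", "doctor_id": doc["doctor_id"]},
            )
            records.append(rec)
            rows.append({
                "question_id": qid, "answer_id": rec.answer_id,
                "topic": topic, "relevance": relevance, "overlap": overlap,
                **dict(zip(_COVARIATE_NAMES, x_num)),
                "eta0": eta0,
            })

    truth = pd.DataFrame(rows)
    alpha = _calibrate_alpha(truth["eta0"].to_numpy(), cfg.positive_rate_target)
    truth["eta"] = alpha + truth["eta0"]
    truth["p"] = 1.0 / (1.0 + np.exp(-truth["eta"]))
    labels = (rng.random(len(truth)) < truth["p"].to_numpy()).astype(int)
    truth["label"] = labels
    truth.drop(columns=["eta0"], inplace=True)
    for rec, lab in zip(records, labels):
        rec.label = int(lab)
        rec.patient_response = (
            ("adopted" if rng.random() < 0.7 else "inquired_after") if lab else "none"
        )

    if cfg.no_response_rate > 0 or cfg.missing_rate > 0:
        _corrupt(records, cfg, rng)

    corpus = Corpus(records=records, provenance=f"synthetic(seed={cfg.seed})")
    return corpus, truth


def _corrupt(records: list[QARecord], cfg: GeneratorConfig, rng: np.random.Generator) -> None:
    """Inject no-response questions and missing tabular values."""
    by_q: dict[str, list[QARecord]] = {}
    for r in records:
        by_q.setdefault(r.question_id, []).append(r)
    for qid, answers in by_q.items():
        if rng.random() < cfg.no_response_rate:
            for a in answers:
                a.label = None
                a.patient_response = None
    for r in records:
        if rng.random() < cfg.missing_rate:
            fld = TABULAR_FIELDS[int(rng.integers(len(TABULAR_FIELDS)))]
            setattr(r, fld, None)


def summarize(corpus: Corpus) -> dict:
    """Corpus summary panel: sizes, lengths, positive rate, participants."""
    if len(corpus) == 0:
        raise ValueError("cannot summarise an empty corpus")
    groups = corpus.by_question()
    q_lens = [len(ans[0].question_text.split()) for ans in groups.values()]
    a_lens = [len(r.answer_text.split()) for r in corpus]
    labeled = [r.label for r in corpus if r.label is not None]
    patients = {r.extras.get("patient_id") for r in corpus} - {None}
    doctors = {r.extras.get("doctor_id") for r in corpus} - {None}
    return {
        "n_records": len(corpus),
        "n_questions": len(groups),
        "answers_per_question": len(corpus) / len(groups),
        "mean_question_tokens": float(np.mean(q_lens)),
        "mean_answer_tokens": float(np.mean(a_lens)),
        "positive_rate": float(np.mean(labeled)) if labeled else float("nan"),
        "n_labeled": len(labeled),
        "n_patients": len(patients),
        "n_doctors": len(doctors),
    }
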