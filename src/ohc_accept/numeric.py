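"""Tabular attributes -> the numerical feature vector h_num.

Categorical attributes (patient gender, doctor title, doctor reputation)
become one-hot blocks whose levels are collected at fit time.  Continuous
attributes are right-skewed counts and delays, so they are mapped through
log(x + offset); patient age is left raw by default (it is not generally
right-skewed) but can be log-transformed too.  No further standardisation
is applied: the downstream classifier is a boosted tree ensemble, which
is invariant to monotone rescaling.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import (
    Corpus,
    GENDER_LEVELS,
    QARecord,
    REPUTATION_LEVELS,
    TITLE_LEVELS,
)

__all__ = ["NumericEncoder", "fit_numeric_encoder", "encode_numeric", "export_feature_csv"]

logger = logging.getLogger(__name__)

#: canonical level order for the known categorical fields, so one-hot
#: block layout is stable across corpora that contain all levels
_CANONICAL_LEVELS = {
    "patient_gender": GENDER_LEVELS,
    "doctor_title": TITLE_LEVELS,
    "doctor_reputation": REPUTATION_LEVELS,
}

_DEFAULT_CATEGORICAL = ("patient_gender", "doctor_title", "doctor_reputation")
_DEFAULT_CONTINUOUS = (
    ("patient_age", "identity"),
    ("patients_helped", "log"),
    ("gratitude_count", "log"),
    ("answer_char_count", "log"),
    ("time_diff_seconds", "log"),
    ("answer_order", "log"),
)


class NumericEncoder(BaseEstimator, TransformerMixin):
    """One-hot + log encoder for the tabular Q&A attributes.

    Parameters
    ----------
    categorical_fields : sequence of str
        Fields encoded as one-hot blocks; levels are collected from the
        data at fit time (in canonical order where known).
    continuous_fields : sequence of (field, transform)
        transform is "log" for log(x + log_offset) or "identity".
    log_offset : float
        Offset inside the log; the default 1.0 keeps zero-valued delays
        and counts finite (log(0 + 1) = 0).

    Attributes
    ----------
    levels_ : dict mapping categorical field -> tuple of levels seen
    feature_names_ : list of output column names
    """

    def __init__(
        self,
        categorical_fields: Sequence[str] = _DEFAULT_CATEGORICAL,
        continuous_fields: Sequence[tuple[str, str]] = _DEFAULT_CONTINUOUS,
        log_offset: float = 1.0,
    ):
        self.categorical_fields = categorical_fields
        self.continuous_fields = continuous_fields
        self.log_offset = log_offset

    def fit(self, X: Corpus | Sequence[QARecord], y=None) -> "NumericEncoder":
        records = list(X)
        if not records:
            raise ValueError("cannot fit a numeric encoder on an empty corpus")
        self.levels_: dict[str, tuple[str, ...]] = {}
        for fld in self.categorical_fields:
            seen = {getattr(r, fld) for r in records} - {None}
            canonical = _CANONICAL_LEVELS.get(fld)
            if canonical is not None:
                levels = tuple(lv for lv in canonical if lv in seen)
                levels += tuple(sorted(seen - set(canonical)))
                if len(levels) < len(canonical):
                    logger.warning(
                        "field %s: only %d of %d known levels present in data",
                        fld, len(levels), len(canonical),
                    )
            else:
                levels = tuple(sorted(seen))
            self.levels_[fld] = levels
        self.feature_names_ = []
        for fld in self.categorical_fields:
            for lv in self.levels_[fld]:
                self.feature_names_.append(f"{fld}={lv}")
        for fld, transform in self.continuous_fields:
            suffix = "_log" if transform == "log" else ""
            self.feature_names_.append(f"{fld}{suffix}")
        self.n_features_out_ = len(self.feature_names_)
        return self

    def encode_record(self, record: QARecord) -> np.ndarray:
        """Encode one record into its fixed-length numeric vector."""
        check_is_fitted(self, "levels_")
        parts: list[float] = []
        for fld in self.categorical_fields:
            levels = self.levels_[fld]
            block = [0.0] * len(levels)
            val = getattr(record, fld)
            if val in levels:
                block[levels.index(val)] = 1.0
            elif val is not None:
                logger.warning("field %s: unseen level %r -> zero block", fld, val)
            parts.extend(block)
        for fld, transform in self.continuous_fields:
            x = getattr(record, fld)
            x = float(x) if x is not None else 0.0
            if x < 0:
                raise ValueError(f"field {fld}: negative value {x} is out of domain")
            parts.append(math.log(x + self.log_offset) if transform == "log" else x)
        return np.asarray(parts, dtype=np.float64)

    def transform(self, X: Corpus | Sequence[QARecord]) -> np.ndarray:
        check_is_fitted(self, "levels_")
        rows = [self.encode_record(r) for r in X]
        if not rows:
            return np.empty((0, self.n_features_out_))
        return np.vstack(rows)

    def decode_categorical(self, vector: np.ndarray, fld: str) -> str | None:
        """Recover the level of ``fld`` from an encoded vector (known levels)."""
        check_is_fitted(self, "levels_")
        start = 0
        for f in self.categorical_fields:
            width = len(self.levels_[f])
            if f == fld:
                block = vector[start : start + width]
                if block.sum() == 0:
                    return None
                return self.levels_[f][int(np.argmax(block))]
            start += width
        raise KeyError(fld)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


def fit_numeric_encoder(corpus: Corpus, **kwargs) -> NumericEncoder:
    """Functional wrapper: fit a :class:`NumericEncoder` on a filtered corpus."""
    return NumericEncoder(**kwargs).fit(corpus)


def encode_numeric(record: QARecord, encoder: NumericEncoder) -> np.ndarray:
    """Functional wrapper over :meth:`NumericEncoder.encode_record`."""
    return encoder.encode_record(record)


def export_feature_csv(
    matrix: np.ndarray, encoder: NumericEncoder, path, labels=None
) -> None:
    """Write the feature matrix as CSV with a header naming each slot."""
    df = pd.DataFrame(matrix, columns=encoder.feature_names_)
    if labels is not None:
        df.insert(0, "label", labels)
    df.to_csv(path, index=False)
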