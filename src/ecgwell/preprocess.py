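"""Segmentation, resampling, feature normalization and label construction.

Raw records are cut into overlapping fixed-duration windows (default 5 s
windows sliding by 1 s, so a 20 s record yields 16 windows), each window is
polyphase-resampled to a fixed model input length (default 500 points), and
per-subject health-index (HI) series are converted to binary wellness labels
through rank-based (Fisher-Yates / normal-scores) normalization.

The label rule: a subject's HI observations are mid-ranked within the
subject's own series, mapped through the inverse standard-normal CDF of
G/(I+1), and binarized at 0 — strictly positive scores are "Better"
(label 0), everything else "Worse" (label 1).  The G/(I+1) plug-in (rather
than G/I) keeps the top rank finite while preserving sign and ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import gcd
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm, rankdata

from .errors import DimensionError, InvalidArgumentError, ValidationError
from .synthetic_ecg import BETTER, WORSE, ECGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "SegmentDataset",
    "NormalizationModel",
    "segment_signal",
    "resample_window",
    "fit_minmax",
    "apply_minmax",
    "fisher_yates_labels",
    "build_segment_dataset",
]


class Window(NamedTuple):
    start_s: float
    values: np.ndarray


def segment_signal(
    record: ECGRecord, window_s: float = 5.0, step_s: float = 1.0
) -> list[Window]:
    """Slide a ``window_s`` window by ``step_s`` over the record.

    Returns ``floor((duration - window_s) / step_s) + 1`` windows; window k
    covers ``[k*step_s, k*step_s + window_s)``.  A record shorter than the
    window yields an empty list with a logged warning rather than an error.
    """
    if window_s <= 0 or step_s <= 0:
        raise InvalidArgumentError("window_s and step_s must be positive")
    n = len(record.samples)
    win_n = int(round(window_s * record.fs))
    step_n = int(round(step_s * record.fs))
    if n < win_n:
        logger.warning(
            "record %s day %d shorter (%.2f s) than window (%.2f s); no segments",
            record.subject_id,
            record.day_index,
            record.duration_s,
            window_s,
        )
        return []
    n_windows = (n - win_n) // step_n + 1
    return [
        Window(start_s=k * step_n / record.fs, values=record.samples[k * step_n : k * step_n + win_n])
        for k in range(n_windows)
    ]


def resample_window(window: np.ndarray, target_len: int = 500) -> np.ndarray:
    """Anti-aliased polyphase resampling of one window to ``target_len`` points.

    The identity case (``target_len == len(window)``) bypasses filtering.
    Upsampling beyond the source length is refused: segments are reductions
    of the raw window, never fabrications.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise InvalidArgumentError("window must be non-empty")
    if target_len > len(window):
        raise InvalidArgumentError(
            f"target_len {target_len} exceeds window length {len(window)}"
        )
    if target_len == len(window):
        return window.copy()
    g = gcd(target_len, len(window))
    up, down = target_len // g, len(window) // g
    out = sps.resample_poly(window, up, down, padtype="line")
    return out[:target_len]


@dataclass
class NormalizationModel:
    """Per-feature training minima/maxima for min-max scaling to [0, 1]."""

    min_: np.ndarray
    max_: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.min_)


def fit_minmax(feature_matrix: np.ndarray) -> NormalizationModel:
    x = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if x.shape[0] < 1:
        raise InvalidArgumentError("need at least one row to fit")
    return NormalizationModel(min_=x.min(axis=0), max_=x.max(axis=0))


def apply_minmax(model: NormalizationModel, feature_matrix: np.ndarray) -> np.ndarray:
    """Scale columns by the fitted training range: (x - min) / (max - min).

    On training data the output lies in [0, 1] per feature; test data may
    exceed that range.  A constant training feature (max == min) maps to 0.
    """
    x = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if x.shape[1] != model.n_features:
        raise DimensionError(
            f"model has {model.n_features} features, matrix has {x.shape[1]}"
        )
    span = model.max_ - model.min_
    degenerate = span == 0
    safe_span = np.where(degenerate, 1.0, span)
    out = (x - model.min_) / safe_span
    out[:, degenerate] = 0.0
    return out


def fisher_yates_labels(
    hi_by_day: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-scores transform of one subject's HI series, then binarize.

    Mid-ranks G over the subject's I observations are mapped through
    phi^{-1}(G / (I + 1)); scores > 0 are "Better" (label 0), the rest
    "Worse" (label 1).  Ties share mid-ranks, so an all-identical series
    maps to 0 and hence entirely to label 1.
    """
    hi = np.asarray(hi_by_day)
    if hi.ndim != 1 or len(hi) < 1:
        raise ValidationError("HI series must be a non-empty 1-D sequence")
    if not np.all(np.isin(hi, [1, 2, 3, 4, 5])):
        raise ValidationError("HI values must lie in {1,...,5}")
    n_days = len(hi)
    ranks = rankdata(hi, method="average")
    normalized = norm.ppf(ranks / (n_days + 1))
    labels = np.where(normalized > 0, 0, 1)
    return normalized, labels


@dataclass
class SegmentDataset:
    """Fixed-length segments with binary labels and provenance.

    ``X`` is (n, target_len); ``labels`` holds 0 = Better, 1 = Worse; the
    provenance frame records subject, day, window start and the generating
    wellness regime when known.
    """

    X: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.labels) or len(self.X) != len(self.provenance):
            raise DimensionError("X, labels and provenance must have equal length")
        if len(self.labels) and not np.all(np.isin(self.labels, [0, 1])):
            raise ValidationError("labels must be binary")

    def to_csv(self, path) -> None:
        cols = [f"x{i}" for i in range(self.X.shape[1])]
        df = pd.DataFrame(self.X, columns=cols)
        df = pd.concat([self.provenance.reset_index(drop=True), df], axis=1)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SegmentDataset":
        df = pd.read_csv(path)
        value_cols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
        prov_cols = [c for c in df.columns if c not in value_cols and c != "label"]
        return cls(
            X=df[value_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            provenance=df[prov_cols],
        )


def build_segment_dataset(
    records: Iterable[ECGRecord],
    window_s: float = 5.0,
    step_s: float = 1.0,
    target_len: int = 500,
    lag_days: int = 1,
    label_source: str = "hi",
) -> SegmentDataset:
    """Segment a cohort and attach one-day-forward wellness labels.

    With ``label_source="hi"`` (the default), the label of a day-t segment is
    derived from the subject's day t+lag HI via Fisher-Yates binarization;
    records whose lagged day has no HI observation are dropped.  With
    ``label_source="class"`` the generating regime of the record itself is
    used (0 = better, 1 = worse) — available only for synthetic records, and
    useful to study the feature extractors in isolation from label noise.
    """
    if label_source not in ("hi", "class"):
        raise InvalidArgumentError("label_source must be 'hi' or 'class'")
    if lag_days < 0:
        raise InvalidArgumentError("lag_days must be >= 0")
    records = list(records)
    by_subject: dict[str, dict[int, ECGRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, {})[rec.day_index] = rec

    rows, labels, prov = [], [], []
    for subject_id, days in by_subject.items():
        day_indices = sorted(days)
        hi_series = [days[d].hi for d in day_indices]
        _, day_labels = fisher_yates_labels(hi_series)
        label_by_day = dict(zip(day_indices, day_labels))
        for d in day_indices:
            rec = days[d]
            if label_source == "hi":
                if d + lag_days not in label_by_day:
                    continue
                label = int(label_by_day[d + lag_days])
            else:
                wc = rec.meta.get("wellness_class")
                if wc not in (BETTER, WORSE):
                    raise ValidationError(
                        "label_source='class' requires records with a "
                        "wellness_class in meta (synthetic records)"
                    )
                label = 0 if wc == BETTER else 1
            for win in segment_signal(rec, window_s, step_s):
                rows.append(resample_window(win.values, target_len))
                labels.append(label)
                prov.append(
                    {
                        "subject_id": subject_id,
                        "day_index": d,
                        "window_start_s": win.start_s,
                        "wellness_class": rec.meta.get("wellness_class", ""),
                    }
                )
    X = np.array(rows) if rows else np.empty((0, target_len))
    return SegmentDataset(
        X=X, labels=np.array(labels, dtype=int), provenance=pd.DataFrame(prov)
    )
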