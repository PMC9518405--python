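"""Predictive models and evaluation protocol.

Two classifiers are provided behind a common fit/predict contract: a random
forest with per-split feature subsampling, and an RBF-kernel SVM whose
(C, gamma) pair is tuned by particle swarm optimization (PSO) maximizing
cross-validated accuracy on the training set.  Deep baselines can be added
through the same contract without touching this module.

Evaluation follows the usual binary-classification quartet

    REC = TP / (TP + FN)        PRE = TP / (TP + FP)
    F   = 2 REC PRE / (REC + PRE)
    ACC = (TP + TN) / (TP + FP + FN + TN)

with the "Worse" class (label 1) as the positive class by default, since
detecting deterioration is the clinical aim.  The cross-validation protocol
is three seeded stratified 67/33 resampling rounds with arithmetically
averaged metrics; classical disjoint k-fold is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    StratifiedKFold,
    StratifiedShuffleSplit,
    cross_val_score,
    train_test_split,
)
from sklearn.svm import SVC

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "RFConfig",
    "PSOConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "Classifier",
    "train_rf",
    "pso_minimize",
    "train_pso_svm",
    "evaluate",
    "split_holdout",
    "cross_validate",
]


class Classifier(Protocol):
    """Pluggable classifier contract (satisfied by sklearn estimators)."""

    def fit(self, X, y): ...

    def predict(self, X) -> np.ndarray: ...


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings.

    ``mtry`` is the number of candidate features per split; when None it
    follows the defaults of the study protocol this package implements:
    12 for the 184-feature input, 20 for 500-dimensional raw input, and
    round(sqrt(p)) otherwise.
    """

    n_trees: int = 500
    mtry: int | None = None
    seed: int = 0


def default_mtry(n_features: int) -> int:
    if n_features == 184:
        return 12
    if n_features == 500:
        return 20
    return max(1, round(np.sqrt(n_features)))


def train_rf(
    features: np.ndarray, labels: np.ndarray, cfg: RFConfig | None = None
) -> RandomForestClassifier:
    """Bagged decision-tree ensemble with per-split feature subsampling."""
    cfg = cfg or RFConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training labels must contain both classes")
    mtry = cfg.mtry if cfg.mtry is not None else default_mtry(X.shape[1])
    if not 1 <= mtry <= X.shape[1]:
        raise ConfigurationError(
            f"mtry={mtry} outside 1..{X.shape[1]} (feature count)"
        )
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees, max_features=mtry, random_state=cfg.seed
    )
    model.fit(X, y)
    return model


@dataclass(frozen=True)
class PSOConfig:
    """Canonical global-best PSO settings.

    Defaults: 20 particles, at most 200 iterations with termination
    tolerance 1e-3 on the global best over a patience window, acceleration
    factors c1 = 1.5 and c2 = 1.7, search box [0.1, 100] per dimension, and
    a linearly decreasing inertia weight 0.9 -> 0.4.
    """

    n_particles: int = 20
    max_iters: int = 200
    tol: float = 1e-3
    patience: int = 20
    c1: float = 1.5
    c2: float = 1.7
    bounds: tuple[tuple[float, float], ...] = ((0.1, 100.0), (0.1, 100.0))
    v_max: float = 100.0
    inertia: tuple[float, float] = (0.9, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ConfigurationError("acceleration factors c1, c2 must be > 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigurationError(f"bound ({lo}, {hi}) must satisfy min < max")


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    cfg: PSOConfig | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Global-best PSO over the configured box.

    Velocity update v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x) with
    positions clipped to the box and velocities to [-v_max, v_max].  Stops
    at ``max_iters`` or when the global-best improvement over the last
    ``patience`` iterations falls below ``tol``.  Returns (best position,
    best value, per-iteration gbest trace); the trace is non-increasing by
    construction.  ``x0`` optionally fixes the initial particle positions
    (shape (n_particles, dim)); velocities always start at zero.
    """
    cfg = cfg or PSOConfig()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    dim = len(cfg.bounds)

    if x0 is not None:
        x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
        if x.shape != (cfg.n_particles, dim):
            raise InvalidArgumentError(f"x0 must have shape ({cfg.n_particles}, {dim})")
    else:
        x = rng.uniform(lo, hi, size=(cfg.n_particles, dim))
    v = np.zeros((cfg.n_particles, dim))

    def _eval(p: np.ndarray) -> float:
        val = float(objective(p))
        if not np.isfinite(val):
            raise InvalidArgumentError(f"objective not finite at {p}")
        return val

    pbest = x.copy()
    pbest_val = np.array([_eval(p) for p in x])
    g_idx = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])

    trace = [gbest_val]
    w_start, w_end = cfg.inertia
    for it in range(cfg.max_iters):
        w = w_start + (w_end - w_start) * it / max(1, cfg.max_iters - 1)
        r1 = rng.uniform(size=(cfg.n_particles, dim))
        r2 = rng.uniform(size=(cfg.n_particles, dim))
        v = w * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        v = np.clip(v, -cfg.v_max, cfg.v_max)
        x = np.clip(x + v, lo, hi)
        vals = np.array([_eval(p) for p in x])
        improved = vals < pbest_val
        pbest[improved] = x[improved]
        pbest_val[improved] = vals[improved]
        g_idx = int(np.argmin(pbest_val))
        if pbest_val[g_idx] < gbest_val:
            gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])
        trace.append(gbest_val)
        if len(trace) > cfg.patience and trace[-cfg.patience - 1] - gbest_val < cfg.tol:
            break
    return gbest, gbest_val, np.array(trace)


def train_pso_svm(
    features: np.ndarray,
    labels: np.ndarray,
    pso_cfg: PSOConfig | None = None,
    cv_folds: int = 5,
) -> tuple[SVC, tuple[float, float]]:
    """RBF-SVM with (C, gamma) selected by PSO on cross-validated accuracy.

    The objective minimized is 1 - mean k-fold CV accuracy on the training
    data; the final model is refit on the full training set with the chosen
    pair.  Seeded end-to-end through ``pso_cfg.seed``.
    """
    cfg = pso_cfg or PSOConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training labels must contain both classes")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=cfg.seed)

    def objective(p: np.ndarray) -> float:
        model = SVC(C=p[0], gamma=p[1], kernel="rbf")
        return 1.0 - float(np.mean(cross_val_score(model, X, y, cv=cv)))

    best, _, _ = pso_minimize(objective, cfg)
    c, gamma = float(best[0]), float(best[1])
    model = SVC(C=c, gamma=gamma, kernel="rbf")
    model.fit(X, y)
    return model, (c, gamma)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """REC/PRE/F on [0, 1]; ACC as a percentage.  ``degenerate`` flags any
    metric whose denominator was zero (reported as 0)."""

    rec: float
    pre: float
    f_score: float
    acc_percent: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "REC": self.rec,
            "PRE": self.pre,
            "F_score": self.f_score,
            "ACC_percent": self.acc_percent,
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    degenerate = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    rec = ratio(cm.tp, cm.tp + cm.fn, "REC")
    pre = ratio(cm.tp, cm.tp + cm.fp, "PRE")
    if rec + pre == 0:
        degenerate.append("F_score")
        f = 0.0
    else:
        f = 2 * rec * pre / (rec + pre)
    acc = 100.0 * ratio(cm.tp + cm.tn, cm.total, "ACC")
    return MetricsReport(
        rec=rec, pre=pre, f_score=f, acc_percent=acc, degenerate=tuple(degenerate)
    )


def evaluate(
    predicted: Sequence[int], actual: Sequence[int], positive: int = 1
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Exact integer confusion counts and the four metrics.

    ``positive`` selects which label counts as positive for REC/PRE/F
    (default 1, "Worse"); ACC is unaffected by the choice.
    """
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.shape != act.shape:
        raise InvalidArgumentError("predicted and actual must have equal length")
    p = pred == positive
    a = act == positive
    cm = ConfusionMatrix(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        fn=int(np.sum(~p & a)),
        tn=int(np.sum(~p & ~a)),
    )
    return cm, metrics_from_confusion(cm)


def split_holdout(
    features: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.70,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded per-class train/test split.  Returns (X_tr, X_te, y_tr, y_te)."""
    X = np.asarray(features)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if stratified and np.any(counts < 2):
        raise InvalidArgumentError("each class needs >= 2 samples for a stratified split")
    return train_test_split(
        X,
        y,
        train_size=train_frac,
        stratify=y if stratified else None,
        random_state=seed,
    )


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    model_factory: Callable[[int], Classifier],
    n_folds: int = 3,
    train_frac: float = 0.67,
    seed: int = 0,
    method: str = "resample",
    positive: int = 1,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Averaged metrics over seeded stratified rounds.

    ``method="resample"`` (default) draws ``n_folds`` independent stratified
    train/test splits at ``train_frac``; ``method="kfold"`` uses classical
    disjoint stratified folds instead.  ``model_factory(round_seed)`` must
    return a fresh classifier per round.  Metrics are averaged
    arithmetically.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if method == "resample":
        splitter = StratifiedShuffleSplit(
            n_splits=n_folds, train_size=train_frac, random_state=seed
        )
    elif method == "kfold":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        raise ConfigurationError("method must be 'resample' or 'kfold'")

    reports: list[MetricsReport] = []
    for round_i, (tr, te) in enumerate(splitter.split(X, y)):
        model = model_factory(seed + round_i)
        model.fit(X[tr], y[tr])
        _, report = evaluate(model.predict(X[te]), y[te], positive=positive)
        reports.append(report)
    mean = MetricsReport(
        rec=float(np.mean([r.rec for r in reports])),
        pre=float(np.mean([r.pre for r in reports])),
        f_score=float(np.mean([r.f_score for r in reports])),
        acc_percent=float(np.mean([r.acc_percent for r in reports])),
    )
    return mean, reports
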