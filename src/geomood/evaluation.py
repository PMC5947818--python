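"""Cross-validation with class equalization, and wrapper feature selection.

Validation schemes partition labeled weeks either by participant
(leave-one-participant-out, or participant-wise 5-/10-fold with stratified
partitions regenerated ``ceil(N/k)`` times) or within participants
(``threefold_within``: each participant's weeks interleaved over three
folds, so the same person contributes to both training and test). Because
depressed weeks are the minority class, every training set is rebalanced by
subsampling the majority class down to the minority count; the subsample is
redrawn ``M`` times per fold and metrics are summarised as median and IQR
over the M pooled-test evaluations.

Wrapper feature selection greedily grows a feature set, scoring every
candidate with a full cross-validation run of the downstream model.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import QuadraticLogisticGLM, classification_metrics, fit_linear, fit_qda, mae

Splits = list[tuple[np.ndarray, np.ndarray]]


@dataclasses.dataclass
class CVConfig:
    """Cross-validation settings.

    ``scheme`` is one of ``lopo``, ``kfold_participant`` (k in {5, 10}) or
    ``threefold_within``; ``m_equalize`` is the number of class-equalization
    redraws per fold (100 in the reference protocol).
    """

    scheme: str = "lopo"
    k: int = 10
    m_equalize: int = 100
    partition_repeats: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("lopo", "kfold_participant", "threefold_within"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "kfold_participant" and self.k not in (5, 10):
            raise ValueError("participant-wise k-fold uses k in {5, 10}")
        if self.m_equalize < 1:
            raise ValueError("m_equalize must be >= 1")


def group_equalize(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample of ``y``.

    All samples of the minority class are kept; the majority class is
    subsampled uniformly without replacement down to the minority count.
    """
    y = np.asarray(y).astype(int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present for equalization")
    n_min = min(len(idx0), len(idx1))
    keep0 = idx0 if len(idx0) == n_min else rng.choice(idx0, n_min, replace=False)
    keep1 = idx1 if len(idx1) == n_min else rng.choice(idx1, n_min, replace=False)
    return np.sort(np.concatenate([keep0, keep1]))


def _participant_folds(
    participants: np.ndarray, y: np.ndarray, groups: np.ndarray, k: int, rng: np.random.Generator
) -> Splits:
    """One random k-fold partition of participants, stratified by whether a
    participant has any depressed week (avoids folds without positives)."""
    has_pos = np.array([y[groups == p].any() for p in participants])
    order_pos = rng.permutation(participants[has_pos])
    order_neg = rng.permutation(participants[~has_pos])
    fold_of = {}
    for i, p in enumerate(np.concatenate([order_pos, order_neg])):
        fold_of[p] = i % k
    splits = []
    for f in range(k):
        test_p = {p for p, fl in fold_of.items() if fl == f}
        test = np.isin(groups, list(test_p))
        if not test.any():
            continue
        splits.append((np.flatnonzero(~test), np.flatnonzero(test)))
    return splits


def make_folds(
    groups: np.ndarray, y: np.ndarray, config: CVConfig, rng: np.random.Generator
) -> list[Splits]:
    """Fold sets per partition repetition (a single repetition except for
    participant-wise k-fold, repeated ``ceil(N/k)`` times)."""
    groups = np.asarray(groups)
    participants = np.unique(groups)
    if config.scheme == "lopo":
        splits = [
            (np.flatnonzero(groups != p), np.flatnonzero(groups == p)) for p in participants
        ]
        return [splits]
    if config.scheme == "kfold_participant":
        reps = config.partition_repeats or math.ceil(len(participants) / config.k)
        return [
            _participant_folds(participants, y, groups, config.k, rng) for _ in range(reps)
        ]
    # threefold_within: interleave each participant's weeks over three folds
    fold_idx = np.empty(len(groups), dtype=int)
    for p in participants:
        rows = np.flatnonzero(groups == p)
        fold_idx[rows] = np.arange(len(rows)) % 3
    splits = [
        (np.flatnonzero(fold_idx != f), np.flatnonzero(fold_idx == f)) for f in range(3)
    ]
    return [splits]


@dataclasses.dataclass
class CVResult:
    """Metric distributions over equalization iterations (and repetitions)."""

    metrics: dict[str, np.ndarray]
    n_skipped_folds: int = 0
    fpr_grid: np.ndarray | None = None
    mean_tpr: np.ndarray | None = None

    def median(self, name: str) -> float:
        v = self.metrics[name]
        v = v[~np.isnan(v)]
        return float(np.median(v)) if v.size else np.nan

    def iqr(self, name: str) -> float:
        v = self.metrics[name]
        v = v[~np.isnan(v)]
        if not v.size:
            return np.nan
        q1, q3 = np.percentile(v, [25, 75])
        return float(q3 - q1)

    def summary(self) -> dict[str, tuple[float, float]]:
        return {name: (self.median(name), self.iqr(name)) for name in self.metrics}


def qda_factory(**kwargs) -> Callable:
    return lambda X, y: fit_qda(X, y, **kwargs)


def linear_factory() -> Callable:
    return lambda X, y: fit_linear(X, y)


def glm_factory(**kwargs) -> Callable:
    return lambda X, y: QuadraticLogisticGLM(**kwargs).fit(X, y)


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    model_factory: Callable,
    config: CVConfig | None = None,
    task: str = "classification",
) -> CVResult:
    """Cross-validate a model over participant-grouped weeks.

    Classification: per fold and equalization redraw, the model is trained
    on a balanced subsample and test predictions from all folds of the same
    redraw are pooled before computing Ac/Se/Sp/F1/AUC; the result holds one
    value per redraw (times partition repetitions). Regression: one fit per
    fold on the full training data, pooled MAE per partition. Folds whose
    training data contain a single class are skipped and counted.
    """
    config = config or CVConfig()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(config.seed)
    partitions = make_folds(groups, y.astype(int) if task == "classification" else y > 0,
                            config, rng)

    n_skipped = 0
    fpr_grid = np.linspace(0, 1, 101)
    tprs = []

    if task == "regression":
        maes = []
        for splits in partitions:
            errors = []
            for tr, te in splits:
                model = model_factory(X[tr], np.asarray(y, float)[tr])
                pred = model.predict(X[te])
                errors.extend(np.abs(np.asarray(y, float)[te] - pred))
            maes.append(float(np.mean(errors)))
        return CVResult({"mae": np.asarray(maes)})

    yc = y.astype(int)
    names = ("ac", "se", "sp", "f1", "auc")
    out = {n: [] for n in names}
    for splits in partitions:
        usable = []
        for tr, te in splits:
            if len(np.unique(yc[tr])) < 2:
                n_skipped += 1
                warnings.warn("skipping fold with single-class training data")
                continue
            usable.append((tr, te))
        for _ in range(config.m_equalize):
            pooled_y, pooled_hat, pooled_score = [], [], []
            for tr, te in usable:
                eq = tr[group_equalize(yc[tr], rng)]
                model = model_factory(X[eq], yc[eq])
                pooled_y.append(yc[te])
                pooled_hat.append(model.predict(X[te]))
                if hasattr(model, "predict_proba"):
                    pooled_score.append(model.predict_proba(X[te])[:, 1])
                else:
                    pooled_score.append(model.predict(X[te]).astype(float))
            if not pooled_y:
                continue
            py = np.concatenate(pooled_y)
            ph = np.concatenate(pooled_hat)
            ps = np.concatenate(pooled_score)
            if len(np.unique(py)) < 2:
                # pooled test weeks single-class (after fold skipping):
                # threshold-sweep metrics are undefined
                for n in names:
                    out[n].append(np.nan)
                continue
            m = classification_metrics(py, ph, ps)
            for n in names:
                out[n].append(getattr(m, n))
            tprs.append(np.interp(fpr_grid, m.fpr, m.tpr))

    return CVResult(
        {n: np.asarray(v) for n, v in out.items()},
        n_skipped_folds=n_skipped,
        fpr_grid=fpr_grid,
        mean_tpr=np.mean(tprs, axis=0) if tprs else None,
    )


def _evaluate_columns(
    table: pd.DataFrame,
    cols: list[str],
    y: np.ndarray,
    groups: np.ndarray,
    model_factory: Callable,
    config: CVConfig,
    task: str,
) -> CVResult | None:
    """CV over the given columns, dropping weeks with missing values there."""
    sub = table[cols]
    ok = ~sub.isna().any(axis=1).to_numpy()
    if task == "classification" and len(np.unique(np.asarray(y)[ok].astype(int))) < 2:
        return None
    return run_cv(sub.to_numpy()[ok], np.asarray(y)[ok], np.asarray(groups)[ok],
                  model_factory, config, task)


def wrapper_select(
    table: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    model_factory: Callable,
    config: CVConfig | None = None,
    criterion: str = "f1",
    max_features: int = 10,
    candidates: Sequence[str] | None = None,
):
    """Greedy forward feature selection scored by cross-validated performance.

    At each step every remaining candidate column is joined to the selected
    set and evaluated with a full CV run; the best by ``criterion`` (median
    F1, maximised, or median MAE, minimised) is kept, ties breaking to the
    first candidate in canonical column order. Returns the ordered selected
    features and the per-size :class:`CVResult` trace.
    """
    config = config or CVConfig()
    task = "regression" if criterion == "mae" else "classification"
    remaining = list(candidates) if candidates is not None else list(table.columns)
    selected: list[str] = []
    trace: list[CVResult] = []
    sign = 1.0 if criterion == "mae" else -1.0

    while remaining and len(selected) < max_features:
        best_col, best_score, best_result = None, np.inf, None
        for col in remaining:
            result = _evaluate_columns(
                table, selected + [col], y, groups, model_factory, config, task
            )
            if result is None:
                continue
            score = sign * result.median(criterion)
            if score < best_score - 1e-12:
                best_col, best_score, best_result = col, score, result
        if best_col is None:
            break
        selected.append(best_col)
        remaining.remove(best_col)
        trace.append(best_result)
    return selected, trace


def permutation_baseline(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    model_factory: Callable,
    config: CVConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """The same CV with labels randomly permuted: a chance-level reference."""
    rng = np.random.default_rng(seed)
    y_perm = rng.permutation(np.asarray(y))
    return run_cv(X, y_perm, groups, model_factory, config)
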