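"""Fast Gentle Boosting phenotype classification.

Gentle boosting with single-threshold regression stumps, the classifier of
CellProfiler Analyst, implemented from scratch.  Each class is trained
one-vs-rest on targets y in {-1, +1} with uniform initial weights.  Every
round fits, for each candidate (feature, threshold), the stump

    f(x) = a * 1[x > theta] + b

by weighted least squares — b is the weighted mean of y where x <= theta
and a is the right-side mean minus b — and keeps the stump with the
smallest weighted squared error (ties: lowest feature index, then lowest
threshold).  Weights then update multiplicatively, w <- w * exp(-y f(x)),
and are renormalized.  Candidate thresholds are midpoints between sorted
distinct feature values; the split is strict (x exactly at theta takes the
``b`` branch).  Training is deterministic and invariant to row order.

Scoring sums the stump responses per class; the predicted class is the
argmax, ties broken by class order.  Stratified cross-validation reports a
row-normalized confusion matrix, and :func:`mitotic_index` derives the
fraction of cells predicted mitotic per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .synthetic import CLASSES

#: default feature set: all per-channel means plus the four size parameters
DEFAULT_SIZE_FEATURES = ["area_um2", "perimeter_um", "major_axis_um",
                         "minor_axis_um"]


@dataclass(frozen=True)
class StumpLearner:
    """One regression stump: response a*1[x > theta] + b on one feature."""

    feature_index: int
    threshold: float
    a: float
    b: float

    def response(self, x: np.ndarray) -> np.ndarray:
        return self.b + self.a * (x > self.threshold)


@dataclass
class BoostModel:
    """Per-class additive stump ensembles."""

    class_names: list[str]
    feature_names: list[str]
    stumps: dict[str, list[StumpLearner]]
    n_rounds: int

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "class_names": self.class_names,
            "feature_names": self.feature_names,
            "n_rounds": self.n_rounds,
            "stumps": {
                cls: [[s.feature_index, s.threshold, s.a, s.b] for s in seq]
                for cls, seq in self.stumps.items()
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "BoostModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            class_names=payload["class_names"],
            feature_names=payload["feature_names"],
            stumps={
                c: [StumpLearner(int(j), float(t), float(a), float(b))
                    for j, t, a, b in seq]
                for c, seq in payload["stumps"].items()
            },
            n_rounds=int(payload["n_rounds"]),
        )


@dataclass
class ConfusionMatrix:
    """Row-normalized true-vs-predicted class frequencies."""

    classes: list[str]
    matrix: np.ndarray  # K x K, rows sum to 1 (all-zero when unsupported)
    support: np.ndarray  # per-class true counts
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> StumpLearner:
    """Exhaustive weighted-least-squares stump search.

    Deterministic tie-break: lowest feature index, then lowest threshold
    (guaranteed by scanning features in order and thresholds ascending, with
    strict improvement required).
    """
    n, d = X.shape
    total_w = w.sum()
    total_wy = float(w @ y)
    best_err = np.inf
    best = None
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        wys = ws * y[order]
        cw = np.cumsum(ws)
        cwy = np.cumsum(wys)
        distinct = np.nonzero(xs[1:] > xs[:-1])[0]  # split after index i
        if distinct.size == 0:
            continue
        sw_l = cw[distinct]
        swy_l = cwy[distinct]
        sw_r = total_w - sw_l
        swy_r = total_wy - swy_l
        # SSE = sum w*y^2 - swy_l^2/sw_l - swy_r^2/sw_r; the constant term
        # is shared by all candidates, so compare the negative explained part
        gain = swy_l**2 / sw_l + swy_r**2 / sw_r
        err = float(w @ (y * y)) - gain
        k = int(np.argmax(gain))  # first maximum -> lowest theta among ties
        if err[k] < best_err:  # strict: ties keep the earlier feature/theta
            i = distinct[k]
            theta = 0.5 * (xs[i] + xs[i + 1])
            m_left = swy_l[k] / sw_l[k]
            m_right = swy_r[k] / sw_r[k]
            best_err = err[k]
            best = StumpLearner(j, float(theta), float(m_right - m_left),
                                float(m_left))
    if best is None:
        # all features constant: a single constant response
        m = total_wy / total_w
        best = StumpLearner(0, np.inf, 0.0, float(m))
    return best


def train_fast_gentle_boosting(
    table: pd.DataFrame,
    labels,
    feature_names: list[str],
    n_rounds: int = 50,
) -> BoostModel:
    """Train one-vs-rest gentle-boosting stump ensembles.

    ``labels`` is a per-row class label sequence; classes follow the
    canonical phenotype order when they are a subset of it, else sorted.
    Every class needs at least 2 members.
    """
    X = _feature_matrix(table, feature_names)
    labels = np.asarray(labels)
    present = list(dict.fromkeys(labels.tolist()))
    if set(present) <= set(CLASSES):
        class_names = [c for c in CLASSES if c in present]
    else:
        class_names = sorted(present)
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    for cls in class_names:
        if int(np.sum(labels == cls)) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")

    n = X.shape[0]
    stumps: dict[str, list[StumpLearner]] = {}
    for cls in class_names:
        y = np.where(labels == cls, 1.0, -1.0)
        w = np.full(n, 1.0 / n)
        seq = []
        for _ in range(n_rounds):
            stump = _best_stump(X, y, w)
            f = stump.response(X[:, stump.feature_index])
            w = w * np.exp(-y * f)
            w = w / w.sum()
            seq.append(stump)
        stumps[cls] = seq
    return BoostModel(class_names, list(feature_names), stumps, n_rounds)


def _feature_matrix(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise KeyError(f"feature column(s) missing from table: {missing}")
    return table.loc[:, list(feature_names)].to_numpy(dtype=float)


def class_scores(model: BoostModel, table: pd.DataFrame) -> np.ndarray:
    """N x K matrix of additive stump scores."""
    X = _feature_matrix(table, model.feature_names)
    scores = np.zeros((X.shape[0], len(model.class_names)))
    for k, cls in enumerate(model.class_names):
        for stump in model.stumps[cls]:
            scores[:, k] += stump.response(X[:, stump.feature_index])
    return scores


def score_cells(model: BoostModel, table: pd.DataFrame) -> pd.DataFrame:
    """Attach ``pred_class`` and per-class ``score_<class>`` columns."""
    scores = class_scores(model, table)
    pred = np.argmax(scores, axis=1)  # first max: ties -> class order
    out = table.copy()
    for k, cls in enumerate(model.class_names):
        out[f"score_{cls}"] = scores[:, k]
    out["pred_class"] = [model.class_names[k] for k in pred]
    return out


def cross_validate(
    table: pd.DataFrame,
    labels,
    feature_names: list[str],
    folds: int = 5,
    n_rounds: int = 50,
    seed: int = 0,
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    Returns the row-normalized confusion matrix (rows = true class) and the
    overall out-of-fold accuracy.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < folds]
    if too_small.size:
        raise ValueError(
            f"class(es) smaller than the fold count {folds}: {too_small.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(labels), dtype=object)
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        model = train_fast_gentle_boosting(
            table.iloc[train_idx], labels[train_idx], feature_names, n_rounds
        )
        scored = score_cells(model, table.iloc[test_idx])
        pred[test_idx] = scored["pred_class"].to_numpy()

    if set(classes) <= set(CLASSES):
        order = [c for c in CLASSES if c in classes]
    else:
        order = sorted(classes.tolist())
    k = len(order)
    idx = {c: i for i, c in enumerate(order)}
    counts_mat = np.zeros((k, k))
    for t, p in zip(labels, pred):
        counts_mat[idx[t], idx[p]] += 1
    support = counts_mat.sum(axis=1)
    matrix = np.zeros_like(counts_mat)
    nz = support > 0
    matrix[nz] = counts_mat[nz] / support[nz, None]
    accuracy = float(np.trace(counts_mat) / counts_mat.sum())
    return ConfusionMatrix(order, matrix, support.astype(int), accuracy)


def mitotic_index(
    scored: pd.DataFrame,
    mitotic_class: str = "pHistone3+",
    class_column: str = "pred_class",
) -> pd.DataFrame:
    """Fraction of cells in the mitotic class, per condition.

    ROI replicates of a condition are pooled; the ratio is formed with exact
    rational arithmetic before conversion to float.  Conditions with zero
    cells are reported with a missing index.
    """
    if class_column not in scored.columns:
        raise KeyError(f"{class_column!r} column absent; score cells first")
    rows = []
    for cond, grp in scored.groupby("condition", sort=False):
        n = len(grp)
        n_mit = int((grp[class_column] == mitotic_class).sum())
        index = float(Fraction(n_mit, n)) if n > 0 else np.nan
        rows.append({"condition": cond, "n_cells": n, "n_mitotic": n_mit,
                     "mitotic_index": index})
    return pd.DataFrame(rows)


def default_feature_names(table: pd.DataFrame) -> list[str]:
    """All mean-intensity columns plus the size parameters present."""
    means = [c for c in table.columns if c.startswith("mean_")]
    sizes = [c for c in DEFAULT_SIZE_FEATURES if c in table.columns]
    return means + sizes
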