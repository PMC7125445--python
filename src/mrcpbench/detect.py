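"""The six single-channel MRCP detectors.

All detectors consume z-normalized 2-second single-channel epochs (as raw
sample vectors) and emit a binary MRCP / non-MRCP decision:

* ``LDA`` — linear discriminant with Ledoit-Wolf shrinkage of the pooled
  covariance (the raw sample vector is high-dimensional relative to the
  number of training epochs);
* ``SVM`` — support vector machine with an inner grid search over kernel
  (linear / RBF), C and gamma, selected by cross-validated F1;
* ``NN_ED`` / ``NN_DTW`` — one-nearest-neighbour under Euclidean distance
  and under dynamic time warping constrained to a Sakoe-Chiba band of
  r = 10% of the series length;
* ``MF`` — matched filter: the template is the arithmetic mean of the
  training MRCP epochs, the decision statistic is the maximum of the
  convolution of the epoch with the time-reversed template, and the
  threshold is the value that maximizes training-set F1;
* ``TM`` — shape-based template matching: the template is the DTW
  barycenter average (DBA) of the training MRCP epochs (medoid-initialized,
  10% band), the statistic is the negated constrained DTW distance to the
  template, thresholded like MF.

Decision convention: statistic >= threshold => MRCP; 1-NN ties go to the
lowest-indexed training epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .preprocess import MRCP, NON_MRCP, Epoch

__all__ = [
    "DETECTORS",
    "DetectorModel",
    "dtw_distance",
    "dba_template",
    "medoid_index",
    "fit_detector",
    "predict",
    "predict_batch",
]

DETECTORS = ["LDA", "SVM", "NN_ED", "NN_DTW", "MF", "TM"]

#: Sakoe-Chiba band radius as a fraction of the series length.
DTW_BAND_R = 0.10

_SVM_GRID = [
    {"kernel": ["linear"], "C": [0.1, 1.0, 10.0, 100.0]},
    {"kernel": ["rbf"], "C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]},
]


# ---------------------------------------------------------------------------
# constrained DTW kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _dtw_cost(a, b, w):  # pragma: no cover - exercised via dtw_distance
    n = a.shape[0]
    m = b.shape[0]
    big = np.inf
    acc = np.full((n + 1, m + 1), big)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo = max(1, i - w)
        jhi = min(m, i + w)
        for j in range(jlo, jhi + 1):
            d = a[i - 1] - b[j - 1]
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = d * d + best
    return acc[n, m]


@njit(cache=False)
def _dtw_path(a, b, w):  # pragma: no cover - exercised via dba_template
    n = a.shape[0]
    m = b.shape[0]
    big = np.inf
    acc = np.full((n + 1, m + 1), big)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo = max(1, i - w)
        jhi = min(m, i + w)
        for j in range(jlo, jhi + 1):
            d = a[i - 1] - b[j - 1]
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = d * d + best
    # backtrack
    path_i = np.empty(n + m, dtype=np.int64)
    path_j = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        path_i[k] = i - 1
        path_j[k] = j - 1
        k += 1
        diag = acc[i - 1, j - 1] if i > 0 and j > 0 else big
        up = acc[i - 1, j] if i > 0 else big
        left = acc[i, j - 1] if j > 0 else big
        if diag <= up and diag <= left:
            i -= 1
            j -= 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    return acc[n, m], path_i[:k], path_j[:k]


def _band_width(n: int, r: float) -> int:
    return int(math.ceil(r * n))


def dtw_distance(a: np.ndarray, b: np.ndarray, r: float = DTW_BAND_R) -> float:
    """Constrained DTW distance between equal-length series.

    Dynamic programming over the Sakoe-Chiba band |i - j| <= ceil(r * n)
    with squared point-wise cost; the accumulated total is square-rooted,
    so the unconstrained distance never exceeds the Euclidean distance.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.shape[0] != b.shape[0]:
        raise ValueError("dtw_distance requires equal-length 1-D series")
    if not 0 < r <= 1:
        raise ValueError("band fraction r must be in (0, 1]")
    return float(np.sqrt(_dtw_cost(a, b, _band_width(a.shape[0], r))))


def medoid_index(series: np.ndarray, r: float = DTW_BAND_R) -> int:
    """Index of the series minimizing the summed DTW distance to all others."""
    k = series.shape[0]
    w = _band_width(series.shape[1], r)
    dmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = np.sqrt(_dtw_cost(series[i], series[j], w))
            dmat[i, j] = dmat[j, i] = d
    return int(np.argmin(dmat.sum(axis=1)))


def dba_template(
    series: Sequence[np.ndarray] | np.ndarray,
    r: float = DTW_BAND_R,
    max_iter: int = 10,
    tol: float = 1e-4,
    return_history: bool = False,
):
    """DTW barycenter average of a set of equal-length series.

    Starts from the medoid, then repeatedly aligns every series to the
    current template under the banded DTW and replaces each template point
    by the mean of all series points mapped onto it.  The DBA objective —
    the sum of accumulated (squared-cost) DTW alignment costs to the
    template — is non-increasing under this update and is tracked in the
    history; iteration stops when the relative improvement drops below
    ``tol`` or after ``max_iter`` rounds, and the best template seen is
    returned.
    """
    x = np.ascontiguousarray(np.asarray(series, dtype=np.float64))
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("dba_template requires a non-empty set of equal-length series")
    if x.shape[0] == 1:
        return (x[0].copy(), [0.0]) if return_history else x[0].copy()
    w = _band_width(x.shape[1], r)
    template = x[medoid_index(x, r)].copy()

    def objective(t: np.ndarray) -> float:
        return float(sum(_dtw_cost(t, s, w) for s in x))

    history = [objective(template)]
    best, best_obj = template, history[0]
    for _ in range(max_iter):
        sums = np.zeros_like(template)
        counts = np.zeros_like(template)
        for s in x:
            _, pi, pj = _dtw_path(template, s, w)
            for a_idx, b_idx in zip(pi, pj):
                sums[a_idx] += s[b_idx]
                counts[a_idx] += 1.0
        template = sums / np.maximum(counts, 1.0)
        obj = objective(template)
        history.append(obj)
        if obj <= best_obj:
            best, best_obj = template, obj
        if abs(history[-2] - obj) < tol * max(history[-2], 1e-30):
            break
    if return_history:
        return best, history
    return best


# ---------------------------------------------------------------------------
# threshold calibration for the template detectors
# ---------------------------------------------------------------------------

def best_threshold(stats: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing F1 of the rule ``stat >= threshold => MRCP``.

    Candidates are the midpoints between consecutive distinct sorted
    statistic values plus one value below the minimum (predict everything
    MRCP) and one above the maximum (predict nothing).  Ties in F1 go to
    the lowest candidate (the most sensitive detector).
    """
    stats = np.asarray(stats, dtype=float)
    y = np.asarray(y)
    vals = np.unique(stats)
    cands = np.concatenate([[vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2.0, [vals[-1] + 1.0]])
    best_f1 = -1.0
    best_thr = cands[0]
    for thr in cands:
        pred = stats >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr, best_f1


# ---------------------------------------------------------------------------
# detector fitting / prediction
# ---------------------------------------------------------------------------

@dataclass
class DetectorModel:
    """A fitted detector; exactly one of clf / train data / template is used."""

    kind: str
    n_features: int
    clf: object | None = None
    train_x: np.ndarray | None = None
    train_y: np.ndarray | None = None
    template: np.ndarray | None = None
    threshold: float | None = None
    dtw_band_r: float = DTW_BAND_R
    fit_metadata: dict = field(default_factory=dict)


def _as_xy(epochs: Sequence[Epoch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([ep.series() for ep in epochs])
    y = np.array([1 if ep.label == MRCP else 0 for ep in epochs])
    return x, y


def _mf_statistic(x: np.ndarray, template: np.ndarray) -> float:
    return float(np.convolve(x, template[::-1], mode="same").max())


def fit_detector(
    kind: str,
    train_epochs: Sequence[Epoch],
    seed: int = 0,
    dba_max_iter: int = 10,
    dba_tol: float = 1e-4,
) -> DetectorModel:
    """Fit one detector on single-channel training epochs (both classes required)."""
    if kind not in DETECTORS:
        raise ValueError(f"unknown detector {kind!r}")
    x, y = _as_xy(train_epochs)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"{kind} needs >= 2 training epochs per class "
                         f"(got {n_pos} MRCP / {n_neg} non-MRCP)")
    n_feat = x.shape[1]
    model = DetectorModel(kind=kind, n_features=n_feat, fit_metadata={"seed": seed})

    if kind == "LDA":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(x, y)
        model.clf = clf
    elif kind == "SVM":
        n_splits = min(3, n_pos, n_neg)
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        gs = GridSearchCV(SVC(), _SVM_GRID, cv=cv, scoring="f1", n_jobs=1)
        gs.fit(x, y)
        model.clf = gs.best_estimator_
        model.fit_metadata["best_params"] = gs.best_params_
    elif kind in ("NN_ED", "NN_DTW"):
        model.train_x = x
        model.train_y = y
    elif kind == "MF":
        template = x[y == 1].mean(axis=0)
        stats = np.array([_mf_statistic(xi, template) for xi in x])
        thr, f1 = best_threshold(stats, y)
        model.template = template
        model.threshold = thr
        model.fit_metadata["train_f1"] = f1
    elif kind == "TM":
        template = dba_template(x[y == 1], r=DTW_BAND_R, max_iter=dba_max_iter, tol=dba_tol)
        stats = np.array([-dtw_distance(xi, template, DTW_BAND_R) for xi in x])
        thr, f1 = best_threshold(stats, y)
        model.template = template
        model.threshold = thr
        model.fit_metadata["train_f1"] = f1
    return model


def _predict_one(model: DetectorModel, x: np.ndarray) -> int:
    if x.shape[0] != model.n_features:
        raise ValueError(
            f"epoch length {x.shape[0]} does not match training length {model.n_features}"
        )
    if model.kind in ("LDA", "SVM"):
        return int(model.clf.predict(x[None, :])[0])
    if model.kind == "NN_ED":
        d = np.linalg.norm(model.train_x - x, axis=1)
        return int(model.train_y[int(np.argmin(d))])  # argmin -> lowest index on ties
    if model.kind == "NN_DTW":
        d = np.array([dtw_distance(x, t, model.dtw_band_r) for t in model.train_x])
        return int(model.train_y[int(np.argmin(d))])
    if model.kind == "MF":
        return int(_mf_statistic(x, model.template) >= model.threshold)
    if model.kind == "TM":
        return int(-dtw_distance(x, model.template, model.dtw_band_r) >= model.threshold)
    raise ValueError(f"unknown detector {model.kind!r}")


def predict(model: DetectorModel, epoch: Epoch) -> str:
    """Binary decision for one single-channel epoch."""
    return MRCP if _predict_one(model, epoch.series()) else NON_MRCP


def predict_batch(model: DetectorModel, epochs: Sequence[Epoch]) -> np.ndarray:
    """Vector of 0/1 decisions (1 = MRCP) for a batch of epochs."""
    if model.kind in ("LDA", "SVM"):
        x = np.stack([ep.series() for ep in epochs])
        if x.shape[1] != model.n_features:
            raise ValueError("epoch length does not match training length")
        return model.clf.predict(x).astype(int)
    return np.array([_predict_one(model, ep.series()) for ep in epochs])
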