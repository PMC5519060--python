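"""Random-forest classification of detected breaks and of the reference scene.

Two classification problems share the machinery:

* detected structural breaks -> {clear-cut, stabilization}, from the break
  features (magnitude, slope before/after, preceding duration);
* the start-of-record reference image -> six cover classes, from its bands.

Both report out-of-bag (OOB) error, estimated only from trees whose bootstrap
excluded the point.  In synthetic mode break training labels come from the
generator truth: a detected break matching a true clear-cut within a dating
tolerance is a clear-cut, anything else is a stabilization break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .breaks import BreakRecord

CLEAR_CUT = "clear-cut"
STABILIZATION = "stabilization"
BREAK_FEATURES = ("magnitude", "slope_before", "slope_after", "duration_before")
FALLBACK_MAGNITUDE_DELTA = 0.15


@dataclass
class ClassifierModel:
    model: RandomForestClassifier
    feature_names: tuple
    classes: tuple
    oob_error: float


def train_break_classifier(features: np.ndarray, labels, seed: int = 0,
                           n_trees: int = 500) -> ClassifierModel:
    """Train the break-type classifier with an OOB error estimate."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != len(BREAK_FEATURES):
        raise ValueError(f"expected features with columns {BREAK_FEATURES}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < 20:
        raise ValueError("need at least 20 labelled breaks")
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return ClassifierModel(rf, BREAK_FEATURES, tuple(rf.classes_), 1.0 - rf.oob_score_)


def classify_break(model: ClassifierModel | None, brk: BreakRecord,
                   delta: float = FALLBACK_MAGNITUDE_DELTA) -> str:
    """Classify one break; with no model, fall back to the magnitude rule
    (a drop larger than ``delta`` is a clear-cut)."""
    if model is None:
        return CLEAR_CUT if brk.magnitude < -delta else STABILIZATION
    if len(model.feature_names) != len(BREAK_FEATURES):
        raise ValueError("feature schema mismatch")
    pred = model.model.predict(brk.features()[None, :])
    return str(pred[0])


def label_breaks_from_truth(detected_times: np.ndarray, true_cut_dates: np.ndarray,
                            tolerance_yr: float = 1.0) -> np.ndarray:
    """Greedy one-to-one matching of detected breaks to true cuts by dating
    error; matched breaks are clear-cuts, the rest stabilization."""
    detected_times = np.asarray(detected_times, dtype=float)
    true_cut_dates = np.asarray(true_cut_dates, dtype=float)
    labels = np.full(len(detected_times), STABILIZATION, dtype=object)
    if len(detected_times) == 0 or len(true_cut_dates) == 0:
        return labels
    pairs = [(abs(dt - tc), i, j)
             for i, dt in enumerate(detected_times)
             for j, tc in enumerate(true_cut_dates)
             if abs(dt - tc) <= tolerance_yr]
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in sorted(pairs):
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        labels[i] = CLEAR_CUT
    return labels


def classify_reference_image(bands: np.ndarray, train_idx: np.ndarray,
                             train_labels: np.ndarray, seed: int = 0,
                             n_trees: int = 500, n_classes: int = 6
                             ) -> tuple[np.ndarray, float, np.ndarray]:
    """Six-class classification of the reference scene.

    bands : (H, W, B) image; train_idx : (n, 2) row/col of labelled pixels.
    Returns (per-pixel class map, OOB error, pairwise OOB error matrix) where
    ``pairwise[i, j]`` is the OOB confusion rate restricted to classes i and j
    (class codes 1..n_classes).
    """
    train_labels = np.asarray(train_labels)
    present = set(np.unique(train_labels).tolist())
    missing = sorted(set(range(1, n_classes + 1)) - present)
    if missing:
        raise ValueError(f"training data missing cover classes: {missing}")
    X = bands[train_idx[:, 0], train_idx[:, 1], :]
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=seed, n_jobs=1)
    rf.fit(X, train_labels)
    oob_error = 1.0 - rf.oob_score_

    # pairwise error from OOB votes
    proba = rf.oob_decision_function_
    oob_pred = rf.classes_[np.nanargmax(np.nan_to_num(proba, nan=-1.0), axis=1)]
    pw = np.zeros((n_classes, n_classes))
    for i in range(1, n_classes + 1):
        for j in range(1, n_classes + 1):
            if i == j:
                continue
            mi = train_labels == i
            mj = train_labels == j
            denom = mi.sum() + mj.sum()
            if denom == 0:
                continue
            err = (oob_pred[mi] == j).sum() + (oob_pred[mj] == i).sum()
            pw[i - 1, j - 1] = err / denom

    h, w, b = bands.shape
    class_map = rf.predict(bands.reshape(-1, b)).reshape(h, w).astype(np.uint8)
    return class_map, float(oob_error), pw
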