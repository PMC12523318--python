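"""Ridge classification of PPV feature maps with a zero decision threshold.

Labels are encoded +1 ("present") / -1 ("absent"); features are
standardized by training statistics (zero-variance columns get unit
scale); the L2 penalty is chosen by efficient leave-one-out error over a
log-spaced grid.  The decision rule is the classic sign rule: "present"
iff the decision value is strictly positive — a value of exactly zero
predicts "absent", favoring specificity.

Feature importance is read directly off the fitted weights: columns
with coefficients near zero contribute negligibly to the decision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import RidgeCV

from .minirocket import FeatureMap

__all__ = [
    "RidgeModel",
    "SplitPlan",
    "make_split",
    "fit",
    "predict",
    "top_features",
    "save_model",
    "load_model",
]

DEFAULT_ALPHAS = np.logspace(-3, 3, 10)


@dataclass
class SplitPlan:
    """Disjoint train/test index sets from a seeded shuffle."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int
    mode: str


def make_split(
    group_ids,
    labels,
    fraction_train: float = 0.8,
    seed: int = 0,
    mode: str = "patient_level",
    patient_ids=None,
) -> SplitPlan:
    """Seeded shuffle-then-split of group indices.

    The train side receives floor(fraction_train * n) groups in
    ``group_level`` mode.  In ``patient_level`` mode whole patients are
    assigned to one side, so no patient's augmented descendants leak
    across the boundary; the train side is filled patient by patient
    until it reaches the target count.
    """
    n = len(group_ids)
    if not 0 < fraction_train < 1:
        raise ValueError("fraction_train must be in (0, 1)")
    n_train = int(np.floor(fraction_train * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split of {n} groups at {fraction_train} leaves one side empty")
    rng = np.random.default_rng(seed)
    if mode == "group_level":
        order = rng.permutation(n)
        train, test = order[:n_train], order[n_train:]
    elif mode == "patient_level":
        if patient_ids is None:
            raise ValueError("patient_level split needs patient_ids")
        patient_ids = np.asarray(patient_ids)
        patients = list(dict.fromkeys(patient_ids))  # stable unique
        rng.shuffle(patients)
        train_patients, count = [], 0
        for p in patients:
            if count >= n_train:
                break
            train_patients.append(p)
            count += int(np.sum(patient_ids == p))
        train_set = set(train_patients)
        train = np.flatnonzero([p in train_set for p in patient_ids])
        test = np.flatnonzero([p not in train_set for p in patient_ids])
        if len(train) == 0 or len(test) == 0:
            raise ValueError("patient_level split left one side empty")
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return SplitPlan(train_ids=np.sort(train), test_ids=np.sort(test), seed=seed, mode=mode)


@dataclass
class RidgeModel:
    weights: np.ndarray
    intercept: float
    alpha: float
    mean: np.ndarray
    scale: np.ndarray
    classes: tuple = ("absent", "present")
    feature_ids: list = field(default_factory=list)


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    y = np.where(labels == "present", 1.0, np.where(labels == "absent", -1.0, np.nan))
    if np.isnan(y).any():
        bad = sorted(set(labels) - {"present", "absent"})
        raise ValueError(f"unknown labels {bad}")
    return y


def fit(
    features,
    labels,
    alphas=DEFAULT_ALPHAS,
    standardize: bool = True,
    class_weight=None,
) -> RidgeModel:
    """Ridge regression on ±1 targets with leave-one-out alpha selection.

    ``class_weight="balanced"`` reweights samples inversely to class
    frequency (off by default).  Requires both classes in the training
    set.
    """
    X = features.values if isinstance(features, FeatureMap) else np.asarray(features)
    X = X.astype(np.float64)
    y = _encode(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    sample_weight = None
    if class_weight == "balanced":
        n_pos, n_neg = np.sum(y > 0), np.sum(y < 0)
        sample_weight = np.where(y > 0, len(y) / (2.0 * n_pos), len(y) / (2.0 * n_neg))
    model = RidgeCV(alphas=np.asarray(alphas), fit_intercept=True)
    model.fit(Xs, y, sample_weight=sample_weight)
    fids = features.feature_ids if isinstance(features, FeatureMap) else []
    return RidgeModel(
        weights=model.coef_.ravel(),
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        mean=mean,
        scale=scale,
        feature_ids=fids,
    )


def predict(model: RidgeModel, features):
    """Labels and raw decision values; "present" iff decision > 0."""
    X = features.values if isinstance(features, FeatureMap) else np.asarray(features)
    if X.shape[1] != len(model.weights):
        raise ValueError(f"feature count {X.shape[1]} != model size {len(model.weights)}")
    decisions = ((X - model.mean) / model.scale) @ model.weights + model.intercept
    labels = np.where(decisions > 0, "present", "absent")
    return labels, decisions


def top_features(model: RidgeModel, k: int) -> list:
    """Top-k features by |coefficient| (descending), ties broken by index."""
    n = len(model.weights)
    if k > n:
        warnings.warn(f"k={k} clamped to feature count {n}", stacklevel=2)
        k = n
    order = np.lexsort((np.arange(n), -np.abs(model.weights)))[:k]
    ids = model.feature_ids or [{"feature": i} for i in range(n)]
    return [(ids[i], float(model.weights[i])) for i in order]


def save_model(model: RidgeModel, path) -> None:
    """JSON manifest (alpha, intercept, standardization) + weight vector file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "alpha": model.alpha,
        "intercept": model.intercept,
        "classes": list(model.classes),
        "n_features": len(model.weights),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    np.savetxt(
        path.with_suffix(".weights.tsv"),
        np.column_stack([model.weights, model.mean, model.scale]),
        header="weight\tmean\tscale", delimiter="\t", comments="",
    )


def load_model(path) -> RidgeModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    table = np.loadtxt(path.with_suffix(".weights.tsv"), delimiter="\t", skiprows=1)
    return RidgeModel(
        weights=table[:, 0],
        intercept=manifest["intercept"],
        alpha=manifest["alpha"],
        mean=table[:, 1],
        scale=table[:, 2],
        classes=tuple(manifest["classes"]),
    )
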