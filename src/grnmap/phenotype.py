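"""Class-weighted logistic classification of binarized clinical phenotypes.

Clinical scales (Braak tangle stage, CERAD plaque score, DCFDX/COGDX cognitive
diagnoses) are binarized at their conventional cut-points, then a logistic
regression on disease-gene expression is evaluated by stratified K-fold
cross-validation. Training folds are balanced with inverse-class-frequency
weights and accuracy is scored as the mean of per-class recalls (balanced
accuracy), so the chance level is 50% for any class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils import resample
from sklearn.utils.validation import check_X_y

SCHEMES: Dict[str, Dict] = {
    # early tangle stages vs late
    "braak": {"domain": set(range(0, 7)), "positive": {4, 5, 6}},
    # no/mild cognitive impairment vs dementia
    "dcfdx": {"domain": set(range(1, 6)), "positive": {4, 5}},
    "cogdx": {"domain": set(range(1, 6)), "positive": {4, 5}},
}


@dataclass
class PhenotypeDataset:
    sample_ids: List[str]
    features: np.ndarray  # samples x d
    labels: np.ndarray  # binary
    phenotype_name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.labels):
            raise ValueError("features and labels are inconsistent")
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("both classes must be present")


@dataclass
class CvResult:
    fold_accuracies: List[float]
    mean_accuracy: float
    K: int
    seed: int


def binarize_phenotype(raw_scores: Sequence[float], scheme: str,
                       cerad_map: Optional[Dict[float, int]] = None,
                       cut: Optional[float] = None) -> np.ndarray:
    """Binarize a clinical scale.

    braak: stages {0..3} -> 0, {4..6} -> 1. dcfdx/cogdx: {1..3} -> 0, {4,5} -> 1.
    cerad: requires an explicit score -> {0,1} mapping (site codings differ).
    threshold: labels 1 iff score >= ``cut``.
    """
    scores = list(raw_scores)
    if scheme == "cerad":
        if cerad_map is None:
            raise ValueError("scheme 'cerad' requires an explicit cerad_map")
        out = []
        for i, s in enumerate(scores):
            if s not in cerad_map:
                raise ValueError(f"sample {i}: CERAD score {s!r} not in supplied mapping")
            out.append(int(cerad_map[s]))
        return np.array(out, dtype=int)
    if scheme == "threshold":
        if cut is None:
            raise ValueError("scheme 'threshold' requires a cut point")
        return np.array([1 if s >= cut else 0 for s in scores], dtype=int)
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    spec = SCHEMES[scheme]
    out = []
    for i, s in enumerate(scores):
        if s not in spec["domain"]:
            raise ValueError(f"sample {i}: score {s!r} outside the {scheme} domain")
        out.append(1 if s in spec["positive"] else 0)
    return np.array(out, dtype=int)


class WeightedLogisticClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression with standardized features and class balancing.

    ``balance='weights'`` uses inverse-frequency class weights in the loss;
    ``balance='resample'`` instead upsamples the minority class in fit. A small
    L2 penalty (strength 1/C) keeps d > n folds well-posed.
    """

    def __init__(self, C: float = 1.0, balance: str = "weights", seed: int = 0,
                 max_iter: int = 2000):
        self.C = C
        self.balance = balance
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.balance not in ("weights", "resample"):
            raise ValueError(f"unknown balance mode {self.balance!r}")
        class_weight = "balanced" if self.balance == "weights" else None
        if self.balance == "resample":
            classes, counts = np.unique(y, return_counts=True)
            n_max = counts.max()
            parts_X, parts_y = [], []
            for cls, cnt in zip(classes, counts):
                Xc, yc = X[y == cls], y[y == cls]
                if cnt < n_max:
                    Xc, yc = resample(Xc, yc, replace=True, n_samples=n_max,
                                      random_state=self.seed)
                parts_X.append(Xc)
                parts_y.append(yc)
            X, y = np.vstack(parts_X), np.concatenate(parts_y)
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, class_weight=class_weight, max_iter=self.max_iter),
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def predict(self, X):
        return self.pipeline_.predict(X)

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(X)


def weighted_logistic_cv(data: PhenotypeDataset, K: int = 5, seed: int = 0,
                         C: float = 1.0, balance: str = "weights") -> CvResult:
    """Stratified K-fold CV (80/20 per fold at K=5) of the weighted classifier,
    scored by balanced accuracy so that chance is 50%."""
    counts = np.bincount(data.labels)
    if counts.min() < K:
        raise ValueError(f"each class needs >= K={K} samples, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(data.features, data.labels):
        clf = WeightedLogisticClassifier(C=C, balance=balance, seed=seed)
        clf.fit(data.features[train_idx], data.labels[train_idx])
        pred = clf.predict(data.features[test_idx])
        accs.append(float(balanced_accuracy_score(data.labels[test_idx], pred)))
    return CvResult(fold_accuracies=accs, mean_accuracy=float(np.mean(accs)), K=K, seed=seed)
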