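"""Base classifiers and the top-k soft-voting diagnostic ensemble.

The registry provides the classifier families used throughout: regularized
logistic regression, random forest, k-nearest neighbors, RBF/linear SVC with
probability outputs, and a gradient-boosted tree family. The final
diagnostic model averages the predicted class probabilities of the top
learners (soft voting), each fitted on its own SFFS-selected feature
subset, with optional inverse-frequency class weighting and an optional
weighted-vote augmentation with serum biomarker channels (CA125/CEA)
rescaled through the training split's empirical CDF.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "LEARNER_NAMES",
    "LEARNER_GRIDS",
    "make_learner",
    "tuned_learner",
    "fit_base",
    "predict_scores",
    "soft_vote",
    "classify",
    "biomarker_weighted_vote",
    "ecdf_rescale",
    "VotingEnsembleClassifier",
    "save_ensemble",
    "load_ensemble",
]

LEARNER_NAMES = ("logreg", "rf", "knn", "svc", "svc_linear", "gbdt")

#: features needing z-scoring before distance/margin-based learners
_SCALE_SENSITIVE = {"logreg", "knn", "svc", "svc_linear"}

#: small fixed hyperparameter grids searched inside the CV when tuning
LEARNER_GRIDS: dict[str, dict] = {
    "logreg": {"C": [0.1, 1.0, 10.0]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 6]},
    "knn": {"n_neighbors": [3, 5, 9]},
    "svc": {"C": [0.5, 1.0, 5.0]},
    "svc_linear": {"C": [0.5, 1.0, 5.0]},
    "gbdt": {"learning_rate": [0.05, 0.1], "max_iter": [100, 200]},
}


def make_learner(name: str, seed: int = 0, class_weighting: bool = False,
                 probability: bool = True, with_scaler: bool = False):
    """Instantiate a registry classifier.

    SVC variants score through their margin (``decision_function``), which
    :func:`predict_scores` squashes onto the probability scale; the margin
    alone suffices for AUC-driven selection. ``with_scaler`` wraps
    scale-sensitive learners in a z-scoring pipeline for final fits.
    """
    cw = "balanced" if class_weighting else None
    if name == "logreg":
        est = LogisticRegression(C=1.0, max_iter=2000, class_weight=cw,
                                 random_state=seed)
    elif name == "rf":
        est = RandomForestClassifier(n_estimators=200, class_weight=cw,
                                     random_state=seed)
    elif name == "knn":
        if class_weighting:
            raise ValueError("knn has no class-weighted loss")
        est = KNeighborsClassifier(n_neighbors=5)
    elif name == "svc":
        est = SVC(kernel="rbf", C=1.0, class_weight=cw, random_state=seed)
    elif name == "svc_linear":
        est = LinearSVC(C=1.0, class_weight=cw, random_state=seed)
    elif name == "gbdt":
        est = HistGradientBoostingClassifier(
            max_iter=150, class_weight=cw, random_state=seed
        )
    else:
        raise ValueError(f"unknown learner {name!r}; choose from {LEARNER_NAMES}")
    if with_scaler and name in _SCALE_SENSITIVE:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def tuned_learner(name: str, seed: int = 0, folds: int = 10,
                  class_weighting: bool = False) -> GridSearchCV:
    """Registry learner wrapped in a small grid search (roc_auc scoring)."""
    est = make_learner(name, seed=seed, class_weighting=class_weighting)
    grid = LEARNER_GRIDS[name]
    return GridSearchCV(est, grid, scoring="roc_auc", cv=folds)


def fit_base(learner, X, y, class_weighting: bool = False, seed: int = 0):
    """Fit one base classifier on its feature subset.

    ``learner`` is a registry name or estimator; class weighting uses
    per-class loss weights proportional to inverse class frequency. The
    fitted model emits probability-scale scores in [0, 1].
    """
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    if isinstance(learner, str):
        model = make_learner(learner, seed=seed, class_weighting=class_weighting,
                             with_scaler=True)
    else:
        model = clone(learner)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def predict_scores(model, X) -> np.ndarray:
    """Probability-scale score of the positive class in [0, 1]."""
    X = np.asarray(X, dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X)[:, 1], dtype=float)
    s = np.asarray(model.decision_function(X), dtype=float)
    return 1.0 / (1.0 + np.exp(-s))  # squash margins onto [0, 1]


def soft_vote(scores: list[np.ndarray] | np.ndarray, weights=None) -> np.ndarray:
    """Weighted elementwise mean of aligned score arrays."""
    arrays = [np.asarray(s, dtype=float) for s in scores]
    n = arrays[0].shape[0]
    for a in arrays[1:]:
        if a.shape[0] != n:
            raise ValueError("score arrays must be aligned")
    if weights is None:
        weights = np.ones(len(arrays))
    w = np.asarray(weights, dtype=float)
    if w.size != len(arrays):
        raise ValueError("one weight per score array required")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be >= 0 and not all zero")
    return np.average(np.vstack(arrays), axis=0, weights=w)


def classify(scores, threshold: float = 0.5) -> np.ndarray:
    """Binary call: positive iff score >= threshold (threshold in (0, 1))."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def ecdf_rescale(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rank-based rescaling onto [0, 1] via the reference empirical CDF
    (midpoint convention; constant references map to 0.5)."""
    ref = np.sort(np.asarray(reference, dtype=float))
    ref = ref[~np.isnan(ref)]
    v = np.asarray(values, dtype=float)
    lo = np.searchsorted(ref, v, side="left")
    hi = np.searchsorted(ref, v, side="right")
    return (lo + hi) / (2.0 * ref.size)


def biomarker_weighted_vote(model_scores, biomarker_values: pd.DataFrame,
                            weights=None,
                            train_reference: pd.DataFrame | None = None) -> np.ndarray:
    """Combine model probabilities with serum biomarker channels by weighted
    voting.

    Each biomarker column is imputed (missing -> training-split median) and
    rescaled to [0, 1] through the training split's empirical CDF before the
    weighted mean; raw U/mL / ng/mL scales are incommensurate with
    probabilities. ``weights`` has one entry for the model followed by one
    per biomarker column (default equal).
    """
    model_scores = np.asarray(model_scores, dtype=float)
    if train_reference is None:
        train_reference = biomarker_values
    channels = [model_scores]
    for col in biomarker_values.columns:
        ref = train_reference[col].to_numpy(float)
        ref = ref[~np.isnan(ref)]
        if ref.size == 0:
            raise ValueError(f"biomarker column {col!r} is entirely missing")
        v = biomarker_values[col].to_numpy(float).copy()
        v[np.isnan(v)] = np.median(ref)
        channels.append(ecdf_rescale(v, ref))
    return soft_vote(channels, weights)


class VotingEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Soft-voting ensemble over base classifiers with per-model feature
    subsets.

    Parameters
    ----------
    base_learners : list of str or estimators
        One entry per base model (registry names or sklearn classifiers).
    subsets : list of list of str, optional
        Feature columns for each base model; None uses all columns for all.
    weights : array-like, optional
        Non-negative vote weights (normalized internally); default equal.
    threshold : float
        Decision threshold on the combined probability (default 0.5).
    class_weighting : bool
        Inverse-class-frequency loss weights in every base model.
    seed : int
        Random state forwarded to the base learners.

    Attributes
    ----------
    models_ : fitted base models
    subsets_ : resolved per-model feature subsets
    weights_ : normalized vote weights (sum to 1)
    classes_ : ndarray [0, 1]
    """

    def __init__(self, base_learners=("logreg", "rf", "gbdt"), subsets=None,
                 weights=None, threshold: float = 0.5,
                 class_weighting: bool = False, seed: int = 0):
        self.base_learners = base_learners
        self.subsets = subsets
        self.weights = weights
        self.threshold = threshold
        self.class_weighting = class_weighting
        self.seed = seed

    def _resolve_subsets(self, X: pd.DataFrame) -> list[list[str]]:
        if self.subsets is None:
            return [list(X.columns)] * len(self.base_learners)
        if len(self.subsets) != len(self.base_learners):
            raise ValueError("one subset per base learner required")
        for sub in self.subsets:
            if not sub:
                raise ValueError("base-model feature subset is empty")
            missing = set(sub) - set(X.columns)
            if missing:
                raise ValueError(f"subset features not in X: {sorted(missing)[:3]}")
        return [list(s) for s in self.subsets]

    def fit(self, X, y) -> "VotingEnsembleClassifier":
        from .select import _as_frame

        X = _as_frame(X)
        y = np.asarray(y).astype(int)
        self.subsets_ = self._resolve_subsets(X)
        w = (np.ones(len(self.base_learners)) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be >= 0 and not all zero")
        self.weights_ = w / w.sum()
        self.models_ = [
            fit_base(learner, X[sub], y, class_weighting=self.class_weighting,
                     seed=self.seed)
            for learner, sub in zip(self.base_learners, self.subsets_)
        ]
        self.classes_ = np.array([0, 1])
        return self

    def base_scores(self, X) -> list[np.ndarray]:
        from .select import _as_frame

        X = _as_frame(X)
        return [predict_scores(m, X[sub])
                for m, sub in zip(self.models_, self.subsets_)]

    def predict_proba(self, X) -> np.ndarray:
        p1 = soft_vote(self.base_scores(X), self.weights_)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_proba(X)[:, 1], self.threshold)

    def tune_threshold_youden(self, X_val, y_val) -> float:
        """Pick the operating threshold maximizing Youden's J (sens + spec
        - 1) on a validation split; stores and returns it."""
        scores = self.predict_proba(X_val)[:, 1]
        y = np.asarray(y_val).astype(int)
        candidates = np.unique(scores)
        best_t, best_j = 0.5, -np.inf
        for t in candidates:
            pred = scores >= t
            sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
            spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
            j = sens + spec - 1
            if j > best_j:
                best_j, best_t = j, float(t)
        self.threshold = min(max(best_t, 1e-9), 1 - 1e-9)
        return self.threshold


def save_ensemble(model: VotingEnsembleClassifier, directory: str | Path) -> Path:
    """Persist an ensemble: versioned JSON manifest + per-model joblib blobs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "base_learners": [l if isinstance(l, str) else type(l).__name__
                          for l in model.base_learners],
        "subsets": model.subsets_,
        "weights": list(map(float, model.weights_)),
        "threshold": model.threshold,
        "class_weighting": model.class_weighting,
        "seed": model.seed,
        "blobs": [f"model_{i}.joblib" for i in range(len(model.models_))],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, m in enumerate(model.models_):
        joblib.dump(m, directory / f"model_{i}.joblib")
    return directory / "manifest.json"


def load_ensemble(directory: str | Path) -> VotingEnsembleClassifier:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != 1:
        raise ValueError("unsupported model bundle version")
    ens = VotingEnsembleClassifier(
        base_learners=manifest["base_learners"], subsets=manifest["subsets"],
        weights=manifest["weights"], threshold=manifest["threshold"],
        class_weighting=manifest["class_weighting"], seed=manifest["seed"],
    )
    ens.subsets_ = manifest["subsets"]
    ens.weights_ = np.asarray(manifest["weights"], dtype=float)
    ens.models_ = [joblib.load(directory / b) for b in manifest["blobs"]]
    ens.classes_ = np.array([0, 1])
    return ens
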