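"""Feature selection: Mann-Whitney/FDR screening, p-value baseline, and
sequential floating forward selection (SFFS) driven by cross-validated AUC.

SFFS is the wrapper strategy used to curate diagnostic feature subsets:
greedy forward additions (the feature maximizing the CV-AUC objective) with
conditional backward removals whenever dropping a feature strictly improves
the best objective known at that subset size. The selector records a full
add/remove trace so the final subset can be audited and replayed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialTable",
    "SelectionTrace",
    "mannwhitney_fdr",
    "pvalue_select",
    "rank_auc",
    "cv_auc",
    "SFFSSelector",
    "sffs",
    "union_top_models",
]


def _as_frame(X) -> pd.DataFrame:
    from .containers import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


# --------------------------------------------------------------------------
# univariate screening
# --------------------------------------------------------------------------

DifferentialTable = pd.DataFrame  # columns: U, p, p_adj, direction, constant


def mannwhitney_fdr(X, labels) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per feature with Benjamini-Hochberg
    adjustment.

    Exact p-values are used when both groups have <= 8 observations,
    otherwise the tie-corrected normal approximation. Constant features get
    p = 1 and are flagged. ``direction`` is the sign of the positive-group
    median shift.
    """
    df = _as_frame(X)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be non-empty")
    pos = df.loc[y == 1]
    neg = df.loc[y == 0]
    method = "exact" if min(len(pos), len(neg)) <= 8 else "asymptotic"
    out = []
    for col in df.columns:
        a, b = pos[col].to_numpy(float), neg[col].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0 or np.ptp(np.concatenate([a, b])) == 0:
            out.append((col, np.nan, 1.0, 0.0, True))
            continue
        # exact distribution is only valid without ties
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        meth = "exact" if (method == "exact" and no_ties) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=meth)
        direction = float(np.sign(np.median(a) - np.median(b)))
        out.append((col, float(res.statistic), float(res.pvalue), direction, False))
    table = pd.DataFrame(out, columns=["feature", "U", "p", "direction", "constant"])
    table = table.set_index("feature")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table[["U", "p", "p_adj", "direction", "constant"]]


def pvalue_select(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Features with adjusted p < alpha, ordered by (adjusted p, raw p)."""
    sig = table.loc[table["p_adj"] < alpha]
    sig = sig.sort_values(["p_adj", "p"], kind="stable")
    return list(sig.index)


# --------------------------------------------------------------------------
# cross-validated AUC objective
# --------------------------------------------------------------------------

def rank_auc(labels, scores) -> float:
    """AUC via the Mann-Whitney identity (ties counted 1/2)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def _model_scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _effective_folds(y: np.ndarray, folds: int) -> int:
    smallest = int(np.bincount(y.astype(int)).min())
    if smallest < folds:
        warnings.warn(
            f"reducing folds from {folds} to {smallest} (smallest class size)",
            stacklevel=3,
        )
        return max(2, smallest)
    return folds


class _CVObjective:
    """Mean out-of-fold AUC for a column subset; fold layout fixed at
    construction and results cached per subset signature."""

    def __init__(self, X: np.ndarray, y: np.ndarray, learner, folds: int, seed: int):
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=int)
        self.learner = learner
        folds = _effective_folds(self.y, folds)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        self.splits = list(skf.split(self.X, self.y))
        self.cache: dict[frozenset, float] = {}
        self.n_evaluations = 0

    def __call__(self, cols: tuple[int, ...]) -> float:
        key = frozenset(cols)
        if key in self.cache:
            return self.cache[key]
        Xs = self.X[:, list(cols)]
        aucs = []
        for tr, te in self.splits:
            model = clone(self.learner)
            model.fit(Xs[tr], self.y[tr])
            aucs.append(rank_auc(self.y[te], _model_scores(model, Xs[te])))
        val = float(np.mean(aucs))
        self.cache[key] = val
        self.n_evaluations += 1
        return val


def cv_auc(X, labels, learner, folds: int = 10, seed: int = 0) -> float:
    """Mean out-of-fold AUC over a stratified K-fold split (deterministic
    given ``seed``). ``learner`` may be an estimator or a registry name."""
    from .model import make_learner

    df = _as_frame(X)
    if isinstance(learner, str):
        learner = make_learner(learner, seed=seed, probability=False)
    y = np.asarray(labels).astype(int)
    obj = _CVObjective(df.to_numpy(float), y, learner, folds, seed)
    return obj(tuple(range(df.shape[1])))


# --------------------------------------------------------------------------
# SFFS
# --------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Ordered SFFS event log plus the final subset."""

    events: list = field(default_factory=list)  # (step, action, feature, objective)
    final_subset: list = field(default_factory=list)
    learner: str = ""
    folds: int = 10
    seed: int = 0

    def replay(self) -> list[str]:
        """Re-apply the event log; must reproduce ``final_subset``."""
        subset: list[str] = []
        for _, action, feature, _ in self.events:
            if action == "add":
                subset.append(feature)
            elif action == "remove":
                subset.remove(feature)
            else:
                raise ValueError(f"unknown action {action!r}")
        return subset

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"learner": self.learner, "folds": self.folds,
                                 "seed": self.seed,
                                 "final_subset": self.final_subset}) + "\n")
            for step, action, feature, obj in self.events:
                fh.write(json.dumps({"step": step, "action": action,
                                     "feature": feature, "objective": obj}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "SelectionTrace":
        lines = Path(path).read_text().splitlines()
        head = json.loads(lines[0])
        events = [
            (d["step"], d["action"], d["feature"], d["objective"])
            for d in map(json.loads, lines[1:])
        ]
        return cls(events=events, final_subset=head["final_subset"],
                   learner=head["learner"], folds=head["folds"], seed=head["seed"])


class SFFSSelector(BaseEstimator):
    """Sequential floating forward selection with a CV-AUC objective.

    Parameters
    ----------
    learner : str or estimator
        Registry name (``"logreg"``, ``"rf"``, ``"knn"``, ``"svc"``,
        ``"gbdt"``, ...) or any sklearn classifier with
        ``decision_function`` or ``predict_proba``.
    folds : int
        Stratified CV folds for the objective (default 10).
    max_features : int
        Hard cap on the subset size (default 25).
    min_delta : float
        Minimum objective gain for a forward step to be accepted.
    standardize : bool
        Z-score the feature table once before selection (scale-sensitive
        learners; rank-based AUC is unaffected for tree learners).
    backward_min_size : int
        Conditional backward steps are only attempted at subset sizes >=
        this guard (cycling protection).
    seed : int
        Controls the fold layout and any learner randomness.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
    selected_labels_ : list of retained column labels (selection order)
    trace_ : SelectionTrace
    best_objective_ : float
    """

    def __init__(self, learner="logreg", folds: int = 10, max_features: int = 25,
                 min_delta: float = 1e-4, standardize: bool = True,
                 backward_min_size: int = 3, seed: int = 0):
        self.learner = learner
        self.folds = folds
        self.max_features = max_features
        self.min_delta = min_delta
        self.standardize = standardize
        self.backward_min_size = backward_min_size
        self.seed = seed

    def fit(self, X, y) -> "SFFSSelector":
        from .model import make_learner

        df = _as_frame(X)
        y = np.asarray(y).astype(int)
        if df.shape[1] == 0:
            raise ValueError("empty feature matrix")
        if self.max_features > df.shape[1]:
            raise ValueError("max_features exceeds feature count")
        learner = (make_learner(self.learner, seed=self.seed, probability=False)
                   if isinstance(self.learner, str) else clone(self.learner))
        Xv = df.to_numpy(float)
        if self.standardize:
            mu = Xv.mean(axis=0)
            sd = Xv.std(axis=0)
            sd[sd == 0] = 1.0
            Xv = (Xv - mu) / sd
        objective = _CVObjective(Xv, y, learner, self.folds, self.seed)
        cols = list(df.columns)

        current: list[int] = []
        best_at_size: dict[int, float] = {0: -np.inf}
        best_seen = (-np.inf, [])
        events = []
        step = 0
        while len(current) < self.max_features:
            # forward: best single addition
            remaining = [j for j in range(len(cols)) if j not in current]
            if not remaining:
                break
            fwd = [(objective(tuple(current + [j])), j) for j in remaining]
            obj_fwd, j_star = max(fwd, key=lambda t: (t[0], -t[1]))
            gain = obj_fwd - best_at_size.get(len(current), -np.inf)
            if current and gain <= self.min_delta:
                break
            current.append(j_star)
            step += 1
            events.append((step, "add", cols[j_star], obj_fwd))
            k = len(current)
            best_at_size[k] = max(best_at_size.get(k, -np.inf), obj_fwd)
            if obj_fwd > best_seen[0]:
                best_seen = (obj_fwd, list(current))

            # conditional backward: drop any feature whose exclusion strictly
            # improves the best objective known at the smaller size
            while len(current) >= self.backward_min_size:
                back = [
                    (objective(tuple(c for c in current if c != j)), j)
                    for j in current[:-1]  # never immediately undo the add
                ]
                obj_back, j_drop = max(back, key=lambda t: (t[0], -t[1]))
                if obj_back <= best_at_size.get(len(current) - 1, -np.inf) + self.min_delta:
                    break
                current.remove(j_drop)
                step += 1
                events.append((step, "remove", cols[j_drop], obj_back))
                best_at_size[len(current)] = obj_back
                if obj_back > best_seen[0]:
                    best_seen = (obj_back, list(current))

        # report the best subset seen during the search
        final_idx = best_seen[1]
        self.best_objective_ = best_seen[0]
        self.selected_labels_ = [cols[j] for j in final_idx]
        self.support_ = np.zeros(len(cols), dtype=bool)
        self.support_[final_idx] = True
        learner_name = self.learner if isinstance(self.learner, str) else type(learner).__name__
        trace_events = events
        # truncate the event log at the step where the best subset was reached
        self.trace_ = SelectionTrace(
            events=_truncate_to_subset(trace_events, self.selected_labels_),
            final_subset=list(self.selected_labels_),
            learner=learner_name, folds=self.folds, seed=self.seed,
        )
        self.n_evaluations_ = objective.n_evaluations
        return self

    def transform(self, X):
        df = _as_frame(X)
        return df[self.selected_labels_]

    def get_support(self) -> np.ndarray:
        return self.support_


def _truncate_to_subset(events: list, target: list[str]) -> list:
    """Shortest event prefix whose replay equals ``target`` (as a set)."""
    subset: list[str] = []
    want = set(target)
    for i, (_, action, feature, _) in enumerate(events):
        if action == "add":
            subset.append(feature)
        else:
            subset.remove(feature)
        if set(subset) == want:
            return events[: i + 1]
    return events


def sffs(X, labels, learner="logreg", folds: int = 10, max_features: int = 25,
         min_delta: float = 1e-4, seed: int = 0, **kwargs) -> SelectionTrace:
    """Functional wrapper over :class:`SFFSSelector`; returns the trace."""
    sel = SFFSSelector(learner=learner, folds=folds, max_features=max_features,
                       min_delta=min_delta, seed=seed, **kwargs)
    sel.fit(X, labels)
    return sel.trace_


def union_top_models(traces: list[SelectionTrace], ranking: list[float],
                     top_k: int = 3) -> list[str]:
    """Union of the final subsets of the ``top_k`` traces by ranking score
    (e.g. validation AUC); ties broken by learner name. Returns the union
    sorted by feature label for determinism."""
    if top_k > len(traces):
        raise ValueError("top_k exceeds number of traces")
    if len(traces) != len(ranking):
        raise ValueError("traces and ranking must align")
    order = sorted(range(len(traces)),
                   key=lambda i: (-ranking[i], traces[i].learner))
    union: set[str] = set()
    for i in order[:top_k]:
        union.update(traces[i].final_subset)
    return sorted(union)
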