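"""Diagnostic evaluation: ROC/AUC with DeLong confidence intervals,
confusion-matrix metrics, decision-curve analysis, subgroup rates and
matched operating points.

AUC is computed by the Mann-Whitney identity (probability a random positive
outscores a random negative, ties counted 1/2). Confidence intervals use
DeLong's placement-based variance by default with a stratified-bootstrap
alternative. Percentages are reported to two decimals, rounding half-up.
Net benefit follows the standard decision-curve definition
``NB(pt) = TP/n - (FP/n) * pt / (1 - pt)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "round_half_up",
    "roc_auc",
    "auc_ci",
    "confusion_matrix_from_predictions",
    "confusion_metrics",
    "decision_curve",
    "subgroup_metrics",
    "matched_operating_point",
    "evaluate_predictions",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero upward (the convention used for
    reported percentages), unlike numpy's banker's rounding."""
    factor = 10.0 ** decimals
    return float(np.floor(x * factor + 0.5) / factor)


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.empty(m)
    v01 = np.empty(n)
    order = np.argsort(neg)
    sneg = neg[order]
    for i, x in enumerate(pos):
        lo = np.searchsorted(sneg, x, side="left")
        hi = np.searchsorted(sneg, x, side="right")
        v10[i] = (lo + 0.5 * (hi - lo)) / n
    order = np.argsort(pos)
    spos = pos[order]
    for j, x in enumerate(neg):
        lo = np.searchsorted(spos, x, side="left")
        hi = np.searchsorted(spos, x, side="right")
        v01[j] = (m - hi + 0.5 * (hi - lo)) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong",
           n_boot: int = 2000, seed: int = 0) -> tuple[float, float, float]:
    """AUC with a confidence interval, clipped to [0, 1].

    ``method="delong"`` (default) uses the placement-variance normal
    interval; ``method="bootstrap"`` uses a stratified bootstrap. Degenerate
    DeLong variance with a non-boundary AUC falls back to the bootstrap with
    a warning. Returns ``(auc, lower, upper)``.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    z = norm.ppf(0.5 + level / 2.0)
    if method == "delong":
        auc, var = _delong_variance(s, y)
        if var == 0.0 and 0.0 < auc < 1.0:
            warnings.warn("degenerate DeLong variance; falling back to bootstrap")
            return auc_ci(s, y, level, method="bootstrap", n_boot=n_boot, seed=seed)
        half = z * np.sqrt(var)
        return auc, max(0.0, auc - half), min(1.0, auc + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([
                rng.choice(pos, size=pos.size, replace=True),
                rng.choice(neg, size=neg.size, replace=True),
            ])
            stats[b] = roc_auc(s[idx], y[idx])
        lo, hi = np.quantile(stats, [(1 - level) / 2, 0.5 + level / 2])
        return roc_auc(s, y), float(max(0.0, lo)), float(min(1.0, hi))
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class ConfusionMatrix:
    """2x2 diagnostic confusion matrix."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


def confusion_matrix_from_predictions(pred, labels) -> ConfusionMatrix:
    y = np.asarray(labels).astype(int)
    p = np.asarray(pred).astype(int)
    return ConfusionMatrix(
        tp=int(((p == 1) & (y == 1)).sum()), fp=int(((p == 1) & (y == 0)).sum()),
        fn=int(((p == 0) & (y == 1)).sum()), tn=int(((p == 0) & (y == 0)).sum()),
    )


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Sens/spec/accuracy/PPV/NPV/F1 in percent (unrounded floats).

    Rates with zero denominators are reported as NaN (flagged missing,
    never coerced to 0).
    """
    def rate(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    sens = rate(cm.tp, cm.tp + cm.fn)
    spec = rate(cm.tn, cm.tn + cm.fp)
    acc = rate(cm.tp + cm.tn, cm.n)
    ppv = rate(cm.tp, cm.tp + cm.fp)
    npv = rate(cm.tn, cm.tn + cm.fn)
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "ppv": ppv, "npv": npv, "f1": f1}


@dataclass
class EvalReport:
    """Full diagnostic evaluation at one operating threshold."""

    auc: float
    ci: tuple[float, float]
    threshold: float
    cm: ConfusionMatrix
    metrics: dict = field(default_factory=dict)
    subgroups: pd.DataFrame | None = None

    def rounded_metrics(self, decimals: int = 2) -> dict:
        return {k: round_half_up(v, decimals) if not np.isnan(v) else float("nan")
                for k, v in self.metrics.items()}

    def to_json(self) -> str:
        payload = {
            "auc": self.auc, "ci_lower": self.ci[0], "ci_upper": self.ci[1],
            "threshold": self.threshold,
            "confusion": {"tp": self.cm.tp, "fp": self.cm.fp,
                          "fn": self.cm.fn, "tn": self.cm.tn},
            "metrics_percent": self.rounded_metrics(),
        }
        if self.subgroups is not None:
            payload["subgroups"] = json.loads(self.subgroups.to_json(orient="index"))
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        m = self.rounded_metrics()
        lines = [
            f"AUC {self.auc:.3f} (95% CI {self.ci[0]:.3f}-{self.ci[1]:.3f})",
            f"threshold {self.threshold:.3f}   "
            f"TP={self.cm.tp} FP={self.cm.fp} FN={self.cm.fn} TN={self.cm.tn}",
            "  ".join(f"{k} {v:.2f}%" for k, v in m.items()),
        ]
        return "\n".join(lines)


def evaluate_predictions(scores, labels, threshold: float = 0.5,
                         ci_method: str = "delong", seed: int = 0) -> EvalReport:
    """Score a continuous predictor at an operating threshold: AUC + CI,
    confusion matrix and all rate metrics."""
    from .model import classify

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc, lo, hi = auc_ci(scores, y, method=ci_method, seed=seed)
    cm = confusion_matrix_from_predictions(classify(scores, threshold), y)
    return EvalReport(auc=auc, ci=(lo, hi), threshold=threshold, cm=cm,
                      metrics=confusion_metrics(cm))


def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Decision-curve analysis.

    At each threshold probability ``pt`` the model classifies by
    ``score >= pt`` and ``NB = TP/n - (FP/n) * pt/(1-pt)``; the treat-all
    policy calls everyone positive, treat-none is identically zero.
    Thresholds equal to 1 are excluded (division by zero).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.601, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n = y.size
    prevalence = (y == 1).sum() / n
    rows = []
    for pt in thresholds:
        pred = s >= pt
        tp = ((pred) & (y == 1)).sum() / n
        fp = ((pred) & (y == 0)).sum() / n
        odds = pt / (1.0 - pt)
        rows.append((pt, tp - fp * odds,
                     prevalence - (1 - prevalence) * odds, 0.0))
    return pd.DataFrame(rows, columns=["pt", "nb_model", "nb_all", "nb_none"])


def subgroup_metrics(pred, labels, meta: pd.DataFrame, by: str) -> pd.DataFrame:
    """Per-level detection rates: sensitivity over the positives of a level
    and specificity over its negatives, with level counts. Empty levels are
    kept and flagged (NaN), never dropped silently."""
    p = np.asarray(pred).astype(int)
    y = np.asarray(labels).astype(int)
    if by not in meta.columns:
        raise ValueError(f"subgroup column {by!r} not in metadata")
    levels = meta[by].astype(str).to_numpy()
    rows = []
    for level in pd.unique(levels):
        mask = levels == level
        n_pos = int((y[mask] == 1).sum())
        n_neg = int((y[mask] == 0).sum())
        sens = (100.0 * (p[mask & (y == 1)] == 1).mean()) if n_pos else float("nan")
        spec = (100.0 * (p[mask & (y == 0)] == 0).mean()) if n_neg else float("nan")
        rows.append((level, n_pos + n_neg, n_pos, n_neg, sens, spec))
    return pd.DataFrame(
        rows, columns=["level", "n", "n_pos", "n_neg",
                       "sensitivity", "specificity"]
    ).set_index("level")


def matched_operating_point(reference_scores, reference_labels,
                            target_specificity: float | None = None,
                            target_sensitivity: float | None = None) -> tuple[float, float]:
    """Operating threshold matched to a requested specificity or sensitivity.

    For a specificity target, returns the smallest threshold whose achieved
    specificity is >= the request, paired with the sensitivity there; for a
    sensitivity target, the largest threshold keeping sensitivity >= the
    request, paired with the specificity. Targets are fractions in [0, 1].
    Raises with the achievable range when the target cannot be met.
    """
    if (target_specificity is None) == (target_sensitivity is None):
        raise ValueError("provide exactly one of target_specificity/target_sensitivity")
    s = np.asarray(reference_scores, dtype=float)
    y = np.asarray(reference_labels).astype(int)
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    cand = np.concatenate([[s.min() - 1.0], np.unique(s), [s.max() + 1.0]])
    sens = np.array([((s >= t) & (y == 1)).sum() / n1 for t in cand])
    spec = np.array([((s < t) & (y == 0)).sum() / n0 for t in cand])
    if target_specificity is not None:
        ok = np.flatnonzero(spec >= target_specificity)
        if ok.size == 0:
            raise ValueError(
                f"specificity {target_specificity} unachievable; range "
                f"[{spec.min():.3f}, {spec.max():.3f}]")
        k = ok[0]  # candidates are in increasing threshold order
        return float(cand[k]), float(sens[k])
    ok = np.flatnonzero(sens >= target_sensitivity)
    if ok.size == 0:
        raise ValueError(
            f"sensitivity {target_sensitivity} unachievable; range "
            f"[{sens.min():.3f}, {sens.max():.3f}]")
    k = ok[-1]  # sens is non-increasing in threshold
    return float(cand[k]), float(spec[k])
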