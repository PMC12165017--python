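"""Cohort-level statistics: covariate-adjusted odds ratios (Wald inference),
propensity matching, Spearman correlation networks, and machine-learning
power analysis.

The logistic model is fitted by Newton-Raphson maximum likelihood with
complete-separation detection; odds ratios are ``exp(coef)`` with Wald
confidence intervals ``exp(coef +- z * SE)``. Matching is greedy 1:1
nearest-neighbor without replacement on the logit propensity within a
caliper (default 0.2 propensity-logit SDs). Power analysis repeatedly
subsamples n per group, fits a classifier on 70% and tests whether the
held-out AUC exceeds 0.5 by a one-sided Mann-Whitney test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ORResult",
    "CorrelationNetwork",
    "logistic_or",
    "covariate_match",
    "spearman_network",
    "ml_power_analysis",
]


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                     tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson ML fit; returns (coef, standard errors)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Hessian in logistic fit") from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > 30:
            raise RuntimeError(
                "diverging logistic fit (quasi-separation: a fitted log-odds "
                "exceeded 30)")
        if np.max(np.abs(delta)) < tol:
            eta = np.clip(X @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            H = (X * w[:, None]).T @ X
            se = np.sqrt(np.diag(np.linalg.inv(H)))
            return beta, se
    raise RuntimeError(f"logistic fit did not converge in {max_iter} iterations")


def _check_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        x1, x0 = X[y == 1, j], X[y == 0, j]
        if x1.size and x0.size and (x1.min() > x0.max() or x1.max() < x0.min()):
            raise ValueError(f"complete separation by variable {name!r}")


@dataclass
class ORResult:
    """Odds ratio of one predictor with Wald inference."""

    predictor: str
    oddsratio: float
    ci: tuple[float, float]
    p: float
    coef: float
    se: float
    covariates: list = field(default_factory=list)
    cohort: str = "before-matching"

    def as_row(self) -> dict:
        return {"predictor": self.predictor, "OR": self.oddsratio,
                "ci_lower": self.ci[0], "ci_upper": self.ci[1],
                "wald_p": self.p, "covariates": "+".join(self.covariates),
                "cohort": self.cohort}


def logistic_or(outcome, predictor, covariates: pd.DataFrame | None = None,
                predictor_name: str = "predictor", max_iter: int = 100,
                tol: float = 1e-8, level: float = 0.95,
                cohort: str = "before-matching") -> ORResult:
    """Covariate-adjusted odds ratio of ``predictor`` for a binary outcome.

    Fits ``logit P(outcome) = b0 + b1 predictor + covariates`` by
    Newton-Raphson; returns OR = exp(b1) with the Wald interval and p-value.
    Complete separation and non-convergence raise informative errors.
    """
    y = np.asarray(outcome).astype(float)
    x = np.asarray(predictor, dtype=float)
    cols = [np.ones_like(x), x]
    names = ["intercept", predictor_name]
    cov_names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(float))
            names.append(str(c))
            cov_names.append(str(c))
    X = np.column_stack(cols)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few observations for the number of covariates")
    _check_separation(X[:, 1:], y, names[1:])
    beta, se = _newton_logistic(X, y, max_iter=max_iter, tol=tol)
    z = norm.ppf(0.5 + level / 2.0)
    b1, s1 = beta[1], se[1]
    wald_z = b1 / s1
    p = 2.0 * norm.sf(abs(wald_z))
    return ORResult(
        predictor=predictor_name, oddsratio=float(np.exp(b1)),
        ci=(float(np.exp(b1 - z * s1)), float(np.exp(b1 + z * s1))),
        p=float(p), coef=float(b1), se=float(s1),
        covariates=cov_names, cohort=cohort,
    )


def covariate_match(meta: pd.DataFrame, treatment, covariates: list[str],
                    caliper: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbor propensity matching without replacement.

    ``treatment`` is a column name or boolean array marking the case arm.
    Covariates are standardized, a logistic propensity model is fitted, and
    each case is matched (in a seeded random order) to the nearest unused
    control within ``caliper`` SDs of the logit propensity. Unmatched cases
    are dropped; the returned frame contains both matched arms.
    """
    if isinstance(treatment, str):
        t = meta[treatment].astype(bool).to_numpy()
    else:
        t = np.asarray(treatment).astype(bool)
    if t.sum() == 0 or (~t).sum() == 0:
        raise ValueError("both arms must be non-empty")
    Z = meta[covariates].astype(float).to_numpy()
    mu, sd = Z.mean(axis=0), Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    X = np.column_stack([np.ones(len(Z)), Z])
    beta, _ = _newton_logistic(X, t.astype(float))
    logit = X @ beta
    width = caliper * logit.std(ddof=1)

    rng = np.random.default_rng(seed)
    cases = rng.permutation(np.flatnonzero(t))
    controls = np.flatnonzero(~t)
    free = np.ones(controls.size, dtype=bool)
    pairs = []
    for i in cases:
        avail = controls[free]
        if avail.size == 0:
            break
        d = np.abs(logit[avail] - logit[i])
        k = int(np.argmin(d))
        if d[k] <= width:
            pairs.append((i, avail[k]))
            free[np.flatnonzero(free)[k]] = False
    if not pairs:
        raise ValueError("no matches within caliper")
    idx = np.concatenate([[i for i, _ in pairs], [j for _, j in pairs]])
    return meta.iloc[np.sort(idx)].copy()


@dataclass
class CorrelationNetwork:
    """Spearman correlation network over selected features."""

    nodes: list[str]
    edges: pd.DataFrame        # feature_a, feature_b, rho, p, p_adj, sign
    undefined: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def spearman_network(X: pd.DataFrame, fdr_alpha: float = 0.05) -> CorrelationNetwork:
    """Pairwise Spearman correlations with BH-adjusted p-values; edges are
    retained at adjusted p < ``fdr_alpha``. Constant features have no
    defined correlation and are flagged in ``undefined``."""
    if len(X) < 3:
        raise ValueError("need at least 3 samples")
    cols = list(X.columns)
    constant = [c for c in cols if X[c].nunique(dropna=True) <= 1]
    usable = [c for c in cols if c not in constant]
    rows = []
    if len(usable) >= 2:
        rho, p = spearmanr(X[usable].to_numpy(float))
        if np.ndim(rho) == 0:  # scipy returns scalars for exactly 2 columns
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
        iu = np.triu_indices(len(usable), k=1)
        p_adj = multipletests(p[iu], method="fdr_bh")[1]
        for (a, b), r, pv, pa in zip(zip(*iu), rho[iu], p[iu], p_adj):
            if pa < fdr_alpha:
                rows.append((usable[a], usable[b], float(r), float(pv),
                             float(pa), int(np.sign(r))))
    edges = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho",
                                        "p", "p_adj", "sign"])
    return CorrelationNetwork(nodes=cols, edges=edges, undefined=constant)


def ml_power_analysis(X, labels, sizes, B: int = 50, alpha: float = 0.05,
                      seed: int = 0, learner: str = "logreg",
                      smooth: bool = True) -> pd.DataFrame:
    """Machine-learning power analysis over a per-group sample-size grid.

    For each n: repeat ``B`` times — subsample n per group, split 70/30
    stratified, fit the learner on the training part, and test whether the
    held-out scores separate the classes (one-sided Mann-Whitney on the
    positive vs negative scores) at ``alpha``. Power is the fraction of
    significant repeats, optionally made monotone in n by isotonic
    regression (reported as ``power_smoothed``).
    """
    from .model import make_learner, predict_scores
    from .select import _as_frame

    if B < 20:
        warnings.warn("B < 20 gives an unstable power estimate")
    df = _as_frame(X)
    y = np.asarray(labels).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    Xv = df.to_numpy(float)
    rows = []
    for n in sizes:
        if n > min(pos.size, neg.size):
            raise ValueError(f"size {n} exceeds available per-group n")
        hits = 0
        n_train = int(round(0.7 * n))
        for _ in range(B):
            pos_take = rng.choice(pos, size=n, replace=False)
            neg_take = rng.choice(neg, size=n, replace=False)
            train = np.concatenate([pos_take[:n_train], neg_take[:n_train]])
            test = np.concatenate([pos_take[n_train:], neg_take[n_train:]])
            model = make_learner(learner, seed=seed, probability=False,
                                 with_scaler=True)
            model.fit(Xv[train], y[train])
            s = (model.decision_function(Xv[test])
                 if hasattr(model, "decision_function")
                 else predict_scores(model, Xv[test]))
            s_pos = s[y[test] == 1]
            s_neg = s[y[test] == 0]
            if s_pos.size and s_neg.size:
                pval = mannwhitneyu(s_pos, s_neg, alternative="greater").pvalue
                hits += pval < alpha
        rows.append((int(n), hits / B))
    out = pd.DataFrame(rows, columns=["n_per_group", "power"])
    if smooth and len(out) > 1:
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(y_min=0.0, y_max=1.0)
        out["power_smoothed"] = iso.fit_transform(out["n_per_group"], out["power"])
    else:
        out["power_smoothed"] = out["power"]
    return out
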