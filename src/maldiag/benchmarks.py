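"""Reproducible benchmark runs used for validation of the whole pipeline.

Each function performs one self-contained study on synthetic data (or on
printed split layouts) and returns plain numbers. They are shared by the
test suite and the results-reproduction script so that both always measure
the same computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthgen as sg
from .evaluate import ConfusionMatrix, confusion_metrics, round_half_up
from .model import VotingEnsembleClassifier
from .preprocess import SpectrumPreprocessor, detect_peaks, smooth, subtract_baseline
from .qc import qc_cv_report
from .select import SFFSSelector, rank_auc, union_top_models

__all__ = [
    "reconstruct_confusion",
    "confusion_reconstruction_report",
    "planted_recovery_run",
    "null_ensemble_auc",
    "peak_recovery_run",
    "qc_stability_run",
]


def reconstruct_confusion(n_pos: int, n_neg: int, sens_pct: float,
                          spec_pct: float) -> ConfusionMatrix:
    """Unique integer confusion matrix consistent with printed class sizes
    and sensitivity/specificity (two-decimal percents).

    Scans all integer TP/TN values and requires exactly one match each.
    """
    tps = [tp for tp in range(n_pos + 1)
           if round_half_up(100.0 * tp / n_pos) == sens_pct]
    tns = [tn for tn in range(n_neg + 1)
           if round_half_up(100.0 * tn / n_neg) == spec_pct]
    if len(tps) != 1 or len(tns) != 1:
        raise ValueError(
            f"printed rates do not identify a unique matrix "
            f"(TP candidates {tps}, TN candidates {tns})")
    tp, tn = tps[0], tns[0]
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def confusion_reconstruction_report() -> dict:
    """Derived confusion metrics for the published validation and test
    splits (72/164 and 71/163 with their printed sens/spec)."""
    out = {}
    for tag, (n_pos, n_neg, sens, spec) in {
        "validation": (72, 164, 83.33, 74.39),
        "test": (71, 163, 81.69, 74.23),
    }.items():
        cm = reconstruct_confusion(n_pos, n_neg, sens, spec)
        m = confusion_metrics(cm)
        out[tag] = {
            "matrix": (cm.tp, cm.fp, cm.fn, cm.tn),
            "ppv": round_half_up(m["ppv"]),
            "npv": round_half_up(m["npv"]),
            "accuracy": round_half_up(m["accuracy"]),
        }
    return out


def planted_recovery_run(seed: int, n_per_group: int = 150, n_noise: int = 200,
                         n_informative: int = 10, log2fc: float = 1.0,
                         learners=("logreg", "knn", "svc_linear"),
                         folds: int = 5, max_features: int = 25,
                         top_k: int = 3) -> dict:
    """One full selection+ensemble study on a planted two-class cohort.

    Returns the fraction of planted features recovered by the union of the
    top-k SFFS subsets and the held-out (30%) ensemble AUC.
    """
    X, y, informative = sg.simulate_classification_matrix(
        n_per_group, n_noise, n_informative, seed=seed, log2fc=log2fc)
    X = np.log(X)
    rng = np.random.default_rng(seed + 1)
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    n_tr = int(round(0.7 * n_per_group))
    train = np.concatenate([pos[:n_tr], neg[:n_tr]])
    test = np.concatenate([pos[n_tr:], neg[n_tr:]])

    traces, ranking = [], []
    for learner in learners:
        sel = SFFSSelector(learner=learner, folds=folds,
                           max_features=max_features, seed=seed)
        sel.fit(X.iloc[train], y[train])
        traces.append(sel.trace_)
        ranking.append(sel.best_objective_)
    union = union_top_models(traces, ranking, top_k=min(top_k, len(traces)))
    recovery = len(set(union) & set(informative)) / len(informative)

    ens = VotingEnsembleClassifier(
        base_learners=list(learners),
        subsets=[t.final_subset for t in traces], seed=seed)
    ens.fit(X.iloc[train], y[train])
    auc = rank_auc(y[test], ens.predict_proba(X.iloc[test])[:, 1])
    return {"recovery": recovery, "ensemble_auc": auc,
            "union_size": len(union)}


def null_ensemble_auc(seed: int, n_per_group: int = 100,
                      n_features: int = 50,
                      learners=("logreg", "knn", "svc_linear")) -> float:
    """Held-out ensemble AUC with zero planted effect (should hover at 0.5)."""
    X, y, _ = sg.simulate_classification_matrix(
        n_per_group, n_features, 0, seed=seed, log2fc=0.0)
    X = np.log(X)
    rng = np.random.default_rng(seed + 1)
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    n_tr = int(round(0.7 * n_per_group))
    train = np.concatenate([pos[:n_tr], neg[:n_tr]])
    test = np.concatenate([pos[n_tr:], neg[n_tr:]])
    ens = VotingEnsembleClassifier(base_learners=list(learners), seed=seed)
    ens.fit(X.iloc[train], y[train])
    return rank_auc(y[test], ens.predict_proba(X.iloc[test])[:, 1])


def peak_recovery_run(seed: int, n_planted_spectra: int = 5,
                      n_noise_spectra: int = 20, n_peaks: int = 200,
                      amplitude: float = 20.0, grid_points: int = 65536) -> dict:
    """Peak-detection quality: recovery of planted peaks at ``amplitude`` x
    the noise floor and false peaks per pure-noise spectrum at S/N > 5."""
    grid = sg.default_grid(grid_points)
    rng = np.random.default_rng(seed)
    hits = planted = 0
    for k in range(n_planted_spectra):
        r = np.random.default_rng(seed * 1000 + k)
        centers = np.sort(r.uniform(70, 345, n_peaks))
        widths = r.uniform(0.008, 0.022, n_peaks)
        y = np.full(grid.size, 6.0)
        for c, w in zip(centers, widths):
            lo, hi = np.searchsorted(grid, [c - 5 * w, c + 5 * w])
            y[lo:hi] += amplitude * np.exp(-0.5 * ((grid[lo:hi] - c) / w) ** 2)
        y = np.clip(y + r.normal(0, 1.0, grid.size), 0, None)
        spec = sg.RawSpectrum(mz=grid, intensity=y)
        peaks = detect_peaks(subtract_baseline(smooth(spec, 3)), snr_min=5)
        d = np.min(np.abs(centers[:, None] - peaks.mz[None, :]), axis=1)
        hits += int((d < 0.05).sum())
        planted += n_peaks
    false = 0
    for k in range(n_noise_spectra):
        r = np.random.default_rng(seed * 2000 + k)
        y = np.clip(6.0 + r.normal(0, 1.0, grid.size), 0, None)
        spec = sg.RawSpectrum(mz=grid, intensity=y)
        false += len(detect_peaks(subtract_baseline(smooth(spec, 3)), snr_min=5))
    return {"recovery": hits / planted,
            "false_per_spectrum": false / n_noise_spectra}


def qc_stability_run(seed: int, n_per_group: int = 14, n_batches: int = 4,
                     qc_per_batch: int = 3, n_strong: int = 650,
                     n_weak: int = 150) -> dict:
    """Scaled render-and-preprocess study: surviving feature count and QC
    CVs through the full spectral chain."""
    cfg = sg.CohortConfig.small(n_per_group, n_batches, qc_per_batch)
    meta = sg.generate_cohort(cfg, seed=seed)
    panel = sg.generate_panel(n_strong, n_weak, seed=seed + 1)
    effects = sg.default_effects(panel, seed=seed + 2)
    spectra = sg.generate_spectra(meta, panel, effects, seed=seed + 3,
                                  replicates=3)
    # workflow stability is assessed per measurement (spot level), before
    # replicate averaging collapses the spot-to-spot variance
    pre = SpectrumPreprocessor(collapse_replicates=False)
    fm = pre.transform(spectra)
    report = qc_cv_report(fm, meta)
    return {
        "n_features": fm.n_features,
        "qc_cv_all_batches": float(report.overall.mean()),
        "qc_cv_intra_batch_mean": float(report.intra_batch.mean().mean()),
    }
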