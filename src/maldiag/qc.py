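"""Quality-control stability reporting and CV-based feature exclusion.

Pooled QC aliquots are measured in every detection batch; their per-feature
coefficients of variation (CV = 100 x sd/mean, sample sd with the n-1
denominator) quantify technical stability. Intra-batch CVs (within one
batch's QC replicates) are reported per batch; the inter-batch CV is
computed over the batch-mean QC intensities. Feature exclusion uses the
all-QC-replicate CV (the single-number criterion): features whose QC CV
exceeds 25% are dropped. The filter is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = ["QCReport", "cv", "qc_cv_report", "filter_by_qc_cv", "QCCVFilter"]


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (sample sd,
    n-1 denominator). Requires n >= 2 and a nonzero mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class QCReport:
    """Per-feature QC CVs: intra-batch (per batch), inter-batch, overall."""

    intra_batch: pd.DataFrame        # batches x features, CV %
    inter_batch: pd.Series           # per feature, CV over batch means, %
    overall: pd.Series               # per feature, CV over all QC rows, %

    @property
    def mean_intra_batch(self) -> pd.Series:
        """Feature-averaged intra-batch CV per batch (%)."""
        return self.intra_batch.mean(axis=1)

    @property
    def mean_inter_batch(self) -> float:
        """Inter-batch CV averaged over features (%)."""
        return float(self.inter_batch.mean())

    def to_csv(self, path) -> None:
        out = self.intra_batch.T.add_prefix("intra_cv_batch_")
        out["inter_batch_cv"] = self.inter_batch
        out["overall_cv"] = self.overall
        out.to_csv(path, index_label="feature")


def _qc_rows(fm: FeatureMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    qc_ids = set(meta.loc[meta["is_qc"], "sample_id"])
    idx = fm.values.index
    if "sample_id" in (idx.names or []):
        sample_ids = idx.get_level_values("sample_id")
    else:
        sample_ids = idx
    mask = np.asarray([sid in qc_ids for sid in sample_ids])
    return fm.values.loc[mask]


def qc_cv_report(fm: FeatureMatrix, meta: pd.DataFrame) -> QCReport:
    """Compute the QC stability report from the QC rows of a feature matrix.

    ``meta`` supplies ``is_qc`` flags and ``batch_id`` per sample. Batches
    with fewer than two QC rows are skipped for intra-batch CVs; with a
    single batch the inter-batch CV is flagged missing (NaN).
    """
    qc = _qc_rows(fm, meta)
    if qc.empty:
        raise ValueError("no QC rows in feature matrix")
    batch_of = meta.set_index("sample_id")["batch_id"]
    sample_ids = (qc.index.get_level_values("sample_id")
                  if "sample_id" in (qc.index.names or []) else qc.index)
    batches = batch_of.reindex(sample_ids).to_numpy()

    intra = {}
    batch_means = {}
    for b in np.unique(batches):
        block = qc.loc[batches == b]
        batch_means[b] = block.mean(axis=0)
        if len(block) >= 2:
            m = block.mean(axis=0)
            s = block.std(axis=0, ddof=1)
            intra[b] = 100.0 * s / m.replace(0, np.nan)
    intra_df = pd.DataFrame(intra).T
    intra_df.index.name = "batch_id"

    bm = pd.DataFrame(batch_means).T
    if len(bm) >= 2:
        inter = 100.0 * bm.std(axis=0, ddof=1) / bm.mean(axis=0).replace(0, np.nan)
    else:
        inter = pd.Series(np.nan, index=fm.values.columns)

    overall = 100.0 * qc.std(axis=0, ddof=1) / qc.mean(axis=0).replace(0, np.nan)
    return QCReport(intra_batch=intra_df, inter_batch=inter, overall=overall)


def filter_by_qc_cv(fm: FeatureMatrix, report: QCReport, max_cv: float = 25.0,
                    which: str = "overall") -> FeatureMatrix:
    """Drop features whose QC CV is strictly higher than ``max_cv`` percent.

    ``which`` selects the criterion CV: ``"overall"`` (all QC replicates,
    default) or ``"inter"`` (CV over batch means). Features at exactly
    ``max_cv`` are retained; NaN CVs (e.g. single-batch inter CV) retain
    the feature.
    """
    crit = report.overall if which == "overall" else report.inter_batch
    missing = [c for c in fm.values.columns if c not in crit.index]
    if missing:
        raise ValueError(f"QC report does not cover features: {missing[:3]}...")
    crit = crit.reindex(fm.values.columns)
    keep = fm.values.columns[~(crit > max_cv)]
    out = fm.subset(keep)
    out.qc_cv = crit[keep]
    return out


class QCCVFilter:
    """sklearn-style transformer applying the QC CV exclusion to a feature
    table (fit learns the per-feature QC CVs; transform drops columns)."""

    def __init__(self, max_cv: float = 25.0, which: str = "overall"):
        self.max_cv = max_cv
        self.which = which

    def get_params(self, deep: bool = True) -> dict:
        return {"max_cv": self.max_cv, "which": self.which}

    def set_params(self, **params) -> "QCCVFilter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, fm: FeatureMatrix, meta: pd.DataFrame) -> "QCCVFilter":
        self.report_ = qc_cv_report(fm, meta)
        crit = (self.report_.overall if self.which == "overall"
                else self.report_.inter_batch)
        self.support_ = ~(crit > self.max_cv)
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        return filter_by_qc_cv(fm, self.report_, self.max_cv, self.which)
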