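"""Synthetic saliva-fingerprint study generator.

This module emulates the statistical structure of a multicenter salivary
MALDI-TOF metabolic-fingerprint screening study of lung cancer: a cohort of
healthy controls (HC), benign lung disease (BD) and lung cancer (LC) donors
with realistic demographics; a panel of reproducible m/z peak features; and
per-sample mass spectra with log-normal peak amplitudes, multiplicative batch
and replicate (spot) effects, pooled quality-control (QC) samples measured in
every detection batch, and a planted subset of class-informative features.

Two levels of fidelity are provided:

* :func:`simulate_feature_matrix` draws peak *amplitudes* directly — the
  ground truth the preprocessing chain is supposed to recover — which makes
  downstream selection/modeling stages testable in milliseconds.
* :func:`generate_spectrum` renders a full profile spectrum (baseline +
  Gaussian peaks + additive noise) on a 65,536-point grid over m/z 66-350,
  exercising the preprocessing chain end to end.

Both levels share one amplitude model, so preprocessing the rendered spectra
recovers (up to TIC scaling) the fast-path matrix.

Amplitude model, natural-log scale, sample i / feature j / replicate r::

    log A_ijr = mu_j                          (panel base amplitude)
              + ln(2) * log2fc_j * 1[i in LC] (planted class effect)
              + bio_sd * (l_j z_ib + sqrt(1 - l_j^2) e_ij)   (biology, block factor)
              + b_{batch(i), j}               (batch,     N(0, batch_sd))
              + u_ijr                         (replicate, N(0, replicate_sd))

QC samples replace ``mu_j`` (plus biology) by the log of the arithmetic mean
of a 50-donor pool's linear amplitudes, so they carry only technical
(batch + replicate) variance — exactly what CV-based QC reporting assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureMatrix, RawSpectrum, feature_label

__all__ = [
    "CohortConfig",
    "PeakPanel",
    "EffectSpec",
    "generate_cohort",
    "generate_panel",
    "default_effects",
    "simulate_feature_matrix",
    "generate_spectrum",
    "generate_spectra",
    "make_qc_pool",
    "simulate_classification_matrix",
]

GROUPS = ("HC", "BD", "LC")
SPLITS = ("discovery", "validation", "test")

# Cohort margins mirror the study's demographic table. Binary traits are
# stored as per-group proportions (counts / default group size), so scaled
# cohorts keep the same marginal structure and the default sizes reproduce
# the table's counts exactly.
_DEF_N = {"HC": 429, "BD": 280, "LC": 334}
_DEFAULT_DEMOGRAPHICS = {
    "female": {g: c / _DEF_N[g] for g, c in {"HC": 281, "BD": 171, "LC": 213}.items()},
    "smoking": {g: c / _DEF_N[g] for g, c in {"HC": 88, "BD": 54, "LC": 44}.items()},
    "family_history": {g: c / _DEF_N[g] for g, c in {"HC": 46, "BD": 30, "LC": 26}.items()},
    "env_exposure": {g: c / _DEF_N[g] for g, c in {"HC": 63, "BD": 27, "LC": 27}.items()},
    "age_mean": {"HC": 58.0, "BD": 57.0, "LC": 58.0},
    "age_sd": {"HC": 9.0, "BD": 10.0, "LC": 10.0},
    "age_range": (35, 80),
}
# Stage I is split 80:20 into IA:IB (the table reports stage I only).
_DEFAULT_STAGE_COUNTS = {"0": 11, "IA": 224, "IB": 56, "II": 9, "III": 12, "IV": 3, "NA": 19}
_DEFAULT_SUBTYPE_COUNTS = {"LUAD": 310, "SCC": 16, "LCC": 2, "ASC": 3, "SCLC": 1, "NA": 2}
_DEFAULT_LUAD_CLASS_COUNTS = {"AIS": 18, "MIA": 101, "IAC": 160, "NA": 31}

_DEFAULT_SPLIT_COUNTS = {
    "discovery": {"HC": 237, "BD": 145, "LC": 191},
    "validation": {"HC": 102, "BD": 62, "LC": 72},
    "test": {"HC": 90, "BD": 73, "LC": 71},
}


@dataclass
class CohortConfig:
    """Cohort design: group sizes, split layout, batches and demographics."""

    n_hc: int = 429
    n_bd: int = 280
    n_lc: int = 334
    split_counts: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SPLIT_COUNTS.items()})
    n_batches: int = 46
    qc_per_batch: int = 3
    n_centers: int = 6
    demographics: dict = field(default_factory=lambda: dict(_DEFAULT_DEMOGRAPHICS))
    stage_counts: dict = field(default_factory=lambda: dict(_DEFAULT_STAGE_COUNTS))
    subtype_counts: dict = field(default_factory=lambda: dict(_DEFAULT_SUBTYPE_COUNTS))
    luad_class_counts: dict = field(default_factory=lambda: dict(_DEFAULT_LUAD_CLASS_COUNTS))
    biomarker_missing_rate: float = 0.4

    def group_counts(self) -> dict:
        return {"HC": self.n_hc, "BD": self.n_bd, "LC": self.n_lc}

    @classmethod
    def small(cls, n_per_group: int = 30, n_batches: int = 4, qc_per_batch: int = 2) -> "CohortConfig":
        """A scaled-down design (equal groups, 7:3:3-ish splits) for fast runs."""
        counts = {}
        for g in GROUPS:
            n = n_per_group
            n_disc = int(round(n * 7 / 13))
            n_val = int(round(n * 3 / 13))
            counts[g] = (n_disc, n_val, n - n_disc - n_val)
        split_counts = {s: {g: counts[g][i] for g in GROUPS} for i, s in enumerate(SPLITS)}
        return cls(
            n_hc=n_per_group, n_bd=n_per_group, n_lc=n_per_group,
            split_counts=split_counts, n_batches=n_batches, qc_per_batch=qc_per_batch,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _exact_binary(rng: np.random.Generator, n: int, n_true: int) -> np.ndarray:
    """Boolean vector of length n with exactly n_true Trues, order randomized."""
    v = np.zeros(n, dtype=bool)
    v[:n_true] = True
    rng.shuffle(v)
    return v


def _scale_counts(counts: dict, n: int) -> dict:
    """Rescale category counts to sum to ``n`` by largest-remainder rounding
    (identity when they already sum to ``n``)."""
    total = sum(counts.values())
    if total == n or total == 0:
        return dict(counts)
    keys = list(counts.keys())
    target = np.array([counts[k] * n / total for k in keys])
    base = np.floor(target).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(target - base))
    base[order[:rem]] += 1
    return dict(zip(keys, base.tolist()))


def _exact_categorical(rng: np.random.Generator, counts: dict, n: int) -> np.ndarray:
    counts = _scale_counts(counts, n)
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    return labels


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None,
                    include_qc: bool = True) -> pd.DataFrame:
    """Generate per-sample clinical/design metadata for a synthetic cohort.

    Categorical margins (gender, smoking, stage, subtype, ...) are matched
    *exactly* to the configured per-group counts by shuffling label vectors,
    so the defaults reproduce the study-style demographic table; ages are
    truncated-normal. Split assignment is stratified by group with explicit
    per-split sizes. QC rows (pooled samples, one entry per batch x
    ``qc_per_batch``) carry ``group="NA"`` and ``is_qc=True``.

    Returns a DataFrame with one row per biological sample (plus QC entries),
    deterministic given ``seed``.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility is contractual)")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    counts = config.group_counts()
    if any(v < 0 for v in counts.values()):
        raise ValueError("group counts must be >= 0")
    for s in SPLITS:
        row = config.split_counts.get(s, {})
        for g in GROUPS:
            if row.get(g, 0) < 0:
                raise ValueError("split counts must be >= 0")
    for g in GROUPS:
        tot = sum(config.split_counts[s][g] for s in SPLITS)
        if tot != counts[g]:
            raise ValueError(
                f"split sizes for group {g} sum to {tot}, expected {counts[g]}"
            )

    frames = []
    demo = config.demographics
    lo, hi = demo["age_range"]
    for g in GROUPS:
        n = counts[g]
        if n == 0:
            continue
        age = rng.normal(demo["age_mean"][g], demo["age_sd"][g], size=n)
        age = np.clip(np.round(age), lo, hi).astype(int)
        def n_true(trait: str) -> int:
            return int(np.clip(round(demo[trait][g] * n), 0, n))

        df = pd.DataFrame({
            "sample_id": [f"{g}_{i + 1:04d}" for i in range(n)],
            "group": g,
            "age": age,
            "gender": np.where(_exact_binary(rng, n, n_true("female")), "F", "M"),
            "smoking": _exact_binary(rng, n, n_true("smoking")),
            "family_history": _exact_binary(rng, n, n_true("family_history")),
            "env_exposure": _exact_binary(rng, n, n_true("env_exposure")),
        })
        # stratified split assignment with explicit sizes
        split = np.repeat(SPLITS, [config.split_counts[s][g] for s in SPLITS])
        rng.shuffle(split)
        df["split"] = split
        if g == "LC":
            df["stage"] = _exact_categorical(rng, config.stage_counts, n)
            df["subtype"] = _exact_categorical(rng, config.subtype_counts, n)
            luad_class = np.full(n, "NA", dtype=object)
            is_luad = np.flatnonzero(df["subtype"].to_numpy() == "LUAD")
            luad_class[is_luad] = _exact_categorical(
                rng, config.luad_class_counts, is_luad.size
            )
            df["luad_class"] = luad_class
        else:
            df["stage"] = "NA"
            df["subtype"] = "NA"
            df["luad_class"] = "NA"
        frames.append(df)

    if frames:
        meta = pd.concat(frames, ignore_index=True)
        n = len(meta)
        meta["center"] = rng.integers(1, config.n_centers + 1, size=n)
        meta["batch_id"] = 1 + (rng.permutation(n) % config.n_batches)
        # serum biomarkers: mildly elevated, heavy-tailed in LC; partly missing
        is_lc = (meta["group"] == "LC").to_numpy()
        ca125 = np.where(
            is_lc,
            rng.lognormal(np.log(14.0), 0.7, size=n),
            rng.lognormal(np.log(10.0), 0.5, size=n),
        )
        cea = np.where(
            is_lc,
            rng.lognormal(np.log(2.2), 0.8, size=n),
            rng.lognormal(np.log(1.4), 0.5, size=n),
        )
        miss = rng.random(n) < config.biomarker_missing_rate
        ca125[miss] = np.nan
        miss = rng.random(n) < config.biomarker_missing_rate
        cea[miss] = np.nan
        meta["ca125"] = np.round(ca125, 2)
        meta["cea"] = np.round(cea, 2)
        meta["is_qc"] = False
    else:
        meta = pd.DataFrame(
            columns=["sample_id", "group", "age", "gender", "smoking",
                     "family_history", "env_exposure", "split", "stage",
                     "subtype", "luad_class", "center", "batch_id",
                     "ca125", "cea", "is_qc"]
        )

    if include_qc and len(meta) > 0:
        qc_rows = []
        for b in range(1, config.n_batches + 1):
            for k in range(1, config.qc_per_batch + 1):
                qc_rows.append({
                    "sample_id": f"QC_b{b:02d}_{k}", "group": "NA", "age": np.nan,
                    "gender": "NA", "smoking": False, "family_history": False,
                    "env_exposure": False, "split": "NA", "stage": "NA",
                    "subtype": "NA", "luad_class": "NA",
                    "center": 0, "batch_id": b, "ca125": np.nan, "cea": np.nan,
                    "is_qc": True,
                })
        meta = pd.concat([meta, pd.DataFrame(qc_rows)], ignore_index=True)

    cols = ["sample_id", "group", "split", "center", "batch_id", "age", "gender",
            "smoking", "family_history", "env_exposure", "stage", "subtype",
            "luad_class", "ca125", "cea", "is_qc"]
    return meta[cols]


# --------------------------------------------------------------------------
# peak panel and effects
# --------------------------------------------------------------------------

@dataclass
class PeakPanel:
    """Ground-truth peak panel: positions, widths and base log-amplitudes.

    Amplitudes are expressed in units of the rendering noise floor
    (``noise_sd = 1``), so ``exp(log_amp_mu)`` is roughly the expected S/N of
    the peak apex before normalization.
    """

    mz: np.ndarray
    width: np.ndarray           # Gaussian sigma, Da
    log_amp_mu: np.ndarray      # natural-log base amplitude

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.log_amp_mu = np.asarray(self.log_amp_mu, dtype=float)
        if not (len(self.mz) == len(self.width) == len(self.log_amp_mu)):
            raise ValueError("panel arrays must be aligned")
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            raise ValueError("panel m/z must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return self.mz.size

    @property
    def labels(self) -> list[str]:
        return [feature_label(m) for m in self.mz]


def generate_panel(n_strong: int = 650, n_weak: int = 150,
                   mz_range: tuple[float, float] = (70.0, 345.0),
                   seed: int | None = None) -> PeakPanel:
    """Draw a random peak panel.

    ``n_strong`` peaks sit well above the detection threshold (apex S/N
    ~20-2000) and survive an 80% presence filter; ``n_weak`` peaks hover
    around S/N 5 and are mostly filtered out, which is what produces a
    realistic surviving-feature count (~646 of 800 by default).
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    n = n_strong + n_weak
    lo, hi = mz_range
    # minimum spacing keeps panel peaks resolvable after binning: place n
    # points uniformly in the span left after reserving the spacing gaps
    min_sep = 0.25
    span = (hi - lo) - (n - 1) * min_sep
    if span <= 0:
        raise ValueError("panel too dense for the m/z range")
    mz = lo + np.sort(rng.uniform(0, span, size=n)) + min_sep * np.arange(n)
    strong = np.zeros(n, dtype=bool)
    strong[rng.choice(n, size=n_strong, replace=False)] = True
    log_amp = np.empty(n)
    log_amp[strong] = rng.uniform(np.log(25.0), np.log(2000.0), size=n_strong)
    log_amp[~strong] = rng.uniform(np.log(1.5), np.log(7.0), size=n_weak)
    # reflectron-TOF-like widths: FWHM ~ 0.02-0.05 Da; keeps the dense panel
    # resolvable and leaves most grid points signal-free for noise estimation
    width = rng.uniform(0.008, 0.022, size=n)
    return PeakPanel(mz=mz, width=width, log_amp_mu=log_amp)


@dataclass
class EffectSpec:
    """Planted ground truth: class effects, correlation blocks, noise scales.

    ``informative_mz``/``log2_fold_effects`` define the signed log2
    fold-changes applied multiplicatively to the LC group; the technical
    noise scales are natural-log SDs of multiplicative log-normal factors.
    """

    informative_mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    log2_fold_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    correlation_blocks: list = field(default_factory=list)  # (mz array, loading)
    batch_sd: float = 0.06
    replicate_sd: float = 0.10
    biological_sd: float = 0.5

    def __post_init__(self) -> None:
        self.informative_mz = np.asarray(self.informative_mz, dtype=float)
        self.log2_fold_effects = np.asarray(self.log2_fold_effects, dtype=float)
        if self.informative_mz.size != self.log2_fold_effects.size:
            raise ValueError("informative_mz and log2_fold_effects must align")
        if not np.all(np.isfinite(self.log2_fold_effects)):
            raise ValueError("effects must be finite")
        for _, loading in self.correlation_blocks:
            if not -1.0 <= loading <= 1.0:
                raise ValueError("block loadings must be in [-1, 1]")

    def validate_against_panel(self, panel: PeakPanel) -> None:
        if self.informative_mz.size and not np.isin(self.informative_mz, panel.mz).all():
            raise ValueError("informative features must be a subset of the panel")


def default_effects(panel: PeakPanel, seed: int,
                    n_up: int = 10, n_down: int = 10, n_weak: int = 15,
                    strong_lfc: tuple[float, float] = (0.8, 1.5),
                    weak_lfc: float = 0.15,
                    n_blocks: int = 4, block_size: int = 6,
                    block_loading: float = 0.6,
                    batch_sd: float = 0.06, replicate_sd: float = 0.10,
                    biological_sd: float = 0.5) -> EffectSpec:
    """Default planted-effect layout: 10 up + 10 down strongly dysregulated
    features plus 15 weakly shifted ones (calibrated so roughly the strong 20
    of the 35 reach FDR < 0.05 at study-scale n), and a few correlated blocks
    sharing a latent biological factor."""
    rng = np.random.default_rng(seed)
    strong_idx = np.flatnonzero(panel.log_amp_mu > np.log(20.0))
    n_info = n_up + n_down + n_weak
    chosen = rng.choice(strong_idx, size=n_info, replace=False)
    lfc = np.concatenate([
        rng.uniform(*strong_lfc, size=n_up),
        -rng.uniform(*strong_lfc, size=n_down),
        rng.uniform(-weak_lfc, weak_lfc, size=n_weak),
    ])
    blocks = []
    pool = np.setdiff1d(strong_idx, chosen)
    for _ in range(n_blocks):
        if pool.size < block_size:
            break
        members = rng.choice(pool, size=block_size, replace=False)
        pool = np.setdiff1d(pool, members)
        blocks.append((panel.mz[np.sort(members)], block_loading))
    order = np.argsort(panel.mz[chosen])
    return EffectSpec(
        informative_mz=panel.mz[chosen][order],
        log2_fold_effects=lfc[order],
        correlation_blocks=blocks,
        batch_sd=batch_sd,
        replicate_sd=replicate_sd,
        biological_sd=biological_sd,
    )


# --------------------------------------------------------------------------
# amplitude model (shared by fast path and spectrum renderer)
# --------------------------------------------------------------------------

def _sample_log_amplitudes(meta: pd.DataFrame, panel: PeakPanel,
                           effects: EffectSpec, seed: int,
                           replicates: int = 3,
                           qc_pool_size: int = 50) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw log amplitudes for every (sample, replicate) x feature.

    Returns ``(log_amp, index_frame)`` where ``log_amp`` has shape
    ``(n_rows, n_features)`` and ``index_frame`` carries sample_id,
    replicate_idx, batch_id, is_qc per row.
    """
    effects.validate_against_panel(panel)
    rng = np.random.default_rng(seed)
    n_feat = panel.n_peaks
    subjects = meta.loc[~meta["is_qc"]].reset_index(drop=True)
    qc = meta.loc[meta["is_qc"]].reset_index(drop=True)
    n_sub = len(subjects)

    # subject-level biological log-amplitude (before technical noise)
    base = np.tile(panel.log_amp_mu, (n_sub, 1))
    if effects.informative_mz.size:
        cols = np.searchsorted(panel.mz, effects.informative_mz)
        is_lc = (subjects["group"] == "LC").to_numpy()
        base[np.ix_(is_lc, cols)] += np.log(2.0) * effects.log2_fold_effects
    bio = rng.standard_normal((n_sub, n_feat))
    for block_mz, loading in effects.correlation_blocks:
        cols = np.searchsorted(panel.mz, np.asarray(block_mz, dtype=float))
        z = rng.standard_normal(n_sub)[:, None]
        bio[:, cols] = loading * z + np.sqrt(1.0 - loading**2) * bio[:, cols]
    base += effects.biological_sd * bio

    # QC parameterization: arithmetic mean (linear scale) of a donor pool;
    # with no donors in the frame the pool is the panel base itself
    if len(qc):
        if n_sub == 0:
            qc_mu = panel.log_amp_mu.copy()
        else:
            pool = min(qc_pool_size, n_sub)
            pool_idx = rng.choice(n_sub, size=pool, replace=False)
            qc_mu = np.log(np.exp(base[pool_idx]).mean(axis=0))

    batch_ids = sorted(meta["batch_id"].unique())
    batch_fx = {b: rng.normal(0.0, effects.batch_sd, size=n_feat) for b in batch_ids}

    rows, logs = [], []
    for frame, is_qc_flag in ((subjects, False), (qc, True)):
        for i in range(len(frame)):
            row = frame.iloc[i]
            mu = qc_mu if is_qc_flag else base[i]
            for r in range(1, replicates + 1):
                noise = rng.normal(0.0, effects.replicate_sd, size=n_feat)
                logs.append(mu + batch_fx[row["batch_id"]] + noise)
                rows.append((row["sample_id"], r, row["batch_id"], is_qc_flag))
    index_frame = pd.DataFrame(
        rows, columns=["sample_id", "replicate_idx", "batch_id", "is_qc"]
    )
    return np.asarray(logs), index_frame


def simulate_feature_matrix(meta: pd.DataFrame, panel: PeakPanel,
                            effects: EffectSpec, seed: int,
                            replicates: int = 3) -> FeatureMatrix:
    """Fast path: the feature matrix preprocessing would recover, drawn
    directly from the amplitude model (rows = sample x replicate)."""
    log_amp, idx = _sample_log_amplitudes(meta, panel, effects, seed, replicates)
    values = pd.DataFrame(
        np.exp(log_amp),
        index=pd.MultiIndex.from_frame(idx[["sample_id", "replicate_idx"]]),
        columns=panel.labels,
    )
    return FeatureMatrix(values=values, feature_mz=panel.mz.copy())


def simulate_classification_matrix(n_per_group: int, n_noise: int,
                                   n_informative: int, seed: int,
                                   log2fc: float = 1.0,
                                   biological_sd: float = 0.5,
                                   replicate_sd: float = 0.1) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Two-class benchmark matrix: ``n_informative`` planted features with
    signed |log2FC| = ``log2fc`` among ``n_noise`` null features.

    Returns ``(X, y, informative_labels)`` with one row per sample (replicates
    already collapsed), suitable for feature-selection and model benchmarks.
    """
    rng = np.random.default_rng(seed)
    n_feat = n_noise + n_informative
    mz = np.sort(rng.uniform(70, 345, size=n_feat))
    labels = [feature_label(m) for m in mz]
    info_cols = np.sort(rng.choice(n_feat, size=n_informative, replace=False))
    signs = np.where(rng.random(n_informative) < 0.5, 1.0, -1.0)
    n = 2 * n_per_group
    y = np.repeat([0, 1], n_per_group)
    sd = np.hypot(biological_sd, replicate_sd)
    log_amp = rng.uniform(np.log(25), np.log(2000), size=n_feat)
    X = log_amp + sd * rng.standard_normal((n, n_feat))
    X[np.ix_(y == 1, info_cols)] += np.log(2.0) * log2fc * signs
    X = pd.DataFrame(np.exp(X), columns=labels,
                     index=[f"S{i:04d}" for i in range(n)])
    return X, y, [labels[c] for c in info_cols]


# --------------------------------------------------------------------------
# spectrum rendering
# --------------------------------------------------------------------------

def default_grid(n_points: int = 65536,
                 mz_range: tuple[float, float] = (66.0, 350.0)) -> np.ndarray:
    """Uniform acquisition grid (>60,000 points over m/z 66-350 by default)."""
    return np.linspace(mz_range[0], mz_range[1], n_points)


def render_spectrum(grid: np.ndarray, peak_mz: np.ndarray, peak_width: np.ndarray,
                    peak_amp: np.ndarray, baseline_amp: float = 30.0,
                    baseline_tau: float = 80.0, baseline_offset: float = 6.0,
                    noise_sd: float = 1.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Render intensities = decaying baseline + Gaussian peaks + noise, >= 0.

    ``baseline_offset`` is the flat chemical-noise floor; keeping it a few
    noise SDs above zero means the additive noise is essentially never
    clipped, as in real acquisitions where the detector records a positive
    chemical background.
    """
    intensity = (baseline_offset
                 + baseline_amp * np.exp(-(grid - grid[0]) / baseline_tau))
    for m, w, a in zip(peak_mz, peak_width, peak_amp):
        lo = np.searchsorted(grid, m - 5 * w)
        hi = np.searchsorted(grid, m + 5 * w)
        if hi > lo:
            g = grid[lo:hi]
            intensity[lo:hi] += a * np.exp(-0.5 * ((g - m) / w) ** 2)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        intensity += rng.normal(0.0, noise_sd, size=grid.size)
    return np.clip(intensity, 0.0, None)


def generate_spectrum(sample: pd.Series, panel: PeakPanel, effects: EffectSpec,
                      seed: int | None = None, grid: np.ndarray | None = None,
                      replicate_idx: int = 1, noise_sd: float = 1.0,
                      baseline_amp: float = 30.0) -> RawSpectrum:
    """Render one replicate spectrum for one cohort row (see module docstring
    for the amplitude model). ``seed`` is mandatory."""
    if seed is None:
        raise ValueError("seed is required (reproducibility is contractual)")
    if grid is None:
        grid = default_grid()
    if panel.n_peaks and (panel.mz.min() < 66.0 or panel.mz.max() > 350.0):
        raise ValueError("panel m/z must lie within [66, 350]")
    meta = sample.to_frame().T
    meta["is_qc"] = bool(sample.get("is_qc", False))
    log_amp, _ = _sample_log_amplitudes(
        meta, panel, effects, seed=seed, replicates=1, qc_pool_size=1
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, replicate_idx, 9173]))
    intensity = render_spectrum(
        grid, panel.mz, panel.width, np.exp(log_amp[0]),
        baseline_amp=baseline_amp, noise_sd=noise_sd,
        rng=rng if noise_sd > 0 else None,
    )
    return RawSpectrum(
        mz=grid, intensity=intensity, sample_id=str(sample["sample_id"]),
        batch_id=int(sample["batch_id"]), replicate_idx=replicate_idx,
        is_qc=bool(sample.get("is_qc", False)),
    )


def generate_spectra(meta: pd.DataFrame, panel: PeakPanel, effects: EffectSpec,
                     seed: int, replicates: int = 3,
                     grid: np.ndarray | None = None, noise_sd: float = 1.0,
                     baseline_amp: float = 30.0) -> list[RawSpectrum]:
    """Render the full study: one spectrum per (cohort row, replicate spot).

    All amplitudes come from one call to the shared amplitude model, so
    planted effects, batch factors and the QC pooling are consistent across
    replicates and with :func:`simulate_feature_matrix`.
    """
    if grid is None:
        grid = default_grid()
    log_amp, idx = _sample_log_amplitudes(meta, panel, effects, seed, replicates)
    root = np.random.SeedSequence([seed, 40427])
    children = root.spawn(len(idx))
    spectra = []
    for i, row in idx.iterrows():
        rng = np.random.default_rng(children[i])
        intensity = render_spectrum(
            grid, panel.mz, panel.width, np.exp(log_amp[i]),
            baseline_amp=baseline_amp, noise_sd=noise_sd,
            rng=rng if noise_sd > 0 else None,
        )
        spectra.append(RawSpectrum(
            mz=grid, intensity=intensity, sample_id=row["sample_id"],
            batch_id=int(row["batch_id"]), replicate_idx=int(row["replicate_idx"]),
            is_qc=bool(row["is_qc"]),
        ))
    return spectra


def make_qc_pool(spectra: list[RawSpectrum]) -> RawSpectrum:
    """Pool spectra by arithmetic mean (equal-volume pooling of aliquots).

    All inputs must share one m/z grid; pooled peak amplitudes equal the mean
    of the input amplitudes. The result is flagged ``is_qc=True``.
    """
    if not spectra:
        raise ValueError("need at least one spectrum to pool")
    grid = spectra[0].mz
    for s in spectra[1:]:
        if s.mz.shape != grid.shape or not np.array_equal(s.mz, grid):
            raise ValueError("mismatched m/z grids")
    pooled = np.mean([s.intensity for s in spectra], axis=0)
    return RawSpectrum(mz=grid.copy(), intensity=pooled,
                       sample_id="QC_pool", batch_id=spectra[0].batch_id,
                       replicate_idx=1, is_qc=True)
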