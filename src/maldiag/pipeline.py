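"""End-to-end orchestration: cohort splitting, staged runs with a checksum
manifest, and seed management.

A run executes simulate -> preprocess -> qc -> select -> train -> evaluate
-> stats into one output directory. Every stage writes its outputs plus an
entry in ``manifest.json`` (parameters, derived seed, sha256 of each output
file). Re-running with the same config resumes from intact cached outputs;
a corrupted intermediate raises a stage-named error rather than silently
recomputing. The single global seed is expanded into per-stage seeds by a
fixed counter scheme (``seed + stage offset``), so no stage shares a random
stream with another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthgen
from .containers import FeatureMatrix, RawSpectrum
from .evaluate import evaluate_predictions, decision_curve, subgroup_metrics
from .model import VotingEnsembleClassifier, fit_base, predict_scores, save_ensemble
from .preprocess import SpectrumPreprocessor
from .qc import filter_by_qc_cv, qc_cv_report
from .select import SFFSSelector, rank_auc, union_top_models
from .stats import logistic_or, ml_power_analysis, spearman_network

__all__ = ["RunConfig", "split_cohort", "run_all", "STAGE_OFFSETS"]

log = logging.getLogger("maldiag")

STAGE_OFFSETS = {
    "simulate": 0, "preprocess": 1, "qc": 2, "select": 3,
    "train": 4, "evaluate": 5, "stats": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + STAGE_OFFSETS[stage]) % (2**31 - 1)


# --------------------------------------------------------------------------
# cohort splitting
# --------------------------------------------------------------------------

def split_cohort(meta: pd.DataFrame, sizes=None, ratio=(7, 3, 3),
                 per_group_counts: dict | None = None,
                 stratify_by: str = "group", seed: int = 0) -> pd.Series:
    """Assign discovery/validation/test split labels, stratified by group.

    Three modes: ``per_group_counts`` gives explicit {split: {group: n}}
    counts (overrides everything, e.g. to reproduce a published layout);
    ``sizes`` gives exact per-split totals apportioned near-proportionally
    per group; otherwise ``ratio`` splits each stratum by largest-remainder
    rounding (per-group counts then deviate from exact proportionality by
    strictly less than 1). QC rows are labeled ``"NA"``.
    """
    rng = np.random.default_rng(seed)
    splits = list(synthgen.SPLITS)
    subjects = meta.loc[~meta["is_qc"]]
    out = pd.Series("NA", index=meta.index, dtype=object)
    groups = subjects[stratify_by].unique()

    if per_group_counts is not None:
        for g in groups:
            idx = subjects.index[subjects[stratify_by] == g].to_numpy()
            counts = [per_group_counts[s].get(g, 0) for s in splits]
            if sum(counts) != idx.size:
                raise ValueError(
                    f"split sizes for stratum {g!r} sum to {sum(counts)}, "
                    f"expected {idx.size}")
            rng.shuffle(idx)
            labels = np.repeat(splits, counts)
            out.loc[idx] = labels
        return out

    n = len(subjects)
    if sizes is not None:
        if sum(sizes) != n:
            raise ValueError(f"sizes sum to {sum(sizes)}, expected {n}")
        weights = np.asarray(sizes, dtype=float) / n
    else:
        weights = np.asarray(ratio, dtype=float)
        weights = weights / weights.sum()

    # largest-remainder apportionment within each stratum
    alloc = {}
    for g in groups:
        n_g = int((subjects[stratify_by] == g).sum())
        if n_g < len(splits) and n_g > 0 and min(weights) > 0:
            raise ValueError(f"stratum {g!r} smaller than number of splits")
        target = weights * n_g
        base = np.floor(target).astype(int)
        rem = n_g - base.sum()
        order = np.argsort(-(target - base))
        base[order[:rem]] += 1
        alloc[g] = base
    if sizes is not None:
        # nudge cells so column totals match the requested sizes exactly
        totals = np.sum(list(alloc.values()), axis=0)
        want = np.asarray(sizes, dtype=int)
        while not np.array_equal(totals, want):
            over = int(np.argmax(totals - want))
            under = int(np.argmin(totals - want))
            g = max(alloc, key=lambda g: alloc[g][over])
            alloc[g][over] -= 1
            alloc[g][under] += 1
            totals = np.sum(list(alloc.values()), axis=0)
    for g in groups:
        idx = subjects.index[subjects[stratify_by] == g].to_numpy()
        rng.shuffle(idx)
        out.loc[idx] = np.repeat(splits, alloc[g])
    return out


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run (round-trips through YAML)."""

    out_dir: str = "run"
    seed: int | None = None
    # simulate
    simulate: bool = True
    n_per_group: int = 30
    n_batches: int = 4
    qc_per_batch: int = 2
    n_strong_peaks: int = 40
    n_weak_peaks: int = 10
    grid_points: int = 8192
    replicates: int = 3
    # real-data entry points (used when simulate=False)
    spectra_dir: str | None = None
    metadata_csv: str | None = None
    # preprocess
    smooth_halfwindow: int = 3
    snip_iterations: int = 50
    snr_min: float = 5.0
    tolerance_ppm: float = 500.0
    min_presence: float = 0.80
    # qc
    qc_max_cv: float = 25.0
    # select
    learners: tuple = ("logreg", "knn", "svc_linear")
    folds: int = 5
    max_features: int = 10
    min_delta: float = 1e-4
    top_k: int = 3
    # model / evaluate
    class_weighting: bool = False
    threshold: float = 0.5
    # stats
    run_power: bool = False
    power_sizes: tuple = (10, 20)
    power_reps: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory in RunConfig")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("learners", "power_sizes"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {"stages": {}}

    def stage_cached(self, name: str, params: dict) -> bool:
        entry = self.data["stages"].get(name)
        if entry is None or entry.get("params") != params:
            return False
        for f, digest in entry["files"].items():
            p = self.path.parent / f
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise RuntimeError(
                    f"stage '{name}': cached output {f} is corrupted "
                    "(checksum mismatch); delete it to recompute")
        return True

    def record(self, name: str, params: dict, files: list[Path], seed: int) -> None:
        self.data["stages"][name] = {
            "params": params, "seed": seed,
            "files": {str(f.relative_to(self.path.parent)): _sha256(f) for f in files},
        }
        self.path.write_text(json.dumps(self.data, indent=2))


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _binary_labels(meta: pd.DataFrame) -> pd.Series:
    return (meta["group"] == "LC").astype(int)


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline into ``config.out_dir``; returns the path.

    Stage failures abort with the stage name; outputs written so far are
    preserved. Re-running resumes from intact cached stage outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = _Manifest(out / "manifest.json")
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate) if config.simulate else ("simulate", _stage_load),
        ("preprocess", _stage_preprocess),
        ("qc", _stage_qc),
        ("select", _stage_select),
        ("train", _stage_train),
        ("evaluate", _stage_evaluate),
        ("stats", _stage_stats),
    ]
    for name, fn in stages:
        seed = stage_seed(config.seed, name)
        params = {"seed": seed, **_stage_params(config, name)}
        log.info("stage %s: params=%s", name, params)
        try:
            cached = manifest.stage_cached(name, params)
            files = fn(config, out, seed, state, cached=cached)
            if not cached:
                manifest.record(name, params, files, seed)
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    return out


def _stage_params(config: RunConfig, stage: str) -> dict:
    fields_by_stage = {
        "simulate": ["n_per_group", "n_batches", "qc_per_batch", "n_strong_peaks",
                     "n_weak_peaks", "grid_points", "replicates", "simulate",
                     "spectra_dir", "metadata_csv"],
        "preprocess": ["smooth_halfwindow", "snip_iterations", "snr_min",
                       "tolerance_ppm", "min_presence"],
        "qc": ["qc_max_cv"],
        "select": ["learners", "folds", "max_features", "min_delta"],
        "train": ["top_k", "class_weighting", "threshold"],
        "evaluate": [],
        "stats": ["run_power", "power_sizes", "power_reps"],
    }
    return {k: getattr(config, k) if not isinstance(getattr(config, k), tuple)
            else list(getattr(config, k)) for k in fields_by_stage[stage]}


def _stage_simulate(config: RunConfig, out: Path, seed: int, state: dict,
                    cached: bool = False) -> list[Path]:
    cohort_cfg = synthgen.CohortConfig.small(
        config.n_per_group, config.n_batches, config.qc_per_batch)
    meta = synthgen.generate_cohort(cohort_cfg, seed=seed)
    panel = synthgen.generate_panel(config.n_strong_peaks, config.n_weak_peaks,
                                    seed=seed + 1)
    effects = synthgen.default_effects(
        panel, seed=seed + 2,
        n_up=3, n_down=3, n_weak=2, n_blocks=1, block_size=3)
    state.update(meta=meta, panel=panel, effects=effects)
    files = [out / "cohort.csv"]
    spectra_dir = out / "spectra"
    if not cached:
        meta.to_csv(out / "cohort.csv", index=False)
        spectra_dir.mkdir(exist_ok=True)
        grid = synthgen.default_grid(config.grid_points)
        spectra = synthgen.generate_spectra(
            meta, panel, effects, seed=seed + 3,
            replicates=config.replicates, grid=grid)
        for s in spectra:
            p = spectra_dir / f"{s.sample_id}_r{s.replicate_idx}.txt.gz"
            s.write_txt(p)
            files.append(p)
        state["spectra"] = spectra
    else:
        state["spectra"] = None  # reloaded on demand by preprocess
    return files


def _stage_load(config: RunConfig, out: Path, seed: int, state: dict,
                cached: bool = False) -> list[Path]:
    if not config.metadata_csv or not config.spectra_dir:
        raise ValueError("simulate=False requires metadata_csv and spectra_dir")
    meta = pd.read_csv(config.metadata_csv)
    state.update(meta=meta, spectra=None)
    state["external_spectra_dir"] = Path(config.spectra_dir)
    return []


def _load_spectra(out: Path, meta: pd.DataFrame, state: dict) -> list[RawSpectrum]:
    if state.get("spectra"):
        return state["spectra"]
    spectra_dir = state.get("external_spectra_dir", out / "spectra")
    spectra = []
    by_id = meta.set_index("sample_id")
    for p in sorted(spectra_dir.glob("*.txt*")):
        stem = p.name.split(".txt")[0]
        sample_id, rep = stem.rsplit("_r", 1)
        row = by_id.loc[sample_id]
        spectra.append(RawSpectrum.read_txt(
            p, sample_id=sample_id, batch_id=int(row["batch_id"]),
            replicate_idx=int(rep), is_qc=bool(row["is_qc"])))
    if not spectra:
        raise FileNotFoundError(f"no spectra found under {spectra_dir}")
    state["spectra"] = spectra
    return spectra


def _stage_preprocess(config: RunConfig, out: Path, seed: int, state: dict,
                      cached: bool = False) -> list[Path]:
    files = [out / "features.csv", out / "features_provenance.csv"]
    if cached:
        state["features"] = FeatureMatrix.read_csv(out / "features.csv")
        return files
    spectra = _load_spectra(out, state["meta"], state)
    pre = SpectrumPreprocessor(
        smooth_halfwindow=config.smooth_halfwindow,
        snip_iterations=config.snip_iterations, snr_min=config.snr_min,
        tolerance_ppm=config.tolerance_ppm, min_presence=config.min_presence)
    fm = pre.transform(spectra)
    state["features"] = fm
    fm.to_csv(files[0], files[1])
    return files


def _stage_qc(config: RunConfig, out: Path, seed: int, state: dict,
              cached: bool = False) -> list[Path]:
    meta = state["meta"]
    fm = state["features"]
    report = qc_cv_report(fm, meta)
    fm_qc = filter_by_qc_cv(fm, report, max_cv=config.qc_max_cv)
    state["features_qc"] = fm_qc
    files = [out / "qc_report.csv", out / "features_qc.csv"]
    if not cached:
        report.to_csv(files[0])
        fm_qc.to_csv(files[1])
    return files


def _discovery_matrix(state: dict) -> tuple[pd.DataFrame, dict]:
    meta = state["meta"]
    fm = state["features_qc"].impute_zero()
    subjects = meta.loc[~meta["is_qc"]].set_index("sample_id")
    X = fm.values.reindex(subjects.index).dropna(how="all")
    subjects = subjects.loc[X.index]
    y = _binary_labels(subjects)
    parts = {}
    for split in synthgen.SPLITS:
        mask = subjects["split"] == split
        parts[split] = (X.loc[mask], y.loc[mask].to_numpy())
    return X, parts


def _stage_select(config: RunConfig, out: Path, seed: int, state: dict,
                  cached: bool = False) -> list[Path]:
    _, parts = _discovery_matrix(state)
    X_disc, y_disc = parts["discovery"]
    X_val, y_val = parts["validation"]
    traces, ranking = [], []
    files = []
    for learner in config.learners:
        sel = SFFSSelector(learner=learner, folds=config.folds,
                           max_features=min(config.max_features, X_disc.shape[1]),
                           min_delta=config.min_delta, seed=seed)
        sel.fit(X_disc, y_disc)
        traces.append(sel.trace_)
        model = fit_base(learner, X_disc[sel.selected_labels_], y_disc,
                         class_weighting=config.class_weighting, seed=seed)
        ranking.append(rank_auc(y_val, predict_scores(model, X_val[sel.selected_labels_])))
        f = out / f"sffs_{learner}.jsonl"
        if not cached:
            sel.trace_.to_jsonl(f)
        files.append(f)
    union = union_top_models(traces, ranking, top_k=min(config.top_k, len(traces)))
    state.update(traces=traces, ranking=ranking, union=union)
    f = out / "selected_features.txt"
    if not cached:
        f.write_text("\n".join(union) + "\n")
    files.append(f)
    return files


def _stage_train(config: RunConfig, out: Path, seed: int, state: dict,
                 cached: bool = False) -> list[Path]:
    X, parts = _discovery_matrix(state)
    X_disc, y_disc = parts["discovery"]
    order = np.argsort(-np.asarray(state["ranking"]))[:config.top_k]
    ens = VotingEnsembleClassifier(
        base_learners=[config.learners[i] for i in order],
        subsets=[state["traces"][i].final_subset for i in order],
        threshold=config.threshold, class_weighting=config.class_weighting,
        seed=seed)
    ens.fit(X_disc, y_disc)
    state["ensemble"] = ens
    files = [out / "model" / "manifest.json", out / "predictions.csv"]
    if not cached:
        save_ensemble(ens, out / "model")
        meta = state["meta"]
        subjects = meta.loc[~meta["is_qc"]].set_index("sample_id").loc[X.index]
        scores = ens.predict_proba(X)[:, 1]
        pred = pd.DataFrame({
            "sample_id": X.index, "split": subjects["split"].to_numpy(),
            "group": subjects["group"].to_numpy(), "score": scores,
            "label": (scores >= ens.threshold).astype(int),
        })
        pred.to_csv(out / "predictions.csv", index=False)
    state["predictions"] = pd.read_csv(out / "predictions.csv")
    return files


def _stage_evaluate(config: RunConfig, out: Path, seed: int, state: dict,
                    cached: bool = False) -> list[Path]:
    pred = state["predictions"]
    files = []
    for split in ("validation", "test"):
        sub = pred.loc[pred["split"] == split]
        y = (sub["group"] == "LC").astype(int).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate_predictions(sub["score"].to_numpy(), y,
                                          threshold=config.threshold, seed=seed)
        state[f"report_{split}"] = report
        f = out / f"eval_{split}.json"
        files.append(f)
        dca = decision_curve(sub["score"].to_numpy(), y)
        fc = out / f"dca_{split}.csv"
        files.append(fc)
        if not cached:
            f.write_text(report.to_json())
            dca.to_csv(fc, index=False)
    return files


def _stage_stats(config: RunConfig, out: Path, seed: int, state: dict,
                 cached: bool = False) -> list[Path]:
    meta = state["meta"]
    pred = state["predictions"].set_index("sample_id")
    subjects = meta.loc[~meta["is_qc"]].set_index("sample_id").loc[pred.index]
    y = (subjects["group"] == "LC").astype(int).to_numpy()
    covars = pd.DataFrame({
        "age": subjects["age"].astype(float).fillna(subjects["age"].median()),
        "gender": (subjects["gender"] == "M").astype(float),
        "smoking": subjects["smoking"].astype(float),
        "family_history": subjects["family_history"].astype(float),
        "env_exposure": subjects["env_exposure"].astype(float),
    })
    try:
        or_res = logistic_or(y, pred["label"].to_numpy(float), covariates=covars,
                             predictor_name="ensemble_prediction")
    except (RuntimeError, ValueError) as exc:
        # separation is legitimate at small n / strong models: flag, don't die
        from .stats import ORResult
        or_res = ORResult(predictor="ensemble_prediction",
                          oddsratio=float("nan"), ci=(float("nan"), float("nan")),
                          p=float("nan"), coef=float("nan"), se=float("nan"),
                          covariates=list(covars.columns),
                          cohort=f"unavailable: {exc}")
    X, _ = _discovery_matrix(state)
    net = spearman_network(X[state["union"]])
    files = [out / "odds_ratios.csv", out / "correlation_network.csv"]
    if not cached:
        pd.DataFrame([or_res.as_row()]).to_csv(files[0], index=False)
        net.to_csv(files[1])
    if config.run_power:
        avail = int(min((y == 1).sum(), (y == 0).sum()))
        sizes = [s for s in config.power_sizes if s <= avail] or [avail]
        power = ml_power_analysis(X, y, sizes=sizes,
                                  B=config.power_reps, seed=seed)
        f = out / "power.csv"
        if not cached:
            power.to_csv(f, index=False)
        files.append(f)
    state["or_result"] = or_res
    return files
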