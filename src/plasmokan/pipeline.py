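"""Staged pipeline: simulate -> features -> train -> evaluate -> explain.

Each stage writes its artifacts under ``<output_dir>/run_<confighash>/<stage>``
so re-running with an identical config and seed reproduces identical outputs;
stages hand results to each other in memory when chained in one call and
reload them from disk when invoked separately.  A machine-readable run log
records the config hash, derived stage seeds, library versions and per-stage
wall time.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from . import __version__
from .cohort import SpectrumDataset, generate_dataset, sample_cohort
from .evaluation import (
    ScoredSet,
    confusion_and_rates,
    export_attention_heatmaps,
    pr_auc,
    roc_auc,
)
from .features import (
    EFFECTS,
    ModeWindows,
    NormalizationStats,
    feature_matrix,
    feature_table,
    patch_tensor,
)
from .io import RunConfig, load_dataset, save_dataset
from .nn.models import (
    build_feature_model,
    build_full_spectrum_model,
    load_model,
    save_model,
)
from .nn.train import TrainConfig, predict, subject_scores, train

STAGES = ("simulate", "features", "train", "evaluate", "explain")
#: each stage's hard prerequisite (artifact it consumes)
_REQUIRES = {
    "features": "simulate",
    "train": "simulate",
    "evaluate": "train",
    "explain": "train",
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed fanned out by stage-name hash."""
    return int((global_seed + zlib.crc32(stage.encode())) % 2**31)


class PipelineError(RuntimeError):
    pass


def _check_stage_order(stages: list[str], run_dir: Path) -> None:
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    order = [STAGES.index(s) for s in stages]
    if order != sorted(order) or len(set(order)) != len(order):
        raise PipelineError(f"stages must be unique and in order {STAGES}, got {stages}")
    for s in stages:
        req = _REQUIRES.get(s)
        if req and req not in stages and not (run_dir / req).exists():
            raise PipelineError(
                f"stage {s!r} requires {req!r} artifacts (run {req!r} first or add it)"
            )


def run_pipeline(
    config: RunConfig,
    stages: list[str] | tuple[str, ...] = STAGES,
    seed: int | None = None,
) -> dict:
    """Run the requested stages; returns a dict of artifacts and paths."""
    stages = list(stages)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    run_dir = Path(config.output_dir) / f"run_{config.config_hash()}"
    _check_stage_order(stages, run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    ctx: dict = {"run_dir": run_dir, "config": config}
    log: dict = {
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }
    for stage in stages:
        t0 = time.perf_counter()
        seed_s = stage_seed(config.seed, stage)
        _STAGE_FNS[stage](config, ctx, seed_s)
        log["stages"][stage] = {
            "seed": seed_s,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
    log_path = run_dir / "run_log.json"
    if log_path.exists():
        old = json.loads(log_path.read_text())
        old["stages"].update(log["stages"])
        log["stages"] = old["stages"]
    log_path.write_text(json.dumps(log, indent=2))
    ctx["log"] = log
    return ctx


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "plasmokan": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _get_dataset(config: RunConfig, ctx: dict) -> SpectrumDataset:
    if "dataset" not in ctx:
        sim_dir = ctx["run_dir"] / "simulate"
        if not sim_dir.exists():
            raise PipelineError("simulate artifacts not found")
        ctx["dataset"] = load_dataset(sim_dir, config.cohort, config.sensor)
    return ctx["dataset"]


def _stage_simulate(config: RunConfig, ctx: dict, seed: int) -> None:
    design = dataclasses.replace(config.cohort, seed=seed)
    dataset = generate_dataset(sample_cohort(design), config.sensor, design)
    save_dataset(dataset, ctx["run_dir"] / "simulate")
    ctx["dataset"] = dataset


def _stage_features(config: RunConfig, ctx: dict, seed: int) -> None:
    dataset = _get_dataset(config, ctx)
    windows = ModeWindows(config.features.windows)
    out = ctx["run_dir"] / "features"
    out.mkdir(exist_ok=True)
    meta = dataset.manifest()[["record_id", "marker", "partition", "subject_id"]]
    tables = {}
    for effect in EFFECTS:
        table = feature_table(dataset.records, effect, windows).merge(meta, on="record_id")
        table.to_csv(out / f"features_{effect}.csv", index=False)
        tables[effect] = table
    ctx["feature_tables"] = tables


def _train_inputs(config: RunConfig, ctx: dict):
    dataset = _get_dataset(config, ctx)
    marker = config.model.marker
    rec_train = dataset.partition("train", marker)
    rec_val = dataset.partition(config.evaluation.validation_partition, marker)
    if not rec_train or not rec_val:
        raise PipelineError("train or validation partition is empty for the configured marker")
    return dataset, rec_train, rec_val


def _stage_train(config: RunConfig, ctx: dict, seed: int) -> None:
    _, rec_train, rec_val = _train_inputs(config, ctx)
    out = ctx["run_dir"] / "train"
    out.mkdir(exist_ok=True)
    tcfg = TrainConfig(
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        learning_rate=config.train.learning_rate,
        optimizer=config.train.optimizer,
        seed=seed,
        patience=config.train.patience,
    )
    ms = config.model
    if ms.pathway == "full_spectrum":
        stats = NormalizationStats.fit(
            (r.pre_spectrum, r.post_spectrum) for r in rec_train
        )
        np.savez(out / "normalization.npz", mean=stats.mean, std=stats.std)
        Xtr, ytr, _ = patch_tensor(rec_train, config.features.patch_length, stats)
        Xva, yva, _ = patch_tensor(rec_val, config.features.patch_length, stats)
        model = build_full_spectrum_model(
            patch_length=config.features.patch_length,
            d_model=ms.d_model,
            n_layers=ms.n_layers,
            n_heads=ms.n_heads,
            head_hidden=ms.head_hidden,
            seed=seed,
        )
    else:
        windows = ModeWindows(config.features.windows)
        Xtr, ytr, _ = feature_matrix(rec_train, ms.pathway, windows)
        Xva, yva, _ = feature_matrix(rec_val, ms.pathway, windows)
        # z-score by training statistics so features sit inside the spline range
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xva = scaler.transform(Xtr), scaler.transform(Xva)
        np.savez(out / "feature_scaler.npz", mean=scaler.mean_, scale=scaler.scale_)
        model = build_feature_model(Xtr.shape[1], hidden=ms.feature_hidden, seed=seed)
        stats = None
        ctx["feature_scaler"] = scaler
    result = train(model, Xtr, ytr, Xva, yva, tcfg)
    save_model(model, str(out / "checkpoint.npz"))
    pd.DataFrame(
        {
            "epoch": np.arange(len(result.train_loss)),
            "train_loss": result.train_loss,
            "val_loss": result.val_loss,
            "val_auc": result.val_auc,
            "val_accuracy": result.val_accuracy,
        }
    ).to_csv(out / "curves.csv", index=False)
    ctx.update(model=model, train_result=result, normalization=stats)


def _load_trained(config: RunConfig, ctx: dict):
    if "model" not in ctx:
        out = ctx["run_dir"] / "train"
        if not (out / "checkpoint.npz").exists():
            raise PipelineError("train artifacts not found")
        ctx["model"] = load_model(str(out / "checkpoint.npz"))
        stats_path = out / "normalization.npz"
        if stats_path.exists():
            with np.load(stats_path) as data:
                ctx["normalization"] = NormalizationStats(data["mean"], data["std"])
        else:
            ctx["normalization"] = None
        scaler_path = out / "feature_scaler.npz"
        if scaler_path.exists():
            with np.load(scaler_path) as data:
                scaler = StandardScaler()
                scaler.mean_, scaler.scale_ = data["mean"], data["scale"]
                ctx["feature_scaler"] = scaler
    return ctx["model"], ctx.get("normalization")


def _records_to_inputs(config: RunConfig, records):
    ms = config.model
    if ms.pathway == "full_spectrum":
        return None  # needs stats; handled by caller
    windows = ModeWindows(config.features.windows)
    return feature_matrix(records, ms.pathway, windows)


def _score_partition(config: RunConfig, ctx: dict, partition: str) -> ScoredSet:
    dataset = _get_dataset(config, ctx)
    model, stats = _load_trained(config, ctx)
    records = dataset.partition(partition, config.model.marker)
    if not records:
        raise PipelineError(f"partition {partition!r} is empty")
    if config.model.pathway == "full_spectrum":
        X, y, subjects = patch_tensor(records, config.features.patch_length, stats)
    else:
        X, y, subjects = _records_to_inputs(config, records)
        if "feature_scaler" in ctx:
            X = ctx["feature_scaler"].transform(X)
    probs = predict(model, X)
    scores = subject_scores(probs, subjects)
    labels = pd.Series(y, index=subjects).groupby(level=0).first()
    return ScoredSet.from_series(scores, labels)


def _stage_evaluate(config: RunConfig, ctx: dict, seed: int) -> None:
    out = ctx["run_dir"] / "evaluate"
    out.mkdir(exist_ok=True)
    ev = config.evaluation
    val_scored = _score_partition(config, ctx, ev.validation_partition)
    rep_scored = _score_partition(config, ctx, ev.report_partition)
    threshold = "youden" if ev.threshold_policy == "youden" else ev.threshold_value
    report = confusion_and_rates(rep_scored, threshold, validation=val_scored)
    report.to_json(out / "report.json")
    _, roc_points = roc_auc(rep_scored)
    roc_points.to_csv(out / "roc.csv", index=False)
    _, pr_points = pr_auc(rep_scored)
    pr_points.to_csv(out / "pr.csv", index=False)
    ctx["report"] = report


def _stage_explain(config: RunConfig, ctx: dict, seed: int) -> None:
    dataset = _get_dataset(config, ctx)
    model, stats = _load_trained(config, ctx)
    from .nn.models import FullSpectrumKAN

    if not isinstance(model, FullSpectrumKAN):
        raise PipelineError("explain requires a full-spectrum (attention) checkpoint")
    out = ctx["run_dir"] / "explain"
    records = dataset.partition(config.evaluation.report_partition, config.model.marker)
    records = records[: config.evaluation.explain_records]
    X, _, _ = patch_tensor(records, config.features.patch_length, stats)
    grid = records[0].pre_spectrum.wavelength_nm
    maps = export_attention_heatmaps(
        model, X, out, wavelength_nm=grid, patch_length=config.features.patch_length
    )
    np.savez(out / "attention.npz", **maps)
    ctx["attention_maps"] = maps


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "explain": _stage_explain,
}
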