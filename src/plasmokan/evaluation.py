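"""Diagnostic evaluation: ROC/PR, operating-point rates, marker fusion, attention maps.

Evaluation is subject-level: replicate record probabilities are averaged into
one score per subject before any metric is computed.  AUC uses the midrank tie
convention (equivalent to the Mann-Whitney pairwise-comparison probability
with ties counted one half); the operating threshold is either fixed or chosen
by Youden's J on a designated validation set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .features import patch_wavelength_ranges
from .nn.models import FeatureKAN, FullSpectrumKAN, Module
from .nn.train import TrainConfig, predict, train


@dataclass(frozen=True)
class ScoredSet:
    """Per-subject scores with binary labels (1 = case)."""

    scores: np.ndarray
    labels: np.ndarray
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be matching 1-d arrays")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("labels must be 0 or 1")
        if self.subject_ids and len(self.subject_ids) != s.size:
            raise ValueError("subject_ids length mismatch")

    @classmethod
    def from_series(cls, scores: pd.Series, labels: pd.Series) -> "ScoredSet":
        scores, labels = scores.align(labels, join="inner")
        return cls(scores.to_numpy(), labels.to_numpy(), tuple(scores.index))

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("need at least one positive and one negative subject")


@dataclass
class EvalReport:
    auc: float
    pr_auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass(frozen=True)
class ImportanceReport:
    """Per-marker relative importance (sums to 1) with resampling spread."""

    importance: dict[str, float]
    resampling_sd: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.importance.values()))
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("importances must be non-negative and sum to 1")


# ---------------------------------------------------------------------------
# threshold-free metrics
# ---------------------------------------------------------------------------


def roc_auc(scored: ScoredSet) -> tuple[float, pd.DataFrame]:
    """AUC (midrank tie convention) plus the ROC curve points."""
    scored.require_both_classes()
    auc = float(roc_auc_score(scored.labels, scored.scores))
    fpr, tpr, thr = roc_curve(scored.labels, scored.scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_auc(scored: ScoredSet) -> tuple[float, pd.DataFrame]:
    """Area under precision-recall by step-wise interpolation (average precision)."""
    if not np.any(scored.labels == 1):
        raise ValueError("precision-recall requires at least one positive")
    ap = float(average_precision_score(scored.labels, scored.scores))
    prec, rec, thr = precision_recall_curve(scored.labels, scored.scores)
    curve = pd.DataFrame({"recall": rec, "precision": prec})
    return ap, curve


def youden_threshold(validation: ScoredSet) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1 on a validation set."""
    validation.require_both_classes()
    fpr, tpr, thr = roc_curve(validation.labels, validation.scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def confusion_and_rates(
    scored: ScoredSet,
    threshold: float | str = 0.5,
    validation: ScoredSet | None = None,
) -> EvalReport:
    """Full report at an operating point.

    ``threshold`` is either a number or ``"youden"``, in which case the
    Youden-optimal threshold is computed on the designated ``validation`` set.
    """
    scored.require_both_classes()
    if threshold == "youden":
        if validation is None:
            raise ValueError("threshold policy 'youden' requires a validation ScoredSet")
        thr = youden_threshold(validation)
    else:
        thr = float(threshold)
    pred = scored.scores >= thr
    y = scored.labels == 1
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    auc, _ = roc_auc(scored)
    ap, _ = pr_auc(scored)
    return EvalReport(
        auc=auc,
        pr_auc=ap,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / scored.labels.size,
        threshold=thr,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


# ---------------------------------------------------------------------------
# dual-marker fusion
# ---------------------------------------------------------------------------


@dataclass
class MarkerFusion:
    """Combine per-marker subject scores into one fused probability.

    A small KAN head (widths [2, 4, 1]) is fitted on the validation
    partition's paired scores; with ``trainable=False`` the fusion falls back
    to the mean of the marker scores.
    """

    markers: tuple[str, str]
    trainable: bool = True
    seed: int = 0
    model: FeatureKAN | None = None

    def fit(
        self,
        paired_scores: pd.DataFrame,
        labels: pd.Series,
        config: TrainConfig | None = None,
    ) -> "MarkerFusion":
        if not self.trainable:
            return self
        X = paired_scores[list(self.markers)].to_numpy(dtype=float)
        y = labels.loc[paired_scores.index].to_numpy(dtype=float)
        self.model = FeatureKAN(2, hidden=(4,), seed=self.seed)
        cfg = config if config is not None else TrainConfig(epochs=200, batch_size=32, seed=self.seed, patience=30)
        train(self.model, X, y, X, y, cfg)
        return self

    def predict(self, paired_scores: pd.DataFrame) -> pd.Series:
        X = paired_scores[list(self.markers)].to_numpy(dtype=float)
        if not self.trainable or self.model is None:
            fused = X.mean(axis=1)
        else:
            fused = predict(self.model, X)
        return pd.Series(fused, index=paired_scores.index, name="fused")


def fuse_markers(
    marker_scores: dict[str, pd.Series],
    labels: pd.Series,
    fit_subjects: list | None = None,
    trainable: bool = True,
    seed: int = 0,
) -> tuple[ScoredSet, MarkerFusion]:
    """Fuse two markers' subject scores; returns the fused set and the fusion model.

    ``fit_subjects`` designates the (validation) subjects used to fit the
    fusion head; prediction covers all subjects present in both score sets.
    """
    names = tuple(marker_scores)
    if len(names) != 2:
        raise ValueError("dual-marker fusion expects exactly two markers")
    paired = pd.DataFrame(marker_scores).dropna()
    if paired.empty:
        raise ValueError("no subjects shared between the marker score sets")
    missing = [s for s in (fit_subjects or []) if s not in paired.index]
    if missing:
        raise ValueError(f"fit subjects absent from paired scores: {missing[:5]}")
    fusion = MarkerFusion(markers=names, trainable=trainable, seed=seed)
    if trainable:
        fit_idx = paired.index if fit_subjects is None else pd.Index(fit_subjects)
        fusion.fit(paired.loc[fit_idx], labels)
    fused = fusion.predict(paired)
    scored = ScoredSet.from_series(fused, labels)
    return scored, fusion


def relative_importance(
    fusion: MarkerFusion,
    paired_scores: pd.DataFrame,
    labels: pd.Series,
    n_permutations: int = 100,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance of each marker in the fused diagnosis.

    The AUC drop when one marker's scores are permuted across subjects,
    averaged over permutations, normalized so the two importances sum to 1.
    """
    if fusion.trainable and fusion.model is None:
        raise ValueError("fusion model has not been fitted")
    rng = np.random.default_rng(seed)
    y = labels.loc[paired_scores.index]
    base_auc, _ = roc_auc(ScoredSet.from_series(fusion.predict(paired_scores), y))
    drops: dict[str, np.ndarray] = {}
    for marker in fusion.markers:
        vals = np.empty(n_permutations)
        for p in range(n_permutations):
            shuffled = paired_scores.copy()
            shuffled[marker] = rng.permutation(shuffled[marker].to_numpy())
            perm_auc, _ = roc_auc(ScoredSet.from_series(fusion.predict(shuffled), y))
            vals[p] = base_auc - perm_auc
        drops[marker] = vals
    means = {m: max(float(v.mean()), 0.0) for m, v in drops.items()}
    total = sum(means.values())
    if total <= 0:
        importance = {m: 1.0 / len(means) for m in means}
    else:
        importance = {m: v / total for m, v in means.items()}
    sds = {m: float(v.std() / max(total, 1e-12)) for m, v in drops.items()}
    return ImportanceReport(importance=importance, resampling_sd=sds)


# ---------------------------------------------------------------------------
# attention interpretability
# ---------------------------------------------------------------------------


def export_attention_heatmaps(
    model: Module,
    X: np.ndarray,
    out_dir: str | Path,
    wavelength_nm: np.ndarray | None = None,
    patch_length: int | None = None,
) -> dict[str, np.ndarray]:
    """Write one record-averaged heatmap per (layer, head); returns the matrices.

    Axes are patch indices; when the wavelength grid and patch length are
    given, ticks are annotated with each patch's wavelength range.
    """
    if not isinstance(model, FullSpectrumKAN):
        raise TypeError("attention heatmaps require the full-spectrum attention model")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = model.attention_maps(X)  # (L, H, P, P)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_patches = maps.shape[-1]
    tick_labels = None
    if wavelength_nm is not None and patch_length is not None:
        ranges = patch_wavelength_ranges(np.asarray(wavelength_nm), patch_length)
        tick_labels = [f"{lo:.0f}-{hi:.0f}" for lo, hi in ranges]
    exported: dict[str, np.ndarray] = {}
    ticks = np.arange(0, n_patches, max(1, n_patches // 8))
    for layer in range(maps.shape[0]):
        for head in range(maps.shape[1]):
            key = f"layer{layer + 1}_head{head + 1}"
            exported[key] = maps[layer, head]
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(maps[layer, head], origin="upper", cmap="viridis", aspect="auto")
            ax.set_title(f"attention {key}")
            ax.set_xlabel("key patch (wavelength range, nm)" if tick_labels else "key patch")
            ax.set_ylabel("query patch")
            if tick_labels:
                ax.set_xticks(ticks)
                ax.set_xticklabels([tick_labels[t] for t in ticks], rotation=45, ha="right", fontsize=6)
                ax.set_yticks(ticks)
                ax.set_yticklabels([tick_labels[t] for t in ticks], fontsize=6)
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            fig.savefig(out_dir / f"attention_{key}.png", dpi=150)
            plt.close(fig)
    return exported


def top_attention_patches(maps: np.ndarray, k: int = 4) -> np.ndarray:
    """Indices of the ``k`` key patches with the highest mean attention weight.

    The mean is taken over layers, heads and query patches, i.e. it answers
    "which spectral regions does the stack attend to overall".
    """
    column_weight = maps.mean(axis=(0, 1, 2))  # (P,)
    return np.argsort(column_weight)[::-1][:k]
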