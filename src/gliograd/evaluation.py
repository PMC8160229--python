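"""Repeated stratified k-fold cross-validation and the metric panel.

Splits are subject-level and stratified: within each class, subjects are
shuffled with the run's seed and dealt round-robin into folds, so fold sizes
per class differ by at most one and the class ratio of every fold matches the
cohort. For every (cell size, run, fold) the whole pipeline is refitted on
the training subjects only — descriptor extraction is split-independent and
shared, but phase-1 centroids and the SVM never see a test subject.

Metrics follow the standard diagnostic panel: accuracy ACC = (TP+TN)/total,
sensitivity SEN = TP/(TP+FN), specificity SPE = TN/(TN+FP), and ROC AUC from
signed decision scores. By default one ROC is built per run by pooling the
out-of-fold scores of all folds (stabler at double-digit cohort sizes than
per-fold ROCs); a per-fold mode is available. Mean and SD are taken across
runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._utils import config_hash, derive_seed
from .classify import SvmConfig, decision_score, fit_two_phase
from .fuzzy import FcmConfig
from .hog import HogConfig, extract_subject
from .preprocess import Volume, zscore_normalize

METRICS = ("acc", "sen", "spe", "auc")


@dataclasses.dataclass(frozen=True)
class CvConfig:
    n_folds: int = 10
    n_runs: int = 10
    cell_sizes: tuple[int, ...] = tuple(range(10, 21))
    seed: int = 0
    method: Literal["twophase", "baseline_concat"] = "twophase"
    transform_mode: Literal["soft", "hard"] = "soft"
    auc_mode: Literal["pooled", "per_fold"] = "pooled"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if len(self.cell_sizes) == 0:
            raise ValueError("cell_sizes must be non-empty")

    @property
    def hash(self) -> str:
        return config_hash(self)


@dataclasses.dataclass(frozen=True)
class CvResult:
    """All per-fold records plus run-level and cell-size-level aggregates."""

    fold_records: pd.DataFrame  # cell_size, run, fold, tp, fn, fp, tn, acc, sen, spe
    run_metrics: pd.DataFrame  # cell_size, run, acc, sen, spe, auc
    aggregates: pd.DataFrame  # cell_size, metric, mean, sd
    confusions: pd.DataFrame  # cell_size, tp, fn, fp, tn (median across runs)
    configs: dict

    def best_cell_size(self, metric: str = "auc") -> int:
        """Cell size with the highest mean of ``metric`` (ties: smaller size)."""
        sub = self.aggregates[self.aggregates["metric"] == metric]
        sub = sub.sort_values(["mean", "cell_size"], ascending=[False, True])
        return int(sub.iloc[0]["cell_size"])


def stratified_folds(
    labels: Sequence[int], n_folds: int, seed: int
) -> np.ndarray:
    """Assign each subject a fold id, stratified by class.

    Within each class, subjects are shuffled with ``seed`` and dealt
    round-robin, so per-class fold sizes differ by at most one. Classes
    smaller than ``n_folds`` are rejected.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    folds = np.full(labels.shape[0], -1, dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size < n_folds:
            raise ValueError(
                f"class {cls} has {members.size} subjects, fewer than "
                f"n_folds={n_folds}"
            )
        members = rng.permutation(members)
        folds[members] = np.arange(members.size) % n_folds
    return folds


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fn, fp, tn


def _rates(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float, float]:
    total = tp + fn + fp + tn
    acc = (tp + tn) / total if total else float("nan")
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sen, spe


def run_cv(
    volumes: Sequence[Volume],
    cv_config: CvConfig,
    hog_config: HogConfig = HogConfig(),
    fcm_config: FcmConfig = FcmConfig(),
    svm_config: SvmConfig = SvmConfig(),
) -> CvResult:
    """Run the full repeated stratified CV over the configured cell sizes.

    ``hog_config.cell_size`` is overridden by each entry of
    ``cv_config.cell_sizes``. Every nested seed (fold shuffling, FCM restarts,
    SVM) is derived deterministically from ``cv_config.seed``, so the whole
    result table is reproducible from the configs alone.
    """
    labels = np.asarray([v.label for v in volumes], dtype=int)
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("all volumes must carry binary labels")
    normalized = [zscore_normalize(v) for v in volumes]

    fold_rows: list[dict] = []
    run_rows: list[dict] = []
    for cell_size in cv_config.cell_sizes:
        hog_cfg = dataclasses.replace(hog_config, cell_size=int(cell_size))
        descriptors = [extract_subject(nv, hog_cfg) for nv in normalized]
        for run in range(cv_config.n_runs):
            run_seed = derive_seed(cv_config.seed, cell_size, run)
            folds = stratified_folds(labels, cv_config.n_folds, run_seed)
            pooled_scores = np.empty(labels.shape[0])
            pooled_pred = np.empty(labels.shape[0], dtype=int)
            fold_aucs: list[float] = []
            for fold in range(cv_config.n_folds):
                test_idx = np.flatnonzero(folds == fold)
                train_idx = np.flatnonzero(folds != fold)
                stage_seed = derive_seed(run_seed, fold)
                model = fit_two_phase(
                    [descriptors[i] for i in train_idx],
                    labels[train_idx],
                    dataclasses.replace(fcm_config, seed=stage_seed),
                    dataclasses.replace(svm_config, seed=stage_seed),
                    feature_mode=cv_config.method,
                    transform_mode=cv_config.transform_mode,
                )
                scores = np.array(
                    [decision_score(model, descriptors[i]) for i in test_idx]
                )
                preds = (scores >= 0).astype(int)
                pooled_scores[test_idx] = scores
                pooled_pred[test_idx] = preds
                tp, fn, fp, tn = _confusion(labels[test_idx], preds)
                acc, sen, spe = _rates(tp, fn, fp, tn)
                if cv_config.auc_mode == "per_fold":
                    fold_aucs.append(
                        float(roc_auc_score(labels[test_idx], scores))
                    )
                fold_rows.append(
                    dict(
                        cell_size=cell_size, run=run, fold=fold,
                        tp=tp, fn=fn, fp=fp, tn=tn, acc=acc, sen=sen, spe=spe,
                    )
                )
            tp, fn, fp, tn = _confusion(labels, pooled_pred)
            acc, sen, spe = _rates(tp, fn, fp, tn)
            auc = (
                float(np.mean(fold_aucs))
                if cv_config.auc_mode == "per_fold"
                else float(roc_auc_score(labels, pooled_scores))
            )
            run_rows.append(
                dict(
                    cell_size=cell_size, run=run,
                    tp=tp, fn=fn, fp=fp, tn=tn,
                    acc=acc, sen=sen, spe=spe, auc=auc,
                )
            )

    fold_records = pd.DataFrame(fold_rows)
    run_metrics = pd.DataFrame(run_rows)

    agg_rows: list[dict] = []
    conf_rows: list[dict] = []
    for cell_size, group in run_metrics.groupby("cell_size"):
        for metric in METRICS:
            values = group[metric].to_numpy(dtype=float)
            sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
            agg_rows.append(
                dict(
                    cell_size=int(cell_size), metric=metric,
                    mean=float(values.mean()), sd=sd,
                )
            )
        # single printable matrix per cell size: element-wise median across
        # runs of the per-run (fold-summed) counts, rounded to integers
        conf_rows.append(
            dict(
                cell_size=int(cell_size),
                **{
                    k: int(round(float(group[k].median())))
                    for k in ("tp", "fn", "fp", "tn")
                },
            )
        )
    return CvResult(
        fold_records=fold_records,
        run_metrics=run_metrics,
        aggregates=pd.DataFrame(agg_rows),
        confusions=pd.DataFrame(conf_rows),
        configs=dict(
            cv=dataclasses.asdict(cv_config),
            hog=dataclasses.asdict(hog_config),
            fcm=dataclasses.asdict(fcm_config),
            svm=dataclasses.asdict(svm_config),
        ),
    )


def mean_metric(result: CvResult, metric: str, cell_size: int | None = None) -> float:
    """Mean of a metric across runs, at one cell size or over all of them."""
    sub = result.aggregates[result.aggregates["metric"] == metric]
    if cell_size is not None:
        sub = sub[sub["cell_size"] == cell_size]
    return float(sub["mean"].mean())


def report(result: CvResult, out_dir: str | Path) -> dict[str, Path]:
    """Write metric tables, confusion matrices, plots and a run manifest.

    CSV and JSON outputs are byte-deterministic for a fixed ``CvResult``.
    Returns the paths written, keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out / "metrics.csv",
        "run_metrics": out / "run_metrics.csv",
        "fold_records": out / "fold_records.csv",
        "confusion": out / "confusion_matrix.csv",
        "manifest": out / "manifest.json",
        "plot": out / "metrics_vs_cell_size.png",
    }
    fmt = "%.10g"
    result.aggregates.to_csv(paths["metrics"], index=False, float_format=fmt)
    result.run_metrics.to_csv(paths["run_metrics"], index=False, float_format=fmt)
    result.fold_records.to_csv(paths["fold_records"], index=False, float_format=fmt)
    result.confusions.to_csv(paths["confusion"], index=False)
    paths["manifest"].write_text(
        json.dumps(result.configs, indent=2, sort_keys=True) + "\n"
    )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for metric in METRICS:
        sub = result.aggregates[result.aggregates["metric"] == metric]
        sub = sub.sort_values("cell_size")
        ax.errorbar(
            sub["cell_size"], sub["mean"], yerr=sub["sd"],
            marker="o", capsize=3, label=metric.upper(),
        )
    ax.set_xlabel("cell size (pixels)")
    ax.set_ylabel("mean over runs")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(paths["plot"], dpi=100)
    plt.close(fig)
    return paths
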