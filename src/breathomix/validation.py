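"""Double (nested) cross-validation of the full pipeline and all metrics.

Outer folds estimate generalization; inner folds drive every model-selection
choice (scaling option, Tucker compressor, candidate networks, judge
assembly).  Nothing fitted ever sees an outer-test sample.  Pooled
out-of-fold predictive values are classified at threshold 0.00 and
summarized by sensitivity, specificity, accuracy, Matthews correlation,
ROC/AUC, and stratified bootstrap confidence intervals.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ann import Hyperparams, predict, train_mlp
from .core import Measurement, ScalingOption, apply_scaling, fit_scaling
from .judge import (
    AnnPool,
    InnerFoldFeatures,
    JudgeModel,
    PoolMember,
    brute_force_select,
    judge_predict,
    mcc_from_predictions,
)
from .tucker import TuckerModel, compress, fit_compressor

__all__ = [
    "PipelineConfig",
    "PredictionRecord",
    "ConfusionSummary",
    "ROCCurve",
    "FoldArtifacts",
    "DoubleCVResult",
    "stratified_folds",
    "double_cross_validate",
    "classify",
    "confusion_metrics",
    "roc_curve",
    "bootstrap_ci",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Model-selection search space and training settings for one run."""

    scaling_names: tuple[str, ...] = ("log_baseline_ratio", "per_measurement_minmax")
    rank_grid: tuple[tuple[int, int, int], ...] = ((4, 3, 2),)
    hidden_sizes: tuple[int, ...] = (4, 8)
    n_weight_seeds: int = 2
    top_m: int = 8
    allow_reuse: bool = False
    selection_metric: str = "mcc"
    threshold: float = 0.0
    learning_rate: float = 0.01
    epochs: int = 2000
    hooi_tol: float = 1e-7
    hooi_max_iter: int = 200
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if not self.scaling_names or not self.rank_grid or not self.hidden_sizes:
            raise ValueError("scaling, rank and hidden-size grids must be non-empty")
        if self.n_weight_seeds < 1:
            raise ValueError("at least one weight seed required")
        if not self.allow_reuse and len(self.hidden_sizes) * self.n_weight_seeds < 3:
            raise ValueError(
                "need at least 3 candidates per feature config for distinct "
                "committees; enlarge the grid or set allow_reuse=True"
            )


@dataclass(frozen=True)
class PredictionRecord:
    patient_id: str
    true_label: str
    value: float
    outer_fold: int
    predicted_label: str


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    threshold: float
    positive_class: str


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class FitConfigArtifacts:
    scaler: ScalingOption
    compressor: TuckerModel
    feature_mean: np.ndarray
    feature_std: np.ndarray


@dataclass
class FoldArtifacts:
    """Everything fitted on one outer-training fold, for audit and the
    leakage sentinel."""

    outer_fold: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    per_config: dict[str, FitConfigArtifacts]
    pool_tags: tuple
    pool_weight_digest: str
    judge: JudgeModel

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.per_config):
            art = self.per_config[name]
            h.update(name.encode())
            if art.scaler.sensor_mean is not None:
                h.update(np.ascontiguousarray(art.scaler.sensor_mean).tobytes())
                h.update(np.ascontiguousarray(art.scaler.sensor_std).tobytes())
            for f in art.compressor.factors:
                h.update(np.ascontiguousarray(f).tobytes())
            h.update(np.ascontiguousarray(art.feature_mean).tobytes())
            h.update(np.ascontiguousarray(art.feature_std).tobytes())
        h.update(repr(self.pool_tags).encode())
        h.update(self.pool_weight_digest.encode())
        h.update(self.judge.to_json().encode())
        return h.hexdigest()


@dataclass
class DoubleCVResult:
    records: list[PredictionRecord]
    folds: list[FoldArtifacts]
    positive_class: str
    negative_class: str
    seed: int


def stratified_folds(
    labels: Sequence[str], k: int, seed: int | np.random.SeedSequence
) -> list[np.ndarray]:
    """Seeded stratified k-fold: shuffle each class, deal round-robin.
    Returns k arrays of test indices partitioning range(n)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    n = len(labels)
    classes = set(labels.tolist())
    for f in folds:
        train_classes = set(labels[np.setdiff1d(np.arange(n), f)].tolist())
        if train_classes != classes:
            raise ValueError(
                f"a class is absent from a training fold at k={k}; use a smaller k"
            )
    return [np.array(sorted(f), dtype=int) for f in folds]


def _config_name(scaling: str, ranks: tuple[int, int, int]) -> str:
    return f"{scaling}|ranks{ranks[0]}-{ranks[1]}-{ranks[2]}"


def _fit_config(
    train_meas: Sequence[Measurement],
    scaling: str,
    ranks: tuple[int, int, int],
    cfg: PipelineConfig,
) -> tuple[FitConfigArtifacts, np.ndarray]:
    """Fit scaler + compressor + feature standardization on training
    measurements only; return artifacts and the training feature matrix."""
    scaler = fit_scaling(list(train_meas), scaling)
    scaled = [apply_scaling(scaler, m) for m in train_meas]
    comp = fit_compressor(scaled, ranks, tol=cfg.hooi_tol, max_iter=cfg.hooi_max_iter)
    X = np.stack([compress(comp, t) for t in scaled])
    if cfg.standardize_features:
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        std = np.where(std == 0, 1.0, std)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    X = (X - mean) / std
    return FitConfigArtifacts(scaler, comp, mean, std), X


def _transform(art: FitConfigArtifacts, measurements: Sequence[Measurement]) -> np.ndarray:
    X = np.stack(
        [compress(art.compressor, apply_scaling(art.scaler, m)) for m in measurements]
    )
    return (X - art.feature_mean) / art.feature_std


def _weight_seed(master: int, outer: int, cfg_name: str, hidden: int, si: int) -> int:
    ss = np.random.SeedSequence(
        [int(master), 3, int(outer), zlib.crc32(cfg_name.encode()), int(hidden), int(si)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def double_cross_validate(
    measurements: Sequence[Measurement],
    config: PipelineConfig = PipelineConfig(),
    outer_k: int = 10,
    inner_k: int = 5,
    seed: int = 0,
    positive_class: str | None = None,
) -> DoubleCVResult:
    """Run the full pipeline under double cross-validation.

    Per outer fold: scaling, Tucker compressor, candidate-network pool and
    judge assembly are all fitted/selected on the outer-training data (the
    judge via inner folds), then the held-out patients are scored exactly
    once.  Returns one pooled record per patient plus per-fold artifacts.
    """
    ids = [m.patient_id for m in measurements]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate patient_id {dup!r} in cohort")
    labels = [m.label for m in measurements]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"binary comparison requires exactly 2 classes, got {classes}")
    counts = {c: labels.count(c) for c in classes}
    if positive_class is None:
        # smaller class is "positive" by default
        positive_class = min(classes, key=lambda c: (counts[c], c))
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not in cohort classes {classes}")
    negative_class = next(c for c in classes if c != positive_class)

    y_all = np.array([1.0 if l == positive_class else -1.0 for l in labels])
    outer = stratified_folds(labels, outer_k, np.random.SeedSequence([int(seed), 1]))
    hp = Hyperparams(learning_rate=config.learning_rate, epochs=config.epochs)

    records: list[PredictionRecord] = []
    folds_art: list[FoldArtifacts] = []
    all_idx = np.arange(len(measurements))
    for fold_i, test_idx in enumerate(outer):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_meas = [measurements[i] for i in train_idx]
        test_meas = [measurements[i] for i in test_idx]
        y_train = y_all[train_idx]
        train_labels = [labels[i] for i in train_idx]

        inner = stratified_folds(
            train_labels, inner_k, np.random.SeedSequence([int(seed), 2, fold_i])
        )
        n_train = len(train_meas)

        # Inner-fold features per config (fitted on inner-training only).
        inner_folds: dict[str, list[InnerFoldFeatures]] = {}
        final_features: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        final_art: dict[str, FitConfigArtifacts] = {}
        for scaling in config.scaling_names:
            for ranks in config.rank_grid:
                name = _config_name(scaling, ranks)
                art, X_tr = _fit_config(train_meas, scaling, ranks, config)
                final_art[name] = art
                final_features[name] = (X_tr, y_train)
                per_fold = []
                for val_idx_local in inner:
                    tr_local = np.setdiff1d(np.arange(n_train), val_idx_local)
                    sub_train = [train_meas[i] for i in tr_local]
                    sub_val = [train_meas[i] for i in val_idx_local]
                    a, Xi = _fit_config(sub_train, scaling, ranks, config)
                    per_fold.append(
                        InnerFoldFeatures(
                            X_train=Xi,
                            y_train=y_train[tr_local],
                            X_val=_transform(a, sub_val),
                            y_val=y_train[val_idx_local],
                            val_idx=val_idx_local,
                        )
                    )
                inner_folds[name] = per_fold

        # Final candidate pool on full outer-training features.
        members = []
        for name in sorted(final_features):
            X, y = final_features[name]
            for h in config.hidden_sizes:
                for si in range(config.n_weight_seeds):
                    wseed = _weight_seed(seed, fold_i, name, h, si)
                    hp_h = Hyperparams(
                        hidden=h, learning_rate=hp.learning_rate, epochs=hp.epochs
                    )
                    members.append(
                        PoolMember(tag=(name, h, si), model=train_mlp(X, y, hp_h, seed=wseed))
                    )
        pool = AnnPool(members=members)

        def _train_candidate(tag, X, y, _fold=fold_i):
            name, h, si = tag
            wseed = _weight_seed(seed, _fold, name, h, si)
            hp_h = Hyperparams(hidden=h, learning_rate=hp.learning_rate, epochs=hp.epochs)
            return train_mlp(X, y, hp_h, seed=wseed)

        judge = brute_force_select(
            pool,
            inner_folds,
            top_m=config.top_m,
            allow_reuse=config.allow_reuse,
            metric=config.selection_metric,
            train_candidate=_train_candidate,
        )

        # Score the held-out patients once.
        X_test = _transform(final_art[judge.config_name], test_meas)
        values = judge_predict(judge, X_test)
        for m, v in zip(test_meas, np.atleast_1d(values)):
            records.append(
                PredictionRecord(
                    patient_id=m.patient_id,
                    true_label=m.label,
                    value=float(v),
                    outer_fold=fold_i,
                    predicted_label=classify(
                        float(v), config.threshold, positive_class, negative_class
                    ),
                )
            )

        wdigest = hashlib.sha256()
        for mem in pool.members:
            wdigest.update(np.ascontiguousarray(mem.model.w1).tobytes())
            wdigest.update(np.ascontiguousarray(mem.model.b1).tobytes())
            wdigest.update(np.ascontiguousarray(mem.model.w2).tobytes())
            wdigest.update(np.ascontiguousarray(mem.model.b2).tobytes())
        folds_art.append(
            FoldArtifacts(
                outer_fold=fold_i,
                train_ids=tuple(m.patient_id for m in train_meas),
                test_ids=tuple(m.patient_id for m in test_meas),
                per_config=final_art,
                pool_tags=tuple(mem.tag for mem in pool.members),
                pool_weight_digest=wdigest.hexdigest(),
                judge=judge,
            )
        )

    order = {pid: i for i, pid in enumerate(ids)}
    records.sort(key=lambda r: order[r.patient_id])
    return DoubleCVResult(
        records=records,
        folds=folds_art,
        positive_class=positive_class,
        negative_class=negative_class,
        seed=int(seed),
    )


def classify(value: float, threshold: float = 0.0, positive: str = "positive",
             negative: str = "negative") -> str:
    """Threshold rule: value >= threshold is the positive class (ties positive)."""
    return positive if value >= threshold else negative


def confusion_metrics(
    records: Sequence[PredictionRecord],
    positive_class: str,
    threshold: float = 0.0,
) -> ConfusionSummary:
    """Confusion counts and derived metrics at a predictive-value threshold.

    MCC uses the convention that a vanishing denominator factor gives 0.
    """
    truth = np.array([r.true_label == positive_class for r in records])
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present to compute a confusion summary")
    pred = np.array([r.value >= threshold for r in records])
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    n = tp + fp + fn + tn
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / n,
        mcc=mcc_from_predictions(pred, truth),
        threshold=threshold,
        positive_class=positive_class,
    )


def roc_curve(records: Sequence[PredictionRecord], positive_class: str) -> ROCCurve:
    """ROC by sweeping thresholds over the distinct predictive values
    (ties grouped); AUC by the trapezoidal rule."""
    values = np.array([r.value for r in records], dtype=float)
    truth = np.array([r.true_label == positive_class for r in records])
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-values, kind="stable")
    v_sorted = values[order]
    t_sorted = truth[order]
    # group ties
    distinct = np.r_[True, np.diff(v_sorted) != 0]
    group_end = np.r_[np.flatnonzero(distinct)[1:] - 1, len(v_sorted) - 1]
    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    tpr = np.r_[0.0, cum_tp[group_end] / n_pos, 1.0]
    fpr = np.r_[0.0, cum_fp[group_end] / n_neg, 1.0]
    thresholds = np.r_[np.inf, v_sorted[group_end], -np.inf]
    # drop a duplicated terminal point if the sweep already reached (1, 1)
    if tpr[-2] == 1.0 and fpr[-2] == 1.0:
        tpr, fpr, thresholds = tpr[:-1], fpr[:-1], thresholds[:-1]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


_METRICS: dict[str, Callable] = {
    "accuracy": lambda recs, pos, thr: confusion_metrics(recs, pos, thr).accuracy,
    "sensitivity": lambda recs, pos, thr: confusion_metrics(recs, pos, thr).sensitivity,
    "specificity": lambda recs, pos, thr: confusion_metrics(recs, pos, thr).specificity,
    "mcc": lambda recs, pos, thr: confusion_metrics(recs, pos, thr).mcc,
    "auc": lambda recs, pos, thr: roc_curve(recs, pos).auc,
}


def bootstrap_ci(
    records: Sequence[PredictionRecord],
    metric: str,
    positive_class: str,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    threshold: float = 0.0,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap over patients, stratified by class.

    Resamples with replacement within each class (so class sizes are
    preserved); a degenerate resample is redrawn up to ``max_redraws`` times.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    fn = _METRICS[metric]
    rng = np.random.default_rng(seed)
    pos_recs = [r for r in records if r.true_label == positive_class]
    neg_recs = [r for r in records if r.true_label != positive_class]
    if not pos_recs or not neg_recs:
        raise ValueError("both classes must be present")
    stats = np.empty(B)
    for b in range(B):
        for _ in range(max_redraws):
            sample = [pos_recs[i] for i in rng.integers(0, len(pos_recs), len(pos_recs))]
            sample += [neg_recs[i] for i in rng.integers(0, len(neg_recs), len(neg_recs))]
            try:
                stats[b] = fn(sample, positive_class, threshold)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(stats, alpha)),
        float(np.quantile(stats, 1.0 - alpha)),
    )


def records_to_dataframe(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "outer_fold": [r.outer_fold for r in records],
            "predictive_value": [r.value for r in records],
            "predicted_label": [r.predicted_label for r in records],
            "true_label": [r.true_label for r in records],
        }
    )
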