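"""Metrics, splits, and the repeated four-arm experiment.

The protocol mirrors a small-cohort diagnostic study: stratified 70/30
subject split, channel-flip augmentation of the training split only, training
on one of four input arms, and accuracy / sensitivity / specificity on the
untouched test split, averaged over independently re-drawn repeats.

Arms
----
``si_raw``   single-branch network on the raw matrices;
``si_norm``  single-branch on the min-max-normalized view;
``si_std``   single-branch on the standardized view;
``mi``       dual-branch network on (standardized, normalized).

PFPS (label 1) is the positive class throughout: sensitivity = TP/(TP+FN) is
the detection rate among patients, specificity = TN/(TN+FP) among pain-free
controls.  A zero denominator yields NaN (the undefined marker), which is
excluded from averages and counted, never silently turned into 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .augmentation import augment_training_set
from .data_io import LABEL_CONTROL, LABEL_PFPS, TrialCollection
from .errors import ContractError, StratificationError
from .model import ArchitectureSpec, ModelHandle, TrainSpec, build_model, predict, train
from .preprocessing import normalize_columns, standardize_columns

logger = logging.getLogger(__name__)

ARMS = ("si_raw", "si_norm", "si_std", "mi")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with PFPS as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def confusion(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Count the four outcomes; truth and prediction are {0,1} vectors."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ContractError("truth and prediction must be equal-length 1-D vectors")
    if not (np.isin(truth, (0, 1)).all() and np.isin(predicted, (0, 1)).all()):
        raise ContractError("classes must be 0 (control) or 1 (PFPS)")
    return ConfusionCounts(
        TP=int(((truth == 1) & (predicted == 1)).sum()),
        TN=int(((truth == 0) & (predicted == 0)).sum()),
        FP=int(((truth == 0) & (predicted == 1)).sum()),
        FN=int(((truth == 1) & (predicted == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN marks a zero denominator."""
    if counts.total == 0:
        raise ContractError("metrics are undefined for all-zero counts")
    accuracy = (counts.TP + counts.TN) / counts.total
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    sensitivity = counts.TP / pos if pos else math.nan
    specificity = counts.TN / neg if neg else math.nan
    return accuracy, sensitivity, specificity


# ---------------------------------------------------------------------------
# Splits


def _apportion(class_sizes: dict[int, int], train_total: int) -> dict[int, int]:
    """Largest-remainder apportionment of the training quota across classes."""
    n = sum(class_sizes.values())
    quotas = {c: s * train_total / n for c, s in class_sizes.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = train_total - sum(alloc.values())
    by_remainder = sorted(quotas, key=lambda c: (quotas[c] - alloc[c], c), reverse=True)
    for c in by_remainder[:leftover]:
        alloc[c] += 1
    # keep at least one subject of each class on both sides of the split
    for c, s in class_sizes.items():
        alloc[c] = min(max(alloc[c], 1), s - 1)
    return alloc


def split_70_30(
    collection: TrialCollection,
    seed: int,
    train_fraction: float = 0.7,
    stratify: bool = True,
) -> tuple[TrialCollection, TrialCollection]:
    """Random subject-level split, stratified by class by default.

    The training size is the train fraction of the cohort rounded half-up
    (70% of 41 -> 29), apportioned across classes by largest remainder.
    Disjoint, exhaustive, and reproducible for a given seed.
    """
    labels = collection.labels()
    counts = collection.class_counts()
    if stratify and (counts[LABEL_PFPS] < 2 or counts[LABEL_CONTROL] < 2):
        raise StratificationError(
            f"need at least 2 subjects per class to stratify, got {counts}"
        )
    n = len(collection)
    train_total = int(math.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    if stratify:
        alloc = _apportion(counts, train_total)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for c in sorted(alloc):
            members = np.flatnonzero(labels == c)
            perm = rng.permutation(members)
            train_idx.extend(perm[: alloc[c]].tolist())
            test_idx.extend(perm[alloc[c] :].tolist())
    else:
        perm = rng.permutation(n)
        train_idx = perm[:train_total].tolist()
        test_idx = perm[train_total:].tolist()
    train_idx.sort()
    test_idx.sort()
    return collection.subset(train_idx), collection.subset(test_idx)


def kfold(
    collection: TrialCollection, k: int = 10, seed: int = 0
) -> list[tuple[TrialCollection, TrialCollection]]:
    """Stratified k folds; every trial lands in exactly one validation fold.

    When k exceeds the smaller class count (e.g. leave-one-out, k = n) the
    folds are plain shuffled partitions, since stratification is impossible.
    """
    n = len(collection)
    if k > n:
        raise ContractError(f"k={k} exceeds the number of trials n={n}")
    if k < 2:
        raise ContractError("k must be at least 2")
    labels = collection.labels()
    min_class = min(np.bincount(labels, minlength=2)[np.bincount(labels, minlength=2) > 0])
    if k <= min_class:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    return [
        (collection.subset(tr.tolist()), collection.subset(va.tolist()))
        for tr, va in split_iter
    ]


# ---------------------------------------------------------------------------
# Experiment runner


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything defining one repeated four-arm comparison."""

    arms: tuple[str, ...] = ARMS
    repeats: int = 10
    base_seed: int = 0
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    train: TrainSpec = field(default_factory=TrainSpec)
    augment: bool = True
    flip_axis: str = "channels"
    stratify: bool = True
    train_fraction: float = 0.7
    ddof: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ContractError(f"unknown arm(s) {sorted(unknown)}; valid: {ARMS}")
        if self.repeats < 1:
            raise ContractError("repeats must be >= 1")


@dataclass
class EvalResult:
    """Headline metrics of one arm: the mean of the per-repeat values."""

    arm: str
    repeats: int
    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts
    per_repeat: list[dict]
    n_undefined: dict[str, int] = field(default_factory=dict)


def _arm_inputs(collection: TrialCollection, arm: str, ddof: int) -> list[np.ndarray]:
    """Stack the per-trial input views required by one arm."""
    raw = np.stack([t.values for t in collection])
    if arm == "si_raw":
        return [raw]
    std = np.stack([standardize_columns(t.values, ddof=ddof) for t in collection])
    if arm == "si_std":
        return [std]
    norm = np.stack([normalize_columns(t.values) for t in collection])
    if arm == "si_norm":
        return [norm]
    return [std, norm]  # mi: standardized branch first, normalized second


def _assert_no_leakage(train: TrialCollection, test: TrialCollection) -> None:
    train_sources = {t.source_subject_id for t in train}
    test_ids = {t.subject_id for t in test}
    if any(t.is_augmented_copy for t in test):
        raise ContractError("augmented copies may never enter a test split")
    overlap = train_sources & test_ids
    if overlap:
        raise ContractError(f"subjects {sorted(overlap)} appear in both splits")


def run_single(
    collection: TrialCollection, arm: str, config: ExperimentConfig, repeat: int
) -> tuple[dict, ModelHandle]:
    """One repeat of one arm: split, augment, train, evaluate on the test split."""
    seed = config.base_seed + repeat
    split_seed, init_seed, train_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(3)
    )
    train_coll, test_coll = split_70_30(
        collection, seed=split_seed, train_fraction=config.train_fraction,
        stratify=config.stratify,
    )
    if config.augment:
        train_coll = augment_training_set(train_coll, axis=config.flip_axis)
    _assert_no_leakage(train_coll, test_coll)

    arch = replace(config.architecture, n_branches=2 if arm == "mi" else 1)
    model = build_model(arch, n_channels=10, input_length=100, seed=init_seed)
    tspec = replace(config.train, seed=train_seed)
    train(model, _arm_inputs(train_coll, arm, config.ddof),
          train_coll.labels(), tspec)

    truth = test_coll.labels()
    predicted, _ = predict(model, _arm_inputs(test_coll, arm, config.ddof))
    counts = confusion(truth, predicted)
    accuracy, sensitivity, specificity = metrics(counts)
    row = {
        "arm": arm, "repeat": repeat, "seed": seed,
        "TP": counts.TP, "TN": counts.TN, "FP": counts.FP, "FN": counts.FN,
        "accuracy": accuracy, "sensitivity": sensitivity,
        "specificity": specificity,
        "final_loss": model.loss_history[-1] if model.loss_history else math.nan,
    }
    return row, model


def run_experiment(
    collection: TrialCollection, config: ExperimentConfig
) -> dict[str, EvalResult]:
    """The full protocol: every repeat re-draws the split, every arm trains.

    A failed repeat of an arm is logged and excluded from that arm's average;
    an arm whose repeats all fail is reported with NaN metrics, never
    silently dropped.
    """
    results: dict[str, EvalResult] = {}
    for arm in config.arms:
        rows: list[dict] = []
        total = ConfusionCounts(0, 0, 0, 0)
        for r in range(config.repeats):
            try:
                row, _ = run_single(collection, arm, config, r)
            except Exception:  # noqa: BLE001 - a repeat failure must not kill the run
                logger.exception("arm %s repeat %d failed", arm, r)
                rows.append({"arm": arm, "repeat": r, "seed": config.base_seed + r,
                             "error": True})
                continue
            rows.append(row)
            total = total + ConfusionCounts(row["TP"], row["TN"], row["FP"], row["FN"])
        ok = [row for row in rows if not row.get("error")]

        def _mean(key: str) -> float:
            vals = [row[key] for row in ok if not math.isnan(row[key])]
            return float(np.mean(vals)) if vals else math.nan

        results[arm] = EvalResult(
            arm=arm, repeats=config.repeats,
            accuracy=_mean("accuracy"), sensitivity=_mean("sensitivity"),
            specificity=_mean("specificity"),
            counts=total, per_repeat=rows,
            n_undefined={
                key: sum(1 for row in ok if math.isnan(row[key]))
                for key in ("sensitivity", "specificity")
            },
        )
    return results


def results_frame(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Per-repeat detail table (arm, repeat, counts, metrics, seed)."""
    rows = []
    for res in results.values():
        for row in res.per_repeat:
            rows.append({k: row.get(k) for k in (
                "arm", "repeat", "TP", "TN", "FP", "FN",
                "accuracy", "sensitivity", "specificity", "seed")})
    return pd.DataFrame(rows)


def summary_frame(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Per-arm mean metrics, formatted like a results table."""
    return pd.DataFrame([
        {"arm": res.arm, "accuracy": res.accuracy,
         "sensitivity": res.sensitivity, "specificity": res.specificity,
         "repeats": res.repeats}
        for res in results.values()
    ])


HYPERPARAMETER_GRID = {
    "dropout_rate": (0.2, 0.3, 0.5),
    "conv_blocks_per_branch": (1, 2, 3),
}


def select_hyperparameters(
    train_coll: TrialCollection,
    arm: str,
    config: ExperimentConfig,
    k: int = 10,
    grid: dict = HYPERPARAMETER_GRID,
) -> ArchitectureSpec:
    """Optional k-fold model selection over a small grid, within the training split.

    Returns the architecture with the best mean validation accuracy; ties go
    to the first grid point in iteration order.  The default experiment skips
    this stage and uses the stated hyperparameters directly.
    """
    best_arch, best_score = None, -math.inf
    folds = kfold(train_coll, k=min(k, len(train_coll)), seed=config.base_seed)
    for dropout in grid["dropout_rate"]:
        for blocks in grid["conv_blocks_per_branch"]:
            arch = replace(
                config.architecture, dropout_rate=dropout,
                conv_blocks_per_branch=blocks,
                n_branches=2 if arm == "mi" else 1,
            )
            accs = []
            for fold_idx, (tr, va) in enumerate(folds):
                model = build_model(arch, seed=config.base_seed + fold_idx)
                tspec = replace(config.train, seed=config.base_seed + fold_idx)
                train(model, _arm_inputs(tr, arm, config.ddof), tr.labels(), tspec)
                pred, _ = predict(model, _arm_inputs(va, arm, config.ddof))
                accs.append(float((pred == va.labels()).mean()))
            score = float(np.mean(accs))
            if score > best_score:
                best_arch, best_score = arch, score
    return best_arch
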