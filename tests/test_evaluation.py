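"""Confusion counts, diagnostic metrics, splits, and the experiment runner."""

import math

import numpy as np
import pytest

from micnn.data_io import TrialCollection
from micnn.errors import ContractError, StratificationError
from micnn.evaluation import (
    ConfusionCounts,
    ExperimentConfig,
    confusion,
    kfold,
    metrics,
    results_frame,
    run_experiment,
    run_single,
    split_70_30,
    summary_frame,
)
from micnn.model import TrainSpec
from micnn.synthetic_data import SimulationSpec, generate_collection

FAST_TRAIN = TrainSpec(iterations=60, learning_rate=1e-4)


def test_confusion_enumerates_four_cases():
    c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
    assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)


def test_confusion_perfect_and_boundary():
    c = confusion([1, 0, 1], [1, 0, 1])
    assert c.FP == c.FN == 0
    c = confusion([0, 0, 0], [1, 1, 1])
    assert (c.FP, c.TP, c.TN, c.FN) == (3, 0, 0, 0)


def test_confusion_rejects_length_mismatch():
    with pytest.raises(ContractError):
        confusion([1, 0], [1])


def test_metrics_hand_values():
    assert metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0)) == (1.0, 1.0, 1.0)
    acc, sens, spec = metrics(ConfusionCounts(TP=3, TN=1, FP=1, FN=0))
    assert (acc, sens, spec) == pytest.approx((0.8, 1.0, 0.5))


def test_metrics_undefined_marker_not_exception():
    acc, sens, spec = metrics(ConfusionCounts(TP=0, TN=4, FP=1, FN=0))
    assert math.isnan(sens) and spec == 0.8
    with pytest.raises(ContractError):
        metrics(ConfusionCounts(0, 0, 0, 0))


def test_accuracy_identity():
    c = ConfusionCounts(TP=5, TN=3, FP=2, FN=1)
    acc, _, _ = metrics(c)
    assert acc * c.total == c.TP + c.TN


# ---------------------------------------------------------------------------
# Splits


def test_split_sizes_and_stratification(default_cohort):
    train, test = split_70_30(default_cohort, seed=0)
    assert (len(train), len(test)) == (29, 12)
    assert train.class_counts() == {1: 18, 0: 11}
    assert test.class_counts() == {1: 8, 0: 4}
    assert set(train.subject_ids()).isdisjoint(test.subject_ids())
    assert sorted(train.subject_ids() + test.subject_ids()) == sorted(
        default_cohort.subject_ids())


def test_split_deterministic_given_seed(default_cohort):
    a = split_70_30(default_cohort, seed=42)
    b = split_70_30(default_cohort, seed=42)
    assert a[0].subject_ids() == b[0].subject_ids()
    assert a[1].subject_ids() == b[1].subject_ids()
    c = split_70_30(default_cohort, seed=43)
    assert c[0].subject_ids() != a[0].subject_ids()


def test_split_requires_both_classes():
    coll = generate_collection(SimulationSpec(n_pfps=5, n_control=0, seed=0))
    with pytest.raises(StratificationError):
        split_70_30(coll, seed=0)


def test_kfold_partitions(default_cohort):
    folds = kfold(default_cohort, k=10, seed=1)
    assert len(folds) == 10
    val_ids = [sid for _, va in folds for sid in va.subject_ids()]
    assert sorted(val_ids) == sorted(default_cohort.subject_ids())
    sizes = [len(va) for _, va in folds]
    assert max(sizes) - min(sizes) <= 1


def test_kfold_equal_folds_counting():
    coll = generate_collection(SimulationSpec(n_pfps=24, n_control=16, seed=2))
    folds = kfold(coll, k=10, seed=0)
    assert all(len(va) == 4 for _, va in folds)


def test_kfold_leave_one_out_boundary():
    coll = generate_collection(SimulationSpec(n_pfps=4, n_control=4, seed=1))
    folds = kfold(coll, k=len(coll), seed=0)
    assert len(folds) == 8 and all(len(va) == 1 for _, va in folds)


def test_kfold_k_larger_than_n_rejected(default_cohort):
    with pytest.raises(ContractError):
        kfold(default_cohort, k=42, seed=0)


# ---------------------------------------------------------------------------
# Experiment runner (reduced problem sizes; the full protocol runs in the
# acceptance tests)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_collection(SimulationSpec(n_pfps=12, n_control=8,
                                              effect_size=3.0, seed=5))


def test_run_single_no_leakage_and_counts(small_cohort):
    cfg = ExperimentConfig(arms=("mi",), repeats=1, train=FAST_TRAIN)
    row, model = run_single(small_cohort, "mi", cfg, repeat=0)
    assert row["TP"] + row["TN"] + row["FP"] + row["FN"] == 6  # 30% of 20
    assert model.input_arity == 2


def test_experiment_reproducible_and_aggregated(small_cohort):
    cfg = ExperimentConfig(arms=("si_std",), repeats=2, base_seed=11,
                           train=FAST_TRAIN)
    res1 = run_experiment(small_cohort, cfg)
    res2 = run_experiment(small_cohort, cfg)
    r1, r2 = res1["si_std"], res2["si_std"]
    assert [x["accuracy"] for x in r1.per_repeat] == [x["accuracy"] for x in r2.per_repeat]
    assert r1.repeats == 2
    per = [x["accuracy"] for x in r1.per_repeat]
    assert r1.accuracy == pytest.approx(np.mean(per), abs=1e-12)


def test_metrics_invariant_under_subject_relabeling(small_cohort):
    cfg = ExperimentConfig(arms=("si_norm",), repeats=1, train=FAST_TRAIN)
    renamed = TrialCollection(
        trials=tuple(
            t.with_values(t.values, subject_id=f"x{i:03d}")
            for i, t in enumerate(small_cohort)
        ),
        condition=small_cohort.condition,
    )
    row1, _ = run_single(small_cohort, "si_norm", cfg, repeat=0)
    row2, _ = run_single(renamed, "si_norm", cfg, repeat=0)
    for key in ("TP", "TN", "FP", "FN"):
        assert row1[key] == row2[key]


def test_frames_have_expected_shape(small_cohort):
    cfg = ExperimentConfig(arms=("si_raw", "mi"), repeats=2, train=FAST_TRAIN)
    res = run_experiment(small_cohort, cfg)
    detail = results_frame(res)
    assert len(detail) == 4
    assert set(["arm", "repeat", "TP", "accuracy", "seed"]).issubset(detail.columns)
    summary = summary_frame(res)
    assert list(summary["arm"]) == ["si_raw", "mi"]
    for res_arm in res.values():
        acc, *_ = metrics(res_arm.counts)  # pooled counts stay consistent
        assert 0.0 <= acc <= 1.0
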