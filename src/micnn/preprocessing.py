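"""Per-subject, per-channel standardization and min-max normalization.

Joint angles span tens of degrees while rectified sEMG envelopes live on
channel-specific scales that can differ by orders of magnitude; feeding the
raw matrix to a network lets the large-scale channels dominate the loss.
Two rescalings address this, each applied to every column of every subject's
matrix independently (no statistic is ever pooled across subjects, so the
training and test sets share nothing):

* standardization: ``x -> (x - mean) / std`` giving zero mean and unit
  variance per column (population std, divide-by-n, by default);
* min-max normalization: ``x -> (x - min) / (max - min)`` mapping each
  column onto [0, 1].

A :class:`DualViewTrial` holds both views of one trial; the two views are the
two input branches of the multi-input network.

Degenerate (constant) columns would divide by zero; they map to all zeros
under standardization and to all 0.5 under normalization, and the event is
logged rather than raised so a flat channel never aborts a training run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import GaitTrial

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnStats:
    """Per-column summary backing both rescalings."""

    mean: float
    std: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("column stats must satisfy min <= mean <= max")
        if self.std < 0:
            raise ValueError("std must be non-negative")

    @property
    def is_constant(self) -> bool:
        return self.min == self.max


@dataclass(frozen=True)
class DualViewTrial:
    """A trial with its standardized and normalized views and column stats."""

    source: GaitTrial
    standardized: np.ndarray
    normalized: np.ndarray
    stats: tuple[ColumnStats, ...]


def column_stats(matrix: np.ndarray, ddof: int = 0) -> list[ColumnStats]:
    """Per-column mean, standard deviation (population by default), min, max."""
    matrix = np.asarray(matrix, dtype=float)
    means = matrix.mean(axis=0)
    stds = matrix.std(axis=0, ddof=ddof)
    mins = matrix.min(axis=0)
    maxs = matrix.max(axis=0)
    return [
        ColumnStats(mean=float(m), std=float(s), min=float(lo), max=float(hi))
        for m, s, lo, hi in zip(means, stds, mins, maxs)
    ]


def standardize_columns(matrix: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Center and scale each column to zero mean, unit variance.

    ``ddof=0`` (population std) is the default; ``ddof=1`` selects the sample
    form.  Constant columns become all zeros.
    """
    matrix = np.asarray(matrix, dtype=float)
    means = matrix.mean(axis=0, keepdims=True)
    stds = matrix.std(axis=0, ddof=ddof, keepdims=True)
    constant = stds[0] == 0.0
    if np.any(constant):
        logger.info(
            "standardize: %d constant column(s) mapped to zeros", int(constant.sum())
        )
    safe = np.where(stds == 0.0, 1.0, stds)
    out = (matrix - means) / safe
    out[:, constant] = 0.0
    return out


def normalize_columns(matrix: np.ndarray) -> np.ndarray:
    """Rescale each column onto [0, 1] by its own min and max.

    Constant columns become all 0.5, the least-informative value in [0, 1].
    """
    matrix = np.asarray(matrix, dtype=float)
    mins = matrix.min(axis=0, keepdims=True)
    maxs = matrix.max(axis=0, keepdims=True)
    span = maxs - mins
    constant = span[0] == 0.0
    if np.any(constant):
        logger.info(
            "normalize: %d constant column(s) mapped to 0.5", int(constant.sum())
        )
    safe = np.where(span == 0.0, 1.0, span)
    out = (matrix - mins) / safe
    out[:, constant] = 0.5
    return out


def preprocess_trial(trial: GaitTrial, ddof: int = 0) -> DualViewTrial:
    """Compute both views of one trial from that trial's own columns only."""
    return DualViewTrial(
        source=trial,
        standardized=standardize_columns(trial.values, ddof=ddof),
        normalized=normalize_columns(trial.values),
        stats=tuple(column_stats(trial.values, ddof=ddof)),
    )
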