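"""Trial/cohort data model and on-disk CSV format.

A *trial* is one subject's time-normalized gait cycle: a 100 x 10 matrix whose
rows are samples at 0..99 % of the cycle and whose columns are, in canonical
order, three lower-limb joint angles (hip flexion HF, knee flexion KF, ankle
dorsiflexion ADF, in degrees, possibly negative) followed by seven rectified
sEMG envelopes (SEB, REF, VL, VM, BIF, MG, LG, non-negative by construction).

On disk a trial is a plain CSV with a mandatory header of the ten channel
names and exactly 100 numeric rows; a cohort is a manifest CSV with columns
``subject_id,label,condition,file`` where label is 1 for PFPS (the positive
class) and 0 for pain-free control, and condition is ``walking`` or
``running``.  The header is validated and columns are reordered to canonical
order on read, so a column swap on disk can never silently exchange an angle
for an sEMG channel.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConditionMismatchError,
    DuplicateSubjectError,
    MalformedTrialError,
    SchemaError,
    TrialParseError,
)

N_SAMPLES = 100
N_CHANNELS = 10

#: Suffix appended to subject ids of channel-flipped augmentation copies.
AUGMENTED_SUFFIX = "+flip"

Condition = Literal["walking", "running"]
Provenance = Literal["raw", "preprocessed", "augmented"]

CONDITIONS = ("walking", "running")
LABEL_PFPS = 1
LABEL_CONTROL = 0


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel identifiers with their kind (angle vs sEMG).

    The default instance is the canonical ten-channel layout; the first three
    channels are joint angles and the remaining seven are sEMG envelopes.
    """

    names: tuple[str, ...] = (
        "HF", "KF", "ADF", "SEB", "REF", "VL", "VM", "BIF", "MG", "LG",
    )
    kinds: tuple[str, ...] = ("angle",) * 3 + ("semg",) * 7

    def __post_init__(self) -> None:
        if len(self.names) != N_CHANNELS or len(self.kinds) != N_CHANNELS:
            raise SchemaError(f"a channel set must have exactly {N_CHANNELS} channels")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("channel names must be unique")
        if self.kinds[:3] != ("angle",) * 3 or self.kinds[3:] != ("semg",) * 7:
            raise SchemaError("first 3 channels must be angles, last 7 sEMG")

    @property
    def angle_indices(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == "angle")

    @property
    def semg_indices(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == "semg")


CANONICAL_CHANNELS = ChannelSet()


@dataclass(frozen=True)
class GaitTrial:
    """One subject's gait-cycle matrix with its label and movement condition.

    ``values`` has shape (100, 10): rows are time samples across the cycle,
    columns follow :data:`CANONICAL_CHANNELS` order.
    """

    subject_id: str
    label: int
    condition: str
    values: np.ndarray
    channels: ChannelSet = field(default=CANONICAL_CHANNELS, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SAMPLES, N_CHANNELS):
            raise MalformedTrialError(
                f"trial {self.subject_id!r}: expected a {N_SAMPLES}x{N_CHANNELS} "
                f"matrix, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise MalformedTrialError(
                f"trial {self.subject_id!r}: matrix contains non-finite values"
            )
        if self.label not in (LABEL_CONTROL, LABEL_PFPS):
            raise SchemaError(f"label must be 0 (control) or 1 (PFPS), got {self.label!r}")
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def is_augmented_copy(self) -> bool:
        return self.subject_id.endswith(AUGMENTED_SUFFIX)

    @property
    def source_subject_id(self) -> str:
        """Subject id with any augmentation suffix stripped."""
        sid = self.subject_id
        return sid[: -len(AUGMENTED_SUFFIX)] if sid.endswith(AUGMENTED_SUFFIX) else sid

    def validate_raw(self) -> None:
        """Check the rectified-signal invariant: sEMG columns non-negative."""
        semg = self.values[:, list(self.channels.semg_indices)]
        if np.any(semg < 0):
            r, c = np.argwhere(semg < 0)[0]
            name = self.channels.names[self.channels.semg_indices[c]]
            raise MalformedTrialError(
                f"trial {self.subject_id!r}: raw sEMG channel {name} has a negative "
                f"value at sample {r}; rectified signals must be non-negative"
            )

    def with_values(self, values: np.ndarray, subject_id: str | None = None) -> "GaitTrial":
        return replace(
            self, values=values,
            subject_id=self.subject_id if subject_id is None else subject_id,
        )


@dataclass(frozen=True)
class TrialCollection:
    """A labeled cohort sharing one movement condition.

    The unit of splitting, augmentation, and training.  Subject ids (with
    their augmentation suffix, if any) must be unique.
    """

    trials: tuple[GaitTrial, ...]
    condition: str
    provenance: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        if self.provenance not in ("raw", "preprocessed", "augmented"):
            raise SchemaError(f"unknown provenance {self.provenance!r}")
        for t in self.trials:
            if t.condition != self.condition:
                raise ConditionMismatchError(
                    f"trial {t.subject_id!r} has condition {t.condition!r} but the "
                    f"collection is tagged {self.condition!r}"
                )
        ids = [t.subject_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DuplicateSubjectError(
                f"duplicate subject id {dup!r} within condition {self.condition!r}"
            )
        if self.provenance == "raw":
            for t in self.trials:
                t.validate_raw()

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[GaitTrial]:
        return iter(self.trials)

    def class_counts(self) -> dict[int, int]:
        counts = {LABEL_CONTROL: 0, LABEL_PFPS: 0}
        for t in self.trials:
            counts[t.label] += 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=int)

    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.trials]

    def subset(self, indices: Sequence[int]) -> "TrialCollection":
        return TrialCollection(
            trials=tuple(self.trials[i] for i in indices),
            condition=self.condition,
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_trial_table(text: str, path: str) -> np.ndarray:
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MalformedTrialError(f"{path}: empty trial file")
    header = [h.strip() for h in lines[0].split(",")]
    canonical = list(CANONICAL_CHANNELS.names)
    unknown = [h for h in header if h not in canonical]
    if unknown:
        raise SchemaError(f"{path}: unknown channel name(s) {unknown} in header")
    if sorted(header) != sorted(canonical):
        raise SchemaError(
            f"{path}: header must contain each of the {N_CHANNELS} canonical "
            f"channel names exactly once, got {header}"
        )
    n_rows = len(lines) - 1
    if n_rows != N_SAMPLES:
        raise MalformedTrialError(
            f"{path}: expected {N_SAMPLES} data rows, found {n_rows}"
        )
    matrix = np.empty((N_SAMPLES, N_CHANNELS), dtype=float)
    for r, line in enumerate(lines[1:]):
        cells = line.split(",")
        if len(cells) != N_CHANNELS:
            raise MalformedTrialError(
                f"{path}: row {r + 1} has {len(cells)} fields, expected {N_CHANNELS}"
            )
        for c, cell in enumerate(cells):
            try:
                matrix[r, c] = float(cell)
            except ValueError:
                raise TrialParseError(
                    f"{path}: non-numeric value {cell.strip()!r} at data row "
                    f"{r + 1}, column {header[c]!r}"
                ) from None
    # reorder on-disk column order to canonical order
    order = [header.index(name) for name in canonical]
    return matrix[:, order]


def read_trial(
    path: str | os.PathLike[str],
    subject_id: str,
    label: int,
    condition: str,
) -> GaitTrial:
    """Read one trial CSV, validating shape and header, reordering columns.

    Raises :class:`MalformedTrialError` for a wrong row/column count,
    :class:`TrialParseError` for a non-numeric cell (with its position) and
    :class:`SchemaError` for an unknown header name.
    """
    path = Path(path)
    matrix = _parse_trial_table(path.read_text(), str(path))
    return GaitTrial(subject_id=subject_id, label=label, condition=condition, values=matrix)


def write_trial(trial: GaitTrial, path: str | os.PathLike[str]) -> Path:
    """Write a trial as header + 100 rows at full double precision."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(",".join(trial.channels.names) + "\n")
    for row in trial.values:
        buf.write(",".join(repr(float(x)) for x in row) + "\n")
    path.write_text(buf.getvalue())
    return path


MANIFEST_COLUMNS = ["subject_id", "label", "condition", "file"]


def read_collection(
    manifest_path: str | os.PathLike[str],
    provenance: str = "raw",
) -> TrialCollection:
    """Read a cohort from a manifest CSV, preserving manifest row order.

    Every manifest must name exactly one condition; mixing walking and
    running rows raises :class:`ConditionMismatchError`.  The empty manifest
    (header only) yields an empty walking collection.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"subject_id": str, "file": str})
    if list(df.columns) != MANIFEST_COLUMNS:
        raise SchemaError(
            f"{manifest_path}: manifest columns must be {MANIFEST_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if len(df) == 0:
        return TrialCollection(trials=(), condition="walking", provenance=provenance)
    conditions = df["condition"].unique().tolist()
    if len(conditions) > 1:
        raise ConditionMismatchError(
            f"{manifest_path}: manifest mixes conditions {conditions}; one "
            "manifest per condition is required"
        )
    trials = []
    for i, row in df.iterrows():
        fpath = manifest_path.parent / row["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"{manifest_path}: row {i + 1} (subject {row['subject_id']!r}) "
                f"references missing file {fpath}"
            )
        trials.append(
            read_trial(fpath, subject_id=row["subject_id"],
                       label=int(row["label"]), condition=row["condition"])
        )
    return TrialCollection(trials=tuple(trials), condition=conditions[0],
                           provenance=provenance)


def write_collection(
    collection: TrialCollection,
    out_dir: str | os.PathLike[str],
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write one CSV per trial plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in collection:
        fname = f"{t.subject_id}_{t.condition}.csv"
        write_trial(t, out_dir / fname)
        rows.append({"subject_id": t.subject_id, "label": t.label,
                     "condition": t.condition, "file": fname})
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
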