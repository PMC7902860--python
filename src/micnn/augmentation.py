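"""Training-set doubling by flipping the channel axis of each trial matrix.

Treating a subject's 100 x 10 gait matrix like an image, mirroring it
horizontally reverses the channel (column) order while leaving each time
sample in place.  Because the ten biomechanical channels carry no positional
ordering the mirrored matrix is an equally valid sample of the same class,
so appending the flipped copy of every training trial doubles the training
set without touching its class balance.  Flipping the time axis instead is
available for ablation but is off by default: gait samples are strongly
ordered in time.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .data_io import AUGMENTED_SUFFIX, GaitTrial, TrialCollection
from .errors import AugmentationStateError

FlipAxis = Literal["channels", "time"]


def flip_channels(trial: GaitTrial, axis: FlipAxis = "channels") -> GaitTrial:
    """Return an augmentation copy with the chosen axis reversed.

    Column j of the output equals column 9-j of the input (``axis="channels"``,
    the default); label and condition are preserved and the subject id gains
    the augmentation suffix so leakage checks can trace the copy to its source.
    """
    if axis == "channels":
        flipped = trial.values[:, ::-1]
    elif axis == "time":
        flipped = trial.values[::-1, :]
    else:
        raise ValueError(f"unknown flip axis {axis!r}")
    return trial.with_values(
        np.ascontiguousarray(flipped),
        subject_id=trial.subject_id + AUGMENTED_SUFFIX,
    )


def augment_training_set(
    train: TrialCollection, axis: FlipAxis = "channels"
) -> TrialCollection:
    """Append the flipped copy of every trial; size exactly doubles.

    Only a raw or preprocessed collection may be augmented; doubling an
    already-augmented one would silently quadruple the originals.
    """
    if train.provenance == "augmented":
        raise AugmentationStateError("collection is already augmented")
    flipped = [flip_channels(t, axis=axis) for t in train]
    return TrialCollection(
        trials=tuple(train.trials) + tuple(flipped),
        condition=train.condition,
        provenance="augmented",
    )
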