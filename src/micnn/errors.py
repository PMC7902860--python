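"""Exception hierarchy for the gait-classification pipeline.

Every error raised on purpose by this package derives from :class:`MicnnError`
so callers can catch pipeline failures without swallowing programming errors.
"""


class MicnnError(Exception):
    """Base class for all package-specific errors."""


class MalformedTrialError(MicnnError, ValueError):
    """A trial file or matrix has the wrong shape or invalid values."""


class TrialParseError(MicnnError, ValueError):
    """A trial file contains a non-numeric cell; message carries row/column."""


class SchemaError(MicnnError, ValueError):
    """A header or manifest column does not match the expected schema."""


class DuplicateSubjectError(MicnnError, ValueError):
    """The same subject id appears twice within one condition."""


class ConditionMismatchError(MicnnError, ValueError):
    """Trials with different condition tags were mixed in one collection."""


class AugmentationStateError(MicnnError, ValueError):
    """Augmentation applied to an already-augmented collection."""


class ArchitectureError(MicnnError, ValueError):
    """A layer chain collapses the temporal axis to length < 1."""


class ArityError(MicnnError, ValueError):
    """Number of input views does not match the model's branch count."""


class TrainingDivergedError(MicnnError, RuntimeError):
    """Loss became non-finite during training; carries the iteration index."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"training loss became non-finite at iteration {iteration}")


class StratificationError(MicnnError, ValueError):
    """A class is absent, making a stratified split impossible."""


class ContractError(MicnnError, ValueError):
    """Generic precondition violation (length mismatch, empty counts, ...)."""
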