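"""Seeded synthetic gait cohorts with the structure of the real recordings.

No distributional parameters of the original cohort are published, so the
generator aims for qualitative fidelity only: smooth bipolar joint-angle
curves spanning tens of degrees, non-negative bursty sEMG envelopes on
channel-specific scales differing by orders of magnitude, 100 samples per
cycle, and a tunable between-class effect.  It exists so that every stage of
the pipeline — I/O, preprocessing, augmentation, training, evaluation — is
exercisable end to end without any external download.

Signal model
------------
Angle channels are low-order sinusoid mixtures of the cycle phase (period =
100 samples) within physiological degree ranges; sEMG channels are sums of
one or two Gaussian activation bursts with channel-specific timing, scaled
per channel, with additive Gaussian noise clipped at zero so the rectified-
signal invariant holds by construction.

The class effect (scaled by ``effect_size``; 0 makes the two classes
identically distributed) follows the vastus-involvement theme of the PFPS
literature as a modeling convenience, not a biological claim: affected
subjects get a knee-flexion offset, delayed vastus-medialis bursts, an
advanced vastus-lateralis burst, and a stronger VM second burst relative to
its first.  Timing and within-channel amplitude-ratio shifts survive both
per-subject rescalings, while the angle offset is only visible in raw data.

All randomness flows from one root seed through per-subject
``SeedSequence(seed, subject_index, label)`` streams, so enlarging a cohort
never reshuffles existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import GaitTrial, TrialCollection

TWO_PI = 2.0 * np.pi

#: Per-sEMG-channel output scales (arbitrary units) emulating the large
#: scale disparity between recorded envelope channels.
DEFAULT_SEMG_SCALES = {
    "SEB": 0.05, "REF": 0.5, "VL": 5.0, "VM": 20.0,
    "BIF": 80.0, "MG": 200.0, "LG": 500.0,
}

#: (amplitude 0..1, burst center in cycle %, burst width in cycle %) per
#: channel; VM and VL get a second burst so within-channel amplitude ratios
#: can carry a class effect that survives min-max normalization.
_SEMG_BURSTS = {
    "SEB": [(1.0, 8.0, 6.0), (0.5, 92.0, 5.0)],
    "REF": [(1.0, 12.0, 7.0)],
    "VL":  [(1.0, 15.0, 6.0), (0.45, 88.0, 5.0)],
    "VM":  [(1.0, 15.0, 6.0), (0.45, 90.0, 5.0)],
    "BIF": [(1.0, 95.0, 6.0)],
    "MG":  [(1.0, 40.0, 8.0)],
    "LG":  [(1.0, 42.0, 8.0), (0.3, 5.0, 5.0)],
}


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort-level generator settings.

    ``effect_size`` multiplies every between-class difference; at 0 the two
    class-conditional distributions coincide exactly.  ``noise_sd`` is the
    Gaussian noise standard deviation as a fraction of each channel's
    deterministic amplitude.
    """

    n_pfps: int = 26
    n_control: int = 15
    condition: str = "walking"
    effect_size: float = 1.0
    noise_sd: float = 0.1
    angle_amplitude_deg: dict = field(default_factory=lambda: {
        "HF": (-20.0, 40.0), "KF": (0.0, 70.0), "ADF": (-15.0, 20.0),
    })
    semg_scale: dict = field(default_factory=lambda: dict(DEFAULT_SEMG_SCALES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _angle_channel(name: str, t: np.ndarray, spec: SimulationSpec,
                   rng: np.random.Generator, pfps: bool) -> np.ndarray:
    """One joint-angle curve in degrees with subject-level phase jitter."""
    lo, hi = spec.angle_amplitude_deg[name]
    center, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    phase = TWO_PI * t / 100.0
    jitter = rng.normal(0.0, 0.08)
    if name == "HF":
        curve = center + 0.8 * amp * np.cos(phase + 0.2 + jitter)
    elif name == "KF":
        # double-peaked knee flexion: loading response + swing peak
        curve = (center - 0.15 * amp
                 + 0.25 * amp * np.sin(phase + 0.3 + jitter)
                 - 0.55 * amp * np.cos(2 * phase - 0.5 + jitter))
        if pfps:
            curve = curve + 3.0 * spec.effect_size  # degrees of extra flexion
    else:  # ADF
        curve = center + 0.75 * amp * np.sin(phase + 1.0 + jitter)
    noise = rng.normal(0.0, spec.noise_sd * amp, size=t.shape)
    return curve + noise


def _semg_channel(name: str, t: np.ndarray, spec: SimulationSpec,
                  rng: np.random.Generator, pfps: bool) -> np.ndarray:
    """One rectified envelope: Gaussian bursts, scaled, noised, clipped at 0."""
    e = spec.effect_size
    envelope = np.zeros_like(t, dtype=float)
    for j, (amp, center, width) in enumerate(_SEMG_BURSTS[name]):
        amp = amp * float(np.exp(rng.normal(0.0, 0.15)))
        center = center + rng.normal(0.0, 1.5)
        if pfps:
            if name == "VM":
                center += 5.0 * e        # delayed vastus medialis onset
                if j == 1:
                    amp *= 1.0 + 0.35 * e  # stronger second burst
            elif name == "VL":
                center -= 3.0 * e        # advanced vastus lateralis onset
        d = t - center
        d = (d + 50.0) % 100.0 - 50.0  # cyclic distance within the gait cycle
        envelope += amp * np.exp(-0.5 * (d / width) ** 2)
    scale = spec.semg_scale[name]
    envelope *= scale
    envelope += rng.normal(0.0, spec.noise_sd * scale, size=t.shape)
    return np.clip(envelope, 0.0, None)


def generate_trial(label: int, spec: SimulationSpec, subject_index: int) -> GaitTrial:
    """One 100 x 10 trial, fully reproducible from (seed, subject_index, label)."""
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, subject_index, label))
    )
    t = np.arange(100, dtype=float)
    pfps = label == 1
    columns = []
    for name in ("HF", "KF", "ADF"):
        columns.append(_angle_channel(name, t, spec, rng, pfps))
    for name in ("SEB", "REF", "VL", "VM", "BIF", "MG", "LG"):
        columns.append(_semg_channel(name, t, spec, rng, pfps))
    prefix = "pfps" if pfps else "ctrl"
    return GaitTrial(
        subject_id=f"{prefix}{subject_index:03d}",
        label=label,
        condition=spec.condition,
        values=np.column_stack(columns),
    )


def generate_collection(spec: SimulationSpec) -> TrialCollection:
    """A cohort of ``n_pfps + n_control`` trials with sequential subject ids."""
    trials = [generate_trial(1, spec, i) for i in range(spec.n_pfps)]
    trials += [generate_trial(0, spec, i) for i in range(spec.n_control)]
    return TrialCollection(trials=tuple(trials), condition=spec.condition,
                           provenance="raw")
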