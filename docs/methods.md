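# Methods

## Problem and data model

The package classifies subjects as patellofemoral pain syndrome (PFPS,
label 1) or pain-free control (label 0) from one time-normalized gait
cycle per subject and movement condition (walking or running).  A trial is
a 100 × 10 matrix: 100 samples spanning 0–100 % of the cycle, and ten
channels in fixed order — hip flexion (HF), knee flexion (KF) and ankle
dorsiflexion (ADF) angles in degrees, then seven rectified sEMG envelopes
(SEB, REF, VL, VM, BIF, MG, LG) in arbitrary per-channel units.  Angles may
be negative; rectified sEMG may not, and a raw collection rejects any trial
violating this.  The time axis is a dimensionless cycle-percent index; the
original acquisition rates are not part of the data model.  The data model
assumes one matrix per subject per condition; one manifest names one
condition only, so walking and running cohorts are analysed separately.

## Preprocessing: two views of the same trial

The joint-angle and sEMG channels live on scales that differ by orders of
magnitude, so a network fed raw matrices is dominated by the
largest-scale channels.  Two per-column rescalings are computed *per
subject*, never pooled across subjects (hence no statistic can leak from
the training to the test set):

- standardization  `x → (x − x̄) / s`, zero mean and unit variance per
  column;
- min-max normalization  `x → (x − min) / (max − min)`, range [0, 1] per
  column.

The standard deviation is the population (divide-by-n) form by default;
the sample form is available via `ddof=1`.  The population form is the one
under which the transformed column has variance exactly 1.  Constant
columns map to all zeros (standardization) or all 0.5 (normalization) —
the midpoint is the least-informative value in [0, 1] — and the event is
logged rather than raised, so a flat or clipped channel never aborts a
run.  Both transforms are invariant under positive affine maps of a
column and monotone within a column; invariant checks use a 1e-9
tolerance on 64-bit arithmetic.

## Augmentation

Each training trial's matrix is mirrored along the **channel** axis
(column j ← column 9−j), doubling the training set while preserving
labels and class balance.  The channel axis carries no positional
ordering, so the mirrored matrix is an equally valid sample; the time
axis, by contrast, is strongly ordered, and flipping it is offered only
as an explicit ablation (`axis="time"`).  Because both rescalings are
per-column, channel flipping commutes with preprocessing exactly (to
1e-12), so whether augmentation runs before or after preprocessing is
immaterial for the default axis; the pipeline augments the raw training
split and computes views afterwards.  Augmented copies carry an id suffix
(`+flip`) so leakage checks can trace each copy to its source subject;
they are never allowed into a test or validation split.

## Network

Each branch applies two blocks of `conv1d(16 filters, kernel 3, stride 1,
valid padding) → ReLU → max-pool(size 2, stride 1)`; dropout (rate 0.3)
follows the last convolutional layer's ReLU.  Kernels slide along the
time axis only and span all input channels.  Branch outputs are
flattened and concatenated, then `dense(50, ReLU) → dense(2, softmax)`.
The multi-input network (two branches) receives the standardized view on
branch 0 and the normalized view on branch 1; the single-input ablation
is the same stack with one branch fed either view or the raw matrix.

With the defaults, the temporal length maps 100 → 98 → 97 → 95 → 94, so
one branch flattens to 94 × 16 = 1504 features and the fused vector of
the dual-branch network has 3008; parameter totals are 76 632 (single)
and 153 112 (dual), the near-doubling coming almost entirely from the
first dense layer.  A closed-form parameter count is cross-checked
against enumeration of the allocated weight arrays in the tests.

Design points that the architecture description leaves open, and how they
are resolved here:

- **Depth**: two conv/pool blocks per branch (`conv_blocks_per_branch`
  exposes it).  Two blocks are the smallest depth consistent with
  "all convolutional layers" sharing one filter specification and a
  dropout layer placed "after the last" of them.
- **Padding**: valid (none); it keeps the length algebra explicit.
- **Dropout position**: between the last ReLU and that block's pooling
  (`pre_pool`); `post_pool` is available and provably identical in
  inference mode (a test asserts this).
- **Initialization**: seeded Glorot-uniform weights, zero biases.
- **Tie-break**: an exact probability tie predicts class 0 (control),
  the conservative choice for a screening positive class.

## Training

Full-batch training: one Adam update (lr 1e-5, β₁ 0.9, β₂ 0.999,
ε 1e-8) per iteration over the entire training set, categorical
cross-entropy on one-hot labels, 4000 iterations by default — under
full batch, "iterations" and "epochs" coincide.  The recorded loss for
each iteration is the training-mode (dropout-active) loss before that
iteration's update.  All arithmetic is float32; forward, backward and
the optimizer are implemented directly on numpy arrays (convolutions are
lowered to one GEMM per layer via im2col; parameters live in one flat
vector).  With fixed seeds and single-threaded BLAS, training is
bit-reproducible; under multi-threaded BLAS reproducibility is only
statistical.  A non-finite loss aborts with the iteration index.

## Evaluation protocol

Per repeat r (seed = base_seed + r, from which split/init/dropout streams
are derived): draw a stratified 70/30 subject split — training size is
70 % of n rounded half-up (29 of 41), apportioned across classes by
largest remainder, with at least one subject of each class on each side —
augment the training split only, train each arm, and evaluate on the
untouched test split.  Headline metrics are the arithmetic means of the
per-repeat accuracy, sensitivity (TP/(TP+FN)) and specificity
(TN/(TN+FP)), with PFPS positive.  A zero denominator yields NaN, which
is excluded from means and counted, never coerced to 0 or 1.  The four
arms are raw/normalized/standardized single-input and the dual-view
multi-input network.

Stratification is the default (the cohort has only 15 controls; an
unstratified 30 % test set can contain too few controls for a stable
specificity); plain random splitting is available via `stratify=False`.
Each repeat re-draws the split — that is the only reading under which
independent repeats change more than the weight initialization.

Ten-fold cross-validation is provided as an optional hyperparameter-
selection stage (`select_hyperparameters`) over a small declared grid
(dropout ∈ {0.2, 0.3, 0.5}, blocks ∈ {1, 2, 3}) run within the training
split; the default experiment skips it and uses the stated values
directly.  When k exceeds the smaller class count (e.g. leave-one-out)
folds fall back to plain shuffled partitions, since stratification is
then impossible.

## Synthetic cohort generator

No distributional parameters of the real cohort are published, so the
generator targets qualitative fidelity only; it exists to make the whole
pipeline exercisable and testable without any download.  Angle channels
are low-order sinusoid mixtures within physiological ranges (HF roughly
−14…34°, KF 2…58°, ADF −9…15° before noise); sEMG channels are one or
two Gaussian activation bursts with channel-specific timing, scaled per
channel over 0.05–500 arbitrary units (so the largest-to-smallest
channel-std ratio exceeds 100, recreating the scale disparity that
motivates preprocessing), plus Gaussian noise (sd = 0.1 of the channel
amplitude), clipped at zero so rectified-signal non-negativity holds by
construction.

The between-class effect, scaled by `effect_size` (default 1.0; 0 makes
the class distributions identical), follows the vastus-involvement theme
of the PFPS literature as a modeling convenience, not a biological
claim: +3° knee-flexion offset, VM bursts delayed by 5 samples with the
second burst amplified ×(1+0.35·e), VL burst advanced by 3 samples.  The
timing and within-channel amplitude-ratio components survive both
per-subject rescalings; the angle offset is visible only in raw data.
Per-subject variability comes from log-normal amplitude jitter, timing
jitter and phase jitter, all drawn from counter-based
`SeedSequence(seed, subject_index, label)` streams so enlarging a cohort
never reshuffles existing subjects.

What passing tests on this cohort do **not** show: the generator has no
inter-channel coupling, no stance/swing asymmetry in noise, no
subject-level covariates (sex, mass, speed), and its class effect is
concentrated and known — real cohorts are harder.  Results on it
demonstrate that the pipeline's machinery behaves as specified, not that
the classifier reaches any particular accuracy on real recordings.

## Problem sizes used by the shipped runs

The experiment-level checks run the full stated protocol — 41 subjects,
10 repeats, 4000 full-batch iterations — for the three-arm ordering
comparison (effect 1.5) and the null calibration (effect 0) in the test
suite, and for the four-arm comparison in `scripts/acceptance.py`.
Unit-level training tests use reduced iteration counts (tens to a few
hundred), which suffice for the properties they check (descent,
determinism, no-op, divergence detection).

## Known limitations

- Exact bit-reproducibility is promised only single-threaded.
- The undefined-metric (NaN) policy means a headline sensitivity or
  specificity can be an average over fewer than `repeats` values; the
  count of undefined repeats is reported alongside.
- `count_trainable_parameters` and the builder support only the valid-
  padding family the package uses.
- The CSV trial format stores full `repr` precision; files are ~25 KB
  per trial and round-trip to <1e-12.
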