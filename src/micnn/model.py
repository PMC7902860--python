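"""Dual-branch 1D convolutional network for gait-cycle classification.

The network (MI-CNN) takes two views of the same 100 x 10 trial matrix — the
standardized view and the min-max-normalized view — through two identical
convolutional branches whose flattened outputs are concatenated before the
dense head.  The single-input ablation (SI-CNN) is the same architecture with
one branch.  Convolutions are one-dimensional: kernels slide along the time
axis only and span all channels.

Per branch, each block is conv(filters=16, kernel=3, stride=1, valid padding)
-> ReLU -> max-pool(size=2, stride=1); a dropout layer (rate 0.3) follows the
ReLU of the last convolutional layer.  Branch outputs are flattened and
concatenated, then dense(50, ReLU) -> dense(n_classes, softmax).  Training is
full batch: one Adam update (lr 1e-5, betas 0.9/0.999, eps 1e-8) per
iteration over the whole training set with categorical cross-entropy loss,
4000 iterations by default, so "iterations" and "epochs" coincide.

Everything here — forward pass, backpropagation, Adam, dropout, Glorot
initialization — is implemented directly on numpy arrays.  Convolutions are
lowered to a single GEMM per layer (im2col), all parameters live in one flat
float32 vector viewed layer-by-layer, and with fixed seeds and
single-threaded BLAS the whole training trajectory is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ArchitectureError, ArityError, ContractError, TrainingDivergedError

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Elementwise pieces


def relu(x):
    """Rectified linear unit, max(x, 0), elementwise."""
    return np.maximum(x, 0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax: exp(z_i - max) / sum_p exp(z_p - max)."""
    z = np.asarray(z)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class ArchitectureSpec:
    """All structural hyperparameters of one network.

    ``n_branches=2`` is the multi-input network, ``n_branches=1`` the
    single-input ablation.  ``dropout_position`` resolves where dropout sits
    relative to the last block's pooling: ``pre_pool`` (default) puts it
    between the last ReLU and that block's pool; ``post_pool`` after the
    pool.  In inference mode the two are identical.
    """

    conv_blocks_per_branch: int = 2
    filters: int = 16
    kernel_size: int = 3
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 1
    dropout_rate: float = 0.3
    dense_units: int = 50
    n_classes: int = 2
    padding: Literal["valid"] = "valid"
    n_branches: int = 2
    dropout_position: Literal["pre_pool", "post_pool"] = "pre_pool"

    def __post_init__(self) -> None:
        for name in ("conv_blocks_per_branch", "filters", "kernel_size",
                     "conv_stride", "pool_size", "pool_stride", "dense_units"):
            if getattr(self, name) < 1:
                raise ArchitectureError(f"{name} must be a positive integer")
        if not (0 <= self.dropout_rate < 1):
            raise ArchitectureError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ArchitectureError("n_classes must be >= 2")
        if self.n_branches not in (1, 2):
            raise ArchitectureError("n_branches must be 1 or 2")
        if self.padding != "valid":
            raise ArchitectureError("only valid (no) padding is supported")


@dataclass(frozen=True)
class TrainSpec:
    """Optimizer configuration; batch mode is always full-batch."""

    learning_rate: float = 1e-5
    iterations: int = 4000
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be positive")
        if self.iterations < 0:
            raise ContractError("iterations must be non-negative")


# ---------------------------------------------------------------------------
# Shape algebra


def _out_length(length: int, window: int, stride: int) -> int:
    return (length - window) // stride + 1 if length >= window else 0


def branch_output_length(input_length: int, arch: ArchitectureSpec) -> int:
    """Temporal length after all conv/pool stages of one branch.

    With valid padding and unit strides each conv shortens the axis by
    ``kernel_size - 1`` and each pool by ``pool_size - 1``; the default
    two-block network maps 100 -> 98 -> 97 -> 95 -> 94.
    """
    length = input_length
    for b in range(arch.conv_blocks_per_branch):
        length = _out_length(length, arch.kernel_size, arch.conv_stride)
        if length < 1:
            raise ArchitectureError(
                f"conv layer {b + 1} collapses the temporal axis to {length}"
            )
        length = _out_length(length, arch.pool_size, arch.pool_stride)
        if length < 1:
            raise ArchitectureError(
                f"pool layer {b + 1} collapses the temporal axis to {length}"
            )
    return length


def count_trainable_parameters(
    arch: ArchitectureSpec, n_channels: int, input_length: int
) -> int:
    """Closed-form weight+bias count for the full network.

    Per branch: the first conv has ``(kernel*n_channels + 1)*filters``
    parameters, each subsequent conv ``(kernel*filters + 1)*filters``.  The
    fused feature vector has length ``n_branches * branch_output_length *
    filters``; the dense head adds ``(F + 1)*dense_units`` and
    ``(dense_units + 1)*n_classes``.
    """
    per_branch = (arch.kernel_size * n_channels + 1) * arch.filters
    per_branch += (arch.conv_blocks_per_branch - 1) * (
        (arch.kernel_size * arch.filters + 1) * arch.filters
    )
    flat = branch_output_length(input_length, arch) * arch.filters
    fused = arch.n_branches * flat
    dense = (fused + 1) * arch.dense_units
    out = (arch.dense_units + 1) * arch.n_classes
    return arch.n_branches * per_branch + dense + out


# ---------------------------------------------------------------------------
# Model container: all parameters in one flat vector, viewed per layer


def _layer_shapes(arch: ArchitectureSpec, n_channels: int, input_length: int):
    shapes: dict[str, dict[str, tuple[int, ...]]] = {}
    for b in range(arch.n_branches):
        c_in = n_channels
        for k in range(arch.conv_blocks_per_branch):
            shapes[f"branch{b}_conv{k}"] = {
                "W": (arch.kernel_size, c_in, arch.filters),
                "b": (arch.filters,),
            }
            c_in = arch.filters
    fused = arch.n_branches * branch_output_length(input_length, arch) * arch.filters
    shapes["dense1"] = {"W": (fused, arch.dense_units), "b": (arch.dense_units,)}
    shapes["output"] = {
        "W": (arch.dense_units, arch.n_classes), "b": (arch.n_classes,),
    }
    return shapes


def _flat_views(shapes, flat: np.ndarray):
    views: dict[str, dict[str, np.ndarray]] = {}
    offset = 0
    for name, layer in shapes.items():
        views[name] = {}
        for key, shape in layer.items():
            size = int(np.prod(shape))
            views[name][key] = flat[offset : offset + size].reshape(shape)
            offset += size
    assert offset == flat.size
    return views


@dataclass
class ModelHandle:
    """A built (possibly trained) network: architecture + weight arrays.

    ``params`` maps layer names to ``{"W": ..., "b": ...}`` arrays that are
    views into one flat parameter vector; branch b's k-th convolution is
    ``branch{b}_conv{k}``, the head layers are ``dense1`` and ``output``.
    Modify weights in place (``params[...]["W"][...] = ...``), never by
    rebinding the dict entry.  ``loss_history`` holds one training loss per
    completed iteration.
    """

    architecture: ArchitectureSpec
    n_channels: int
    input_length: int
    flat_params: np.ndarray
    params: dict[str, dict[str, np.ndarray]]
    loss_history: list[float] = field(default_factory=list)
    adam_state: dict | None = None

    @property
    def input_arity(self) -> int:
        return self.architecture.n_branches

    def introspect_parameter_count(self) -> int:
        """Total number of scalars across all allocated weight arrays."""
        return int(sum(a.size for layer in self.params.values() for a in layer.values()))


def build_model(
    arch: ArchitectureSpec,
    n_channels: int = 10,
    input_length: int = 100,
    seed: int = 0,
) -> ModelHandle:
    """Allocate and initialize all weights (seeded Glorot uniform, zero biases)."""
    shapes = _layer_shapes(arch, n_channels, input_length)
    total = sum(int(np.prod(s)) for layer in shapes.values() for s in layer.values())
    flat = np.zeros(total, dtype=DTYPE)
    params = _flat_views(shapes, flat)
    rng = np.random.default_rng(seed)
    for name, layer in params.items():
        W = layer["W"]
        if name.startswith("branch"):
            k, c_in, f = W.shape
            fan_in, fan_out = k * c_in, k * f
        else:
            fan_in, fan_out = W.shape
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W[...] = rng.uniform(-limit, limit, size=W.shape)
    return ModelHandle(
        architecture=arch, n_channels=n_channels, input_length=input_length,
        flat_params=flat, params=params,
    )


# ---------------------------------------------------------------------------
# Layer primitives (valid padding, arbitrary positive strides)
#
# The training loop reuses one workspace of preallocated buffers across
# iterations (shapes are constant within a run), so the hot path performs no
# per-iteration allocation beyond what BLAS needs.  ``ws=None`` (inference)
# simply allocates fresh arrays; the arithmetic is identical either way.


def _buf(ws, key, shape, dtype=DTYPE):
    if ws is None:
        return np.empty(shape, dtype)
    a = ws.get(key)
    if a is None or a.shape != tuple(shape) or a.dtype != dtype:
        a = np.empty(shape, dtype)
        ws[key] = a
    return a


def _conv1d_forward(x, W, b, stride, ws, key, static_input=False):
    """x: (N, L, C); W: (k, C, F) -> (out (N, Lout, F), im2col patch matrix)."""
    k, c, f = W.shape
    n = x.shape[0]
    lout = _out_length(x.shape[1], k, stride)
    cols = _buf(ws, key + ".cols", (n, lout, k * c))
    ready_key = key + ".cols_ready"
    if not (static_input and ws is not None and ws.get(ready_key) == id(x)):
        for i in range(k):
            cols[:, :, i * c : (i + 1) * c] = x[:, i : i + stride * lout : stride, :]
        if static_input and ws is not None:
            ws[ready_key] = id(x)  # first-layer patches never change within a run
    z = _buf(ws, key + ".z", (n, lout, f))
    np.matmul(cols.reshape(-1, k * c), W.reshape(k * c, f), out=z.reshape(-1, f))
    z += b
    return z, cols


def _conv1d_backward(cols, x_shape, W, stride, d_out, gW, gb, ws, key,
                     need_dx=True):
    """Gradients from the cached im2col matrix; d_out: (N, Lout, F)."""
    k, c, f = W.shape
    n, lout = d_out.shape[:2]
    d_flat = d_out.reshape(-1, f)
    np.matmul(cols.reshape(-1, k * c).T, d_flat, out=gW.reshape(k * c, f))
    np.sum(d_flat, axis=0, out=gb)
    if not need_dx:
        return None
    d_cols = _buf(ws, key + ".d_cols", cols.shape)
    np.matmul(d_flat, W.reshape(k * c, f).T, out=d_cols.reshape(-1, k * c))
    dx = _buf(ws, key + ".dx", x_shape)
    dx[...] = 0
    for i in range(k):
        dx[:, i : i + stride * lout : stride, :] += d_cols[:, :, i * c : (i + 1) * c]
    return dx


def _maxpool_forward(x, size, stride, ws=None, key=""):
    """x: (N, L, F) -> (pooled (N, Lout, F), argmax offsets in [0, size))."""
    lout = _out_length(x.shape[1], size, stride)
    if size == 2:
        a = x[:, 0 : stride * lout : stride, :]
        b = x[:, 1 : 1 + stride * lout : stride, :]
        arg = _buf(ws, key + ".arg", a.shape, bool)
        np.greater(b, a, out=arg)  # ties keep the earlier sample
        pooled = _buf(ws, key + ".pooled", a.shape)
        np.maximum(a, b, out=pooled)
        return pooled, arg
    windows = np.stack(
        [x[:, j : j + stride * lout : stride, :] for j in range(size)], axis=-1
    )
    arg = windows.argmax(axis=-1).astype(np.int8)
    return windows.max(axis=-1), arg


def _maxpool_backward(x_shape, size, stride, arg, d_out, ws=None, key=""):
    dx = _buf(ws, key + ".d_pool_x", x_shape)
    dx[...] = 0
    lout = d_out.shape[1]
    tmp = _buf(ws, key + ".d_pool_tmp", d_out.shape)
    if size == 2:  # boolean arg: offset 1 where True
        np.multiply(d_out, ~arg, out=tmp)
        dx[:, 0 : stride * lout : stride, :] += tmp
        np.multiply(d_out, arg, out=tmp)
        dx[:, 1 : 1 + stride * lout : stride, :] += tmp
        return dx
    for j in range(size):
        np.multiply(d_out, arg == j, out=tmp)
        dx[:, j : j + stride * lout : stride, :] += tmp
    return dx


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ContractError("labels must be a 1-D class vector")
    if np.any((labels < 0) | (labels >= n_classes)):
        raise ContractError(f"labels must lie in [0, {n_classes})")
    return np.eye(n_classes, dtype=DTYPE)[labels]


def _check_inputs(model: ModelHandle, inputs: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(inputs) != model.input_arity:
        raise ArityError(
            f"model expects {model.input_arity} input view(s), got {len(inputs)}"
        )
    arrays = [np.ascontiguousarray(x, dtype=DTYPE) for x in inputs]
    for x in arrays:
        if x.ndim != 3 or x.shape[1:] != (model.input_length, model.n_channels):
            raise ContractError(
                f"each input view must have shape (N, {model.input_length}, "
                f"{model.n_channels}), got {x.shape}"
            )
    if len({x.shape[0] for x in arrays}) != 1:
        raise ContractError("all input views must have the same number of trials")
    return arrays


# ---------------------------------------------------------------------------
# Forward / backward over the whole network


def _dropout_mask(rng, shape, keep, ws, key):
    r = _buf(ws, key + ".rand", shape)
    rng.random(out=r, dtype=DTYPE)
    hit = _buf(ws, key + ".hit", shape, bool)
    np.less(r, keep, out=hit)
    mask = _buf(ws, key + ".mask", shape)
    np.divide(hit, DTYPE(keep), out=mask)
    return mask


def _forward(
    model: ModelHandle,
    inputs: Sequence[np.ndarray],
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
    ws: dict | None = None,
):
    """Full forward pass; returns (probabilities, cache for backprop)."""
    arch = model.architecture
    cache: dict = {"branches": []}
    flats = []
    for b, x in enumerate(inputs):
        layers = []
        for k in range(arch.conv_blocks_per_branch):
            key = f"{b}.{k}"
            p = model.params[f"branch{b}_conv{k}"]
            z, cols = _conv1d_forward(
                x, p["W"], p["b"], arch.conv_stride, ws, key, static_input=k == 0
            )
            pos = _buf(ws, key + ".pos", z.shape, bool)
            np.greater(z, 0, out=pos)
            drop_mask = None
            is_last = k == arch.conv_blocks_per_branch - 1
            bp_mask = pos  # multiplier taking pool-input gradients to d_z
            if (training and arch.dropout_rate > 0 and is_last
                    and arch.dropout_position == "pre_pool"):
                drop_mask = _dropout_mask(
                    dropout_rng, z.shape, 1.0 - arch.dropout_rate, ws, key)
                drop_mask *= pos  # fold ReLU and dropout into one mask
                bp_mask = drop_mask
            a = _buf(ws, key + ".a", z.shape)
            np.multiply(z, bp_mask, out=a)
            pooled, arg = _maxpool_forward(
                a, arch.pool_size, arch.pool_stride, ws, key)
            if (training and arch.dropout_rate > 0 and is_last
                    and arch.dropout_position == "post_pool"):
                drop_mask = _dropout_mask(
                    dropout_rng, pooled.shape, 1.0 - arch.dropout_rate, ws, key)
                pooled *= drop_mask
            layers.append({
                "x_shape": x.shape, "cols": cols, "bp_mask": bp_mask,
                "a_shape": a.shape, "arg": arg, "post_mask": drop_mask
                if arch.dropout_position == "post_pool" else None,
                "pooled_shape": pooled.shape,
            })
            x = pooled
        cache["branches"].append(layers)
        flats.append(x.reshape(x.shape[0], -1))
    n = flats[0].shape[0]
    fused = _buf(ws, "fused", (n, sum(f.shape[1] for f in flats)))
    np.concatenate(flats, axis=1, out=fused)
    cache["fused"] = fused
    cache["flat_dims"] = [f.shape[1] for f in flats]
    d1 = model.params["dense1"]
    h_pre = _buf(ws, "h_pre", (n, arch.dense_units))
    np.matmul(fused, d1["W"], out=h_pre)
    h_pre += d1["b"]
    h_pos = _buf(ws, "h_pos", h_pre.shape, bool)
    np.greater(h_pre, 0, out=h_pos)
    h = _buf(ws, "h", h_pre.shape)
    np.multiply(h_pre, h_pos, out=h)
    cache["h_pos"], cache["h"] = h_pos, h
    out = model.params["output"]
    logits = h @ out["W"] + out["b"]
    return softmax(logits, axis=1), cache


def _backward(model: ModelHandle, cache: dict, probs, y, grads, ws=None):
    """Write the gradient of mean cross-entropy into the ``grads`` views."""
    arch = model.architecture
    n = probs.shape[0]
    d_logits = ((probs - y) / n).astype(DTYPE)
    h = cache["h"]
    np.matmul(h.T, d_logits, out=grads["output"]["W"])
    np.sum(d_logits, axis=0, out=grads["output"]["b"])
    d_h = d_logits @ model.params["output"]["W"].T
    d_h_pre = d_h * cache["h_pos"]
    np.matmul(cache["fused"].T, d_h_pre, out=grads["dense1"]["W"])
    np.sum(d_h_pre, axis=0, out=grads["dense1"]["b"])
    d_fused = _buf(ws, "d_fused", cache["fused"].shape)
    np.matmul(d_h_pre, model.params["dense1"]["W"].T, out=d_fused)
    offset = 0
    for b, layers in enumerate(cache["branches"]):
        key = f"{b}"
        dim = cache["flat_dims"][b]
        d_flat = d_fused[:, offset : offset + dim]
        offset += dim
        d_pooled = _buf(ws, key + ".d_top", layers[-1]["pooled_shape"])
        d_pooled[...] = d_flat.reshape(layers[-1]["pooled_shape"])
        for k in range(arch.conv_blocks_per_branch - 1, -1, -1):
            key = f"{b}.{k}"
            lay = layers[k]
            if lay["post_mask"] is not None:
                d_pooled = d_pooled * lay["post_mask"]
            d_a = _maxpool_backward(
                lay["a_shape"], arch.pool_size, arch.pool_stride, lay["arg"],
                d_pooled, ws, key)
            d_a *= lay["bp_mask"]
            p = model.params[f"branch{b}_conv{k}"]
            g = grads[f"branch{b}_conv{k}"]
            d_pooled = _conv1d_backward(
                lay["cols"], lay["x_shape"], p["W"], arch.conv_stride, d_a,
                g["W"], g["b"], ws, key,
                need_dx=k > 0,  # the input gradient of the first layer is unused
            )


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-(y * np.log(probs + eps)).sum(axis=1).mean())


def train(
    model: ModelHandle,
    inputs: Sequence[np.ndarray],
    labels: np.ndarray,
    spec: TrainSpec,
) -> ModelHandle:
    """Run exactly ``spec.iterations`` full-batch Adam updates in place.

    The loss recorded for each iteration is the training-mode cross-entropy
    (dropout active) evaluated before that iteration's update, so two runs
    with the same seed produce identical histories.  A non-finite loss raises
    :class:`TrainingDivergedError` carrying the iteration index.
    """
    arrays = _check_inputs(model, inputs)
    labels = np.asarray(labels, dtype=int)
    if arrays[0].shape[0] != labels.shape[0]:
        raise ContractError("input row count must equal label count")
    y = _one_hot(labels, model.architecture.n_classes)

    dropout_rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    flat = model.flat_params
    shapes = _layer_shapes(model.architecture, model.n_channels, model.input_length)
    g_flat = np.zeros_like(flat)
    grads = _flat_views(shapes, g_flat)
    if model.adam_state is None:
        model.adam_state = {
            "t": 0, "m": np.zeros_like(flat), "v": np.zeros_like(flat),
        }
    state = model.adam_state
    m, v = state["m"], state["v"]
    b1, b2 = DTYPE(spec.beta1), DTYPE(spec.beta2)
    eps = DTYPE(spec.epsilon)
    ws: dict = {}

    for it in range(spec.iterations):
        probs, cache = _forward(
            model, arrays, training=True, dropout_rng=dropout_rng, ws=ws)
        loss = _cross_entropy(probs, y)
        if not np.isfinite(loss):
            raise TrainingDivergedError(it)
        model.loss_history.append(loss)
        _backward(model, cache, probs, y, grads, ws=ws)
        state["t"] += 1
        t = state["t"]
        lr_t = DTYPE(
            spec.learning_rate * np.sqrt(1 - spec.beta2**t) / (1 - spec.beta1**t)
        )
        m *= b1
        m += (1 - b1) * g_flat
        v *= b2
        v += (1 - b2) * np.square(g_flat)
        flat -= lr_t * m / (np.sqrt(v) + eps)
    return model


# ---------------------------------------------------------------------------
# Serialization: a JSON architecture record plus an .npz of weight arrays


def save_model(model: ModelHandle, directory) -> None:
    """Write ``config.json`` and ``weights.npz`` into ``directory``."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    record = {
        "architecture": asdict(model.architecture),
        "n_channels": model.n_channels,
        "input_length": model.input_length,
        "loss_history": model.loss_history,
    }
    (directory / "config.json").write_text(json.dumps(record, indent=2))
    arrays = {
        f"{name}/{key}": a
        for name, layer in model.params.items()
        for key, a in layer.items()
    }
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory) -> ModelHandle:
    """Rebuild a saved model; weights are copied into fresh flat storage."""
    import json
    from pathlib import Path

    directory = Path(directory)
    record = json.loads((directory / "config.json").read_text())
    arch = ArchitectureSpec(**record["architecture"])
    model = build_model(
        arch, n_channels=record["n_channels"],
        input_length=record["input_length"], seed=0,
    )
    with np.load(directory / "weights.npz") as arrays:
        for name, layer in model.params.items():
            for key in layer:
                layer[key][...] = arrays[f"{name}/{key}"]
    model.loss_history = list(record["loss_history"])
    return model


def predict(
    model: ModelHandle, inputs: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode forward pass: (predicted labels, class probabilities).

    The label is the argmax of the softmax output; an exact probability tie
    resolves to class 0 (control), the conservative choice for a screening
    positive class.
    """
    arrays = _check_inputs(model, inputs)
    probs, _ = _forward(model, arrays, training=False)
    labels = probs.argmax(axis=1)  # np.argmax takes the first maximum: class 0 on ties
    return labels, probs
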