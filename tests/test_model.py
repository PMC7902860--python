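"""Network building blocks: activations, shape algebra, training mechanics."""

import numpy as np
import pytest

from micnn.errors import ArchitectureError, ArityError, TrainingDivergedError
from micnn.model import (
    ArchitectureSpec,
    TrainSpec,
    branch_output_length,
    build_model,
    count_trainable_parameters,
    load_model,
    predict,
    relu,
    save_model,
    softmax,
    train,
)
from micnn.model import _forward


def si_arch(**kw):
    return ArchitectureSpec(n_branches=1, **kw)


# ---------------------------------------------------------------------------
# Activations


def test_relu_examples():
    assert relu(-2) == 0
    assert relu(5) == 5
    assert np.array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])


def test_relu_idempotent_and_monotone(rng):
    x = rng.normal(size=1000)
    y = relu(x)
    assert np.array_equal(relu(y), y)
    order = np.argsort(x)
    assert np.all(np.diff(y[order]) >= 0)


def test_softmax_examples():
    assert softmax([0.0, 0.0]) == pytest.approx([0.5, 0.5])
    assert softmax([np.log(2.0), 0.0]) == pytest.approx([2 / 3, 1 / 3], abs=1e-9)


def test_softmax_overflow_stability():
    out = softmax([1000.0, 0.0])
    assert np.all(np.isfinite(out))
    assert out == pytest.approx([1.0, 0.0], abs=1e-12)


def test_softmax_rows_sum_to_one(rng):
    z = rng.normal(scale=50, size=(20, 2))
    assert softmax(z, axis=1).sum(axis=1) == pytest.approx(np.ones(20), abs=1e-6)


# ---------------------------------------------------------------------------
# Shape algebra and parameter counts


def test_branch_output_length_defaults():
    # 100 -conv-> 98 -pool-> 97 -conv-> 95 -pool-> 94
    assert branch_output_length(100, ArchitectureSpec()) == 94


def test_branch_output_length_boundary_error():
    arch = si_arch(conv_blocks_per_branch=1, kernel_size=3, pool_size=2)
    with pytest.raises(ArchitectureError):
        branch_output_length(3, arch)  # conv gives 1, pool cannot fit


def test_identity_configuration_keeps_length():
    arch = si_arch(kernel_size=1, pool_size=1)
    assert branch_output_length(100, arch) == 100


def test_conv_param_count_hand_example():
    # one conv layer, 2 input channels, 4 filters, kernel 3: (3*2+1)*4 = 28
    arch = si_arch(conv_blocks_per_branch=1, filters=4, kernel_size=3,
                   pool_size=2, dense_units=5)
    total = count_trainable_parameters(arch, n_channels=2, input_length=10)
    flat = branch_output_length(10, arch) * 4
    assert total == 28 + (flat + 1) * 5 + (5 + 1) * 2


@pytest.mark.parametrize("arch", [
    ArchitectureSpec(),
    si_arch(),
    si_arch(conv_blocks_per_branch=1, filters=8),
    ArchitectureSpec(conv_blocks_per_branch=3, filters=4, kernel_size=5),
    si_arch(pool_size=3, dense_units=20, kernel_size=7),
    ArchitectureSpec(filters=2, dense_units=3, n_classes=2),
])
def test_closed_form_matches_introspection(arch):
    """The closed-form count equals enumeration of allocated weight arrays."""
    model = build_model(arch, n_channels=10, input_length=100, seed=0)
    assert count_trainable_parameters(arch, 10, 100) == model.introspect_parameter_count()


def test_mi_branch_parameters_double_si():
    mi, si = ArchitectureSpec(n_branches=2), ArchitectureSpec(n_branches=1)

    def branch_params(arch):
        m = build_model(arch, seed=0)
        return sum(a.size for name, layer in m.params.items()
                   for a in layer.values() if name.startswith("branch"))

    assert branch_params(mi) == 2 * branch_params(si)


def test_fused_feature_lengths():
    mi = build_model(ArchitectureSpec(), seed=0)
    si = build_model(si_arch(), seed=0)
    assert mi.params["dense1"]["W"].shape[0] == 2 * 94 * 16 == 3008
    assert si.params["dense1"]["W"].shape[0] == 94 * 16 == 1504


# ---------------------------------------------------------------------------
# Forward-pass oracle


def test_forward_matches_hand_computed_sliding_sum_and_max():
    """All-ones conv weights turn the branch into sliding-sum + windowed max."""
    arch = si_arch(conv_blocks_per_branch=1, filters=1, kernel_size=3,
                   pool_size=2, dropout_rate=0.0, dense_units=1)
    x = np.array([[1.0, 2.0],
                  [3.0, -1.0],
                  [0.5, 0.5],
                  [2.0, 2.0],
                  [-4.0, 1.0],
                  [1.0, 1.0]])
    model = build_model(arch, n_channels=2, input_length=6, seed=0)
    model.params["branch0_conv0"]["W"][...] = 1.0
    model.params["branch0_conv0"]["b"][...] = 0.0
    # window sums over rows i..i+2 of both channels
    sums = np.array([x[i : i + 3].sum() for i in range(4)])  # [6.0, 7.5, 2.0, 3.5]
    expect = np.maximum(
        np.maximum(sums[:-1], sums[1:]), 0.0)                # relu then max-pool
    _, cache = _forward(model, [x[None, :, :]], training=False)
    got = cache["fused"][0]
    assert got == pytest.approx(expect, abs=1e-6)


# ---------------------------------------------------------------------------
# Training mechanics


def small_training_setup(n=16, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    x = rng.normal(size=(n, 100, 10))
    x[labels == 1, 40:60, :] += 1.5  # separable bump
    return x, labels


def test_training_loss_descends():
    x, labels = small_training_setup()
    model = build_model(si_arch(), seed=1)
    train(model, [x], labels, TrainSpec(iterations=300, learning_rate=1e-4, seed=1))
    assert len(model.loss_history) == 300
    assert model.loss_history[-1] < model.loss_history[0]


def test_zero_iterations_is_a_no_op():
    x, labels = small_training_setup()
    model = build_model(si_arch(), seed=1)
    before = model.flat_params.copy()
    train(model, [x], labels, TrainSpec(iterations=0, seed=1))
    assert np.array_equal(model.flat_params, before)
    assert model.loss_history == []


def test_same_seed_same_history():
    x, labels = small_training_setup()
    hists = []
    for _ in range(2):
        model = build_model(ArchitectureSpec(), seed=3)
        train(model, [x, x], labels, TrainSpec(iterations=120, seed=3))
        hists.append(np.array(model.loss_history))
    assert np.max(np.abs(hists[0] - hists[1])) < 1e-6


def test_divergence_reports_iteration():
    x, labels = small_training_setup()
    model = build_model(si_arch(), seed=1)
    with pytest.raises(TrainingDivergedError) as err, np.errstate(all="ignore"):
        train(model, [1e30 * x], labels,
              TrainSpec(iterations=50, learning_rate=1e30, seed=1))
    assert err.value.iteration >= 0


def test_arity_mismatch_rejected():
    x, labels = small_training_setup(n=4)
    mi = build_model(ArchitectureSpec(), seed=0)
    with pytest.raises(ArityError):
        predict(mi, [x])
    si = build_model(si_arch(), seed=0)
    with pytest.raises(ArityError):
        train(si, [x, x], labels, TrainSpec(iterations=1, seed=0))


def test_probabilities_sum_to_one_untrained():
    x, _ = small_training_setup(n=8)
    model = build_model(ArchitectureSpec(), seed=5)
    _, probs = predict(model, [x, x])
    assert probs.sum(axis=1) == pytest.approx(np.ones(8), abs=1e-6)


def test_probability_tie_goes_to_control():
    x, _ = small_training_setup(n=4)
    model = build_model(si_arch(), seed=0)
    model.flat_params[...] = 0.0  # all-zero net: logits are exactly tied
    labels, probs = predict(model, [x])
    assert probs == pytest.approx(0.5)
    assert np.all(labels == 0)


def test_dropout_only_active_during_training():
    x, labels = small_training_setup()
    model = build_model(si_arch(dropout_rate=0.5), seed=2)
    train(model, [x], labels, TrainSpec(iterations=20, seed=2))
    _, p1 = predict(model, [x])
    _, p2 = predict(model, [x])
    assert np.array_equal(p1, p2)


def test_dropout_position_equivalent_at_inference():
    x, _ = small_training_setup(n=6)
    pre = build_model(si_arch(dropout_position="pre_pool"), seed=4)
    post = build_model(si_arch(dropout_position="post_pool"), seed=4)
    _, p1 = predict(pre, [x])
    _, p2 = predict(post, [x])
    assert np.array_equal(p1, p2)


def test_mi_with_zeroed_second_branch_reproduces_si():
    """Fusion sanity: feeding one view twice and silencing branch 1's dense
    rows makes the dual-branch net equal the single-branch net."""
    x, _ = small_training_setup(n=8)
    si = build_model(si_arch(), seed=7)
    mi = build_model(ArchitectureSpec(), seed=8)
    for k in range(2):
        for key in ("W", "b"):
            mi.params[f"branch0_conv{k}"][key][...] = si.params[f"branch0_conv{k}"][key]
    half = si.params["dense1"]["W"].shape[0]
    mi.params["dense1"]["W"][:half] = si.params["dense1"]["W"]
    mi.params["dense1"]["W"][half:] = 0.0
    mi.params["dense1"]["b"][...] = si.params["dense1"]["b"]
    for key in ("W", "b"):
        mi.params["output"][key][...] = si.params["output"][key]
    _, p_si = predict(si, [x])
    _, p_mi = predict(mi, [x, x])
    assert p_mi == pytest.approx(p_si, abs=1e-6)


def test_save_load_round_trip(tmp_path):
    x, labels = small_training_setup(n=8)
    model = build_model(ArchitectureSpec(), seed=6)
    train(model, [x, x], labels, TrainSpec(iterations=10, seed=6))
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    _, p1 = predict(model, [x, x])
    _, p2 = predict(back, [x, x])
    assert np.array_equal(p1, p2)
    assert back.loss_history == model.loss_history
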