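"""Network building blocks: residual identities, gradients, architecture laws."""

import numpy as np
import pytest

from dlgwas.errors import ConfigurationError
from dlgwas.nn import (
    ArchitectureSpec,
    Conv2d,
    ResidualBlock,
    Sequential,
    build_model,
    relu,
    softmax_cross_entropy,
)
from dlgwas.nn.layers import AvgPool2d, BatchNorm2d, Linear, MaxPool2d


def zero_params(layer):
    for sub in layer.iter_layers():
        for name in sub.p:
            sub.p[name][:] = 1.0 if name == "gamma" else 0.0


def test_relu_values():
    assert list(relu(np.array([-1.0, 0.0, 2.0]))) == [0.0, 0.0, 2.0]


def test_zeroed_residual_stack_is_identity():
    """With the residual branch zeroed, H(x) = 0 + x exactly."""
    rng = np.random.default_rng(0)
    stack = Sequential(
        ResidualBlock(3, 3, rng=rng, post_activation=False),
        ResidualBlock(3, 3, rng=rng, post_activation=False),
    )
    zero_params(stack)
    x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
    assert np.abs(stack.forward(x, train=False) - x).max() == 0.0


def test_residual_stack_accumulates_branch_outputs():
    """x_K = x_0 + sum_r F(x_{r-1}) for a dimension-preserving stack."""
    rng = np.random.default_rng(1)
    blocks = [
        ResidualBlock(1, 1, rng=rng, use_bn=False, post_activation=False)
        for _ in range(3)
    ]
    stack = Sequential(*blocks)
    x0 = rng.standard_normal((2, 1, 6, 6)).astype(np.float32)
    # capture intermediate inputs
    xs = [x0]
    for b in blocks:
        xs.append(b.forward(xs[-1], train=False))
    branch_sum = sum(b.branch.forward(x, train=False) for b, x in zip(blocks, xs[:-1]))
    assert np.allclose(xs[-1], x0 + branch_sum, atol=1e-5)


def test_resnet34_has_more_parameters_than_resnet18():
    m18 = build_model(ArchitectureSpec("resnet18", side=32, width=0.25), seed=0)
    m34 = build_model(ArchitectureSpec("resnet34", side=32, width=0.25), seed=0)
    assert m34.n_parameters() > m18.n_parameters()


@pytest.mark.parametrize("family", ["plain_cnn", "resnet18"])
def test_numeric_gradient_check(family):
    """Analytic backward gradients match central finite differences."""
    side = 8 if family == "plain_cnn" else 16
    model = build_model(ArchitectureSpec(family, side=side, width=0.25), seed=3)
    rng = np.random.default_rng(4)
    x = rng.standard_normal((4, side, side))
    Y = np.eye(2)[[0, 1, 0, 1]].astype(np.float64)

    logits = model.forward(x, train=True)
    loss, dl = softmax_cross_entropy(logits, Y)
    model.backward(dl)

    layer = model.param_layers()[0]
    g_analytic = float(layer.g["W"].flat[0])
    eps = 1e-3
    layer.p["W"].flat[0] += eps
    l1, _ = softmax_cross_entropy(model.forward(x, train=True), Y)
    layer.p["W"].flat[0] -= 2 * eps
    l2, _ = softmax_cross_entropy(model.forward(x, train=True), Y)
    layer.p["W"].flat[0] += eps
    assert g_analytic == pytest.approx((l1 - l2) / (2 * eps), rel=0.05, abs=1e-4)


def test_pooling_forward_values_and_backward_mass():
    x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
    mx = MaxPool2d(2)
    av = AvgPool2d(2)
    assert np.array_equal(mx.forward(x)[0, 0], [[5, 7], [13, 15]])
    assert np.array_equal(av.forward(x)[0, 0], [[2.5, 4.5], [10.5, 12.5]])
    d = np.ones((1, 1, 2, 2))
    # max routes gradient to the argmax; avg spreads it
    dmx = mx.backward(d)
    assert dmx.sum() == 4 and dmx[0, 0, 1, 1] == 1
    dav = av.backward(d)
    assert dav.sum() == pytest.approx(4.0)
    assert np.unique(dav) == pytest.approx(0.25)


def test_batchnorm_normalises_and_tracks_running_stats():
    bn = BatchNorm2d(2)
    rng = np.random.default_rng(5)
    x = rng.standard_normal((8, 2, 4, 4)) * 3 + 1
    out = bn.forward(x, train=True)
    assert out.mean(axis=(0, 2, 3)) == pytest.approx([0, 0], abs=1e-6)
    assert out.std(axis=(0, 2, 3)) == pytest.approx([1, 1], abs=1e-3)
    # eval mode uses the running statistics
    out_eval = bn.forward(x, train=False)
    assert not np.allclose(out, out_eval)


def test_conv_matches_direct_convolution():
    rng = np.random.default_rng(6)
    conv = Conv2d(1, 1, 3, pad=1, rng=rng)
    x = rng.standard_normal((1, 1, 5, 5))
    out = conv.forward(x, train=False)
    xp = np.pad(x[0, 0], 1)
    W = conv.p["W"][0, 0]
    expected = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            expected[i, j] = (xp[i : i + 3, j : j + 3] * W).sum() + conv.p["b"][0]
    assert np.allclose(out[0, 0], expected, atol=1e-5)


@pytest.mark.parametrize(
    "bad",
    [
        dict(family="vgg"),
        dict(side=4),
        dict(n_classes=1),
        dict(width=0.0),
        dict(pooling="median"),
    ],
)
def test_invalid_architecture_specs(bad):
    with pytest.raises(ConfigurationError):
        ArchitectureSpec(**{**dict(family="plain_cnn", side=64), **bad})


def test_input_side_too_small_rejected():
    with pytest.raises(ConfigurationError):
        ArchitectureSpec("resnet18", side=7)


def test_state_round_trip_preserves_predictions():
    model = build_model(ArchitectureSpec("plain_cnn", side=16, width=0.25), seed=7)
    x = np.random.default_rng(8).standard_normal((3, 16, 16))
    before = model.predict_proba(x)
    state = model.state()
    for layer in model.param_layers():
        for k in layer.p:
            layer.p[k] = layer.p[k] + 1.0
    assert not np.allclose(model.predict_proba(x), before)
    model.load_state(state)
    assert np.allclose(model.predict_proba(x), before)


def test_linear_layer_backward_shapes():
    rng = np.random.default_rng(9)
    lin = Linear(6, 4, rng=rng)
    x = rng.standard_normal((5, 6))
    out = lin.forward(x, train=True)
    dx = lin.backward(np.ones_like(out))
    assert dx.shape == x.shape
    assert lin.g["W"].shape == lin.p["W"].shape
    assert lin.g["b"].shape == (4,)
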