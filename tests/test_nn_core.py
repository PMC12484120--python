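"""Autodiff core: convolution oracle agreement and gradient correctness."""

import numpy as np
import pytest

from mafnet import nn
from mafnet.nn import functional as F
from mafnet.nn.tensor import Tensor

from conftest import naive_dilated_conv2d


def central_diff_grad(fn, arr, upstream, eps=1e-6):
    """Numerical gradient of sum(fn() * upstream) w.r.t. arr (mutated in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        hi = (fn() * upstream).sum()
        arr[i] = orig - eps
        lo = (fn() * upstream).sum()
        arr[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


@pytest.mark.parametrize("dilation", [1, 3, 5])
def test_conv2d_matches_naive_loop_oracle(rng, dilation):
    x = rng.standard_normal((1, 2, 9, 9))
    w = rng.standard_normal((3, 2, 3, 3))
    got = F.conv2d(Tensor(x), Tensor(w), dilation=dilation).data
    want = naive_dilated_conv2d(x, w, dilation)
    assert np.abs(got - want).max() <= 1e-10


# each case: (input shape, extra-parameter shapes, graph builder)
_GRAD_CASES = {
    "conv_dilated": ((2, 3, 5, 5), {"w": (4, 3, 3, 3), "b": (4,)},
                     lambda t: F.conv2d(t["x"], t["w"], t["b"], dilation=2)),
    "conv_7x7": ((1, 2, 8, 8), {"w": (1, 2, 7, 7)},
                 lambda t: F.conv2d(t["x"], t["w"])),
    "linear": ((4, 6), {"w": (3, 6), "b": (3,)},
               lambda t: F.linear(t["x"], t["w"], t["b"])),
    "maxpool": ((2, 3, 4, 4), {}, lambda t: F.max_pool2d(t["x"])),
    "avgpool": ((2, 3, 4, 4), {}, lambda t: F.avg_pool2d(t["x"])),
    "resize_bilinear": ((2, 2, 4, 4), {}, lambda t: F.resize(t["x"], (7, 6))),
    "resize_nearest": ((2, 2, 4, 4), {},
                       lambda t: F.resize(t["x"], (8, 2), mode="nearest")),
    "sigmoid": ((2, 3, 4, 4), {}, lambda t: F.sigmoid(t["x"])),
    "relu": ((2, 3, 4, 4), {}, lambda t: F.relu(t["x"])),
    "channel_max": ((2, 5, 3, 3), {}, lambda t: F.channel_max(t["x"])),
    "global_pools": ((2, 4, 3, 3), {},
                     lambda t: F.concat([F.global_avg_pool(t["x"]),
                                         F.global_max_pool(t["x"])], axis=1)),
}


@pytest.mark.parametrize("case", sorted(_GRAD_CASES))
def test_gradients_match_finite_differences(rng, case):
    x_shape, param_shapes, build = _GRAD_CASES[case]
    arrays = {"x": rng.standard_normal(x_shape)}
    arrays.update({k: rng.standard_normal(s) for k, s in param_shapes.items()})

    tensors = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
    out = build(tensors)
    upstream = rng.standard_normal(out.shape)
    out.backward(upstream)

    for name, arr in arrays.items():
        numeric = central_diff_grad(
            lambda: build({k: Tensor(v) for k, v in arrays.items()}).data,
            arr, upstream)
        assert np.abs(numeric - tensors[name].grad).max() < 1e-6, name


@pytest.mark.parametrize("training", [True, False])
def test_batch_norm_gradients(rng, training):
    x = rng.standard_normal((3, 4, 3, 3))
    gamma = rng.standard_normal(4) + 1.0
    beta = rng.standard_normal(4)
    rm, rv = rng.standard_normal(4), rng.random(4) + 0.5

    def build(xt, gt, bt):
        return F.batch_norm(xt, gt, bt, rm.copy(), rv.copy(), training=training)

    xt = Tensor(x, requires_grad=True)
    gt = Tensor(gamma, requires_grad=True)
    bt = Tensor(beta, requires_grad=True)
    out = build(xt, gt, bt)
    upstream = rng.standard_normal(out.shape)
    out.backward(upstream)
    for arr, t in ((x, xt), (gamma, gt), (beta, bt)):
        numeric = central_diff_grad(
            lambda: build(Tensor(x), Tensor(gamma), Tensor(beta)).data, arr, upstream)
        assert np.abs(numeric - t.grad).max() < 1e-5


def test_broadcast_add_mul_gradient_shapes(rng):
    a = Tensor(rng.standard_normal((2, 3, 1, 4)), requires_grad=True)
    b = Tensor(rng.standard_normal((1, 3, 5, 1)), requires_grad=True)
    out = F.add(F.mul(a, b), b)
    out.backward(np.ones(out.shape))
    assert a.grad.shape == a.shape and b.grad.shape == b.shape
    # d/da sum(a*b + b) broadcasts b over axes 0 and 3 of the output
    assert np.allclose(a.grad, np.broadcast_to(b.data, (2, 3, 5, 4)).sum(axis=2,
                                                                         keepdims=True))


@pytest.mark.parametrize("name", sorted(nn.OPTIMIZERS))
def test_every_optimizer_descends_a_quadratic(name):
    p = nn.Parameter(np.array([3.0, -2.0], dtype=np.float64))
    opt = nn.make_optimizer(name, [p], lr=0.1)
    start = float((p.data ** 2).sum())
    for _ in range(500):
        p.grad = 2.0 * p.data
        opt.step()
    assert float((p.data ** 2).sum()) < 0.05 * start


def test_no_grad_suppresses_graph(rng):
    w = nn.Parameter(rng.standard_normal((2, 2, 3, 3)))
    with nn.no_grad():
        out = F.conv2d(Tensor(rng.standard_normal((1, 2, 4, 4))), w)
    assert not out.requires_grad and out._backward is None


def test_resize_nearest_constant_roundtrip():
    x = Tensor(np.full((1, 1, 6, 6), 3.25))
    back = F.avg_pool2d(F.resize(x, (12, 12), mode="nearest"))
    assert np.array_equal(back.data, x.data)


def test_state_dict_roundtrip(rng):
    nn.manual_seed(7)
    a = nn.Sequential(nn.ConvBlock(2, 3, 3), nn.ConvBlock(3, 2, 3))
    nn.manual_seed(99)
    b = nn.Sequential(nn.ConvBlock(2, 3, 3), nn.ConvBlock(3, 2, 3))
    b.load_state_dict(a.state_dict())
    x = Tensor(rng.standard_normal((1, 2, 6, 6)).astype(np.float32))
    a.eval(), b.eval()
    assert np.array_equal(a(x).data, b(x).data)
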