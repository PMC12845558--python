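"""Autodiff engine correctness: forward ops against independent oracles
(scipy correlation, closed forms) and gradients against central finite
differences."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from tgsr.nn import Adam, BatchNorm2d, Conv2d
from tgsr.nn import tensor as T
from tgsr.nn.tensor import Tensor


def _numeric_grad(f, x, eps=1e-3):
    """Central-difference gradient of scalar f with respect to array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def _check_grad(build, arrays, tol=2e-2, eps=1e-3):
    """build() -> scalar Tensor referencing the given parameter Tensors.

    Analytic gradients are snapshotted before the finite-difference sweeps
    (each sweep re-runs build(), which resets grads).  For losses linear in
    the checked tensor a large ``eps`` is exact and suppresses float32
    cancellation noise.
    """
    loss = build()
    loss.backward()
    analytic = [t.grad.copy() for t in arrays]
    for t, ana in zip(arrays, analytic):
        numeric = _numeric_grad(lambda: float(build().data.reshape(())),
                                t.data, eps=eps)
        np.testing.assert_allclose(ana, numeric, rtol=tol, atol=tol)


@pytest.mark.parametrize("cin,cout,k,stride,pad,groups", [
    (3, 4, 3, 1, 1, 1),
    (4, 6, 3, 2, 1, 2),
    (5, 5, 3, 1, 1, 5),     # depthwise fast path
    (6, 6, 5, 2, 2, 6),     # depthwise, stride 2
    (4, 7, 1, 1, 0, 1),     # pointwise
])
def test_conv2d_forward_matches_scipy(cin, cout, k, stride, pad, groups, rng):
    x = rng.standard_normal((2, cin, 8, 8)).astype(np.float32)
    w = rng.standard_normal((cout, cin // groups, k, k)).astype(np.float32)
    b = rng.standard_normal(cout).astype(np.float32)
    out = T.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=stride,
                   padding=pad, groups=groups)
    cg, cog = cin // groups, cout // groups
    for n in range(2):
        for o in range(cout):
            g = o // cog
            acc = np.zeros((8 + 2 * pad - k + 1, 8 + 2 * pad - k + 1))
            for ci in range(cg):
                xp = np.pad(x[n, g * cg + ci], pad)
                acc += correlate2d(xp, w[o, ci], mode="valid")
            expect = acc[::stride, ::stride] + b[o]
            np.testing.assert_allclose(out.data[n, o], expect, atol=1e-4)


@pytest.mark.parametrize("k,stride,pad,groups", [
    (3, 1, 1, 1), (3, 2, 1, 2), (3, 1, 1, 4), (5, 2, 2, 4), (1, 1, 0, 1),
])
def test_conv2d_gradients(k, stride, pad, groups, rng):
    cin = cout = 4
    x = Tensor(rng.standard_normal((2, cin, 6, 6)), requires_grad=True)
    w = Tensor(rng.standard_normal((cout, cin // groups, k, k)) * 0.5,
               requires_grad=True)
    b = Tensor(rng.standard_normal(cout), requires_grad=True)

    probe = None

    def build():
        nonlocal probe
        for t in (x, w, b):
            t.grad = None
        y = T.conv2d(x, w, b, stride=stride, padding=pad, groups=groups)
        if probe is None:
            probe = Tensor(np.random.default_rng(0).standard_normal(y.shape))
        return T.tsum(T.mul(y, probe))

    _check_grad(build, [x, w, b], tol=5e-3, eps=0.05)


def test_batch_norm_train_gradients(rng):
    x = Tensor(rng.standard_normal((3, 2, 4, 4)), requires_grad=True)
    g = Tensor(rng.standard_normal(2) + 1.0, requires_grad=True)
    be = Tensor(rng.standard_normal(2), requires_grad=True)

    def build():
        for t in (x, g, be):
            t.grad = None
        y = T.batch_norm(x, g, be, running_mean=np.zeros(2, np.float32),
                         running_var=np.ones(2, np.float32), training=True)
        w = Tensor(np.linspace(0.5, 1.5, y.data.size,
                               dtype=np.float32).reshape(y.shape))
        return T.tsum(T.mul(y, w))

    _check_grad(build, [x, g, be])


def test_batch_norm_running_stats_and_eval(rng):
    bn = BatchNorm2d(3)
    x = rng.standard_normal((8, 3, 5, 5)).astype(np.float32) * 2 + 1
    for _ in range(60):
        bn(Tensor(x))
    np.testing.assert_allclose(bn.running_mean, x.mean(axis=(0, 2, 3)),
                               atol=1e-2)
    bn.eval()
    y = bn(Tensor(x))
    expect = (x - bn.running_mean.reshape(1, -1, 1, 1)) / np.sqrt(
        bn.running_var.reshape(1, -1, 1, 1) + bn.eps)
    np.testing.assert_allclose(y.data, expect, atol=1e-4)


@pytest.mark.parametrize("op", [T.relu, T.gelu, T.sigmoid, T.hardsigmoid,
                                T.hardswish])
def test_activation_gradients(op, rng):
    # keep inputs away from the piecewise kinks of the hard activations
    base = rng.uniform(-6, 6, (40,))
    base = base[(np.abs(np.abs(base) - 3.0) > 0.1) & (np.abs(base) > 0.05)]
    x = Tensor(base, requires_grad=True)

    probe = Tensor(np.random.default_rng(0).standard_normal(x.shape))

    def build():
        x.grad = None
        return T.tsum(T.mul(op(x), probe))

    _check_grad(build, [x], tol=5e-3)


def test_gelu_is_exact_gaussian_cdf_form(rng):
    from scipy.stats import norm
    x = rng.standard_normal(100).astype(np.float32)
    y = T.gelu(Tensor(x))
    np.testing.assert_allclose(y.data, x * norm.cdf(x), atol=1e-6)


def test_maxpool_forward_and_gradient(rng):
    x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
    # keep each 2x2 window's top two entries well separated so the finite
    # difference cannot flip the argmax
    xw = x.reshape(2, 3, 3, 2, 3, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xw.reshape(2, 3, 3, 3, 4)
    top = xw.argmax(axis=-1)
    np.put_along_axis(xw, top[..., None],
                      np.take_along_axis(xw, top[..., None], -1) + 0.2, -1)
    x = xw.reshape(2, 3, 3, 3, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        2, 3, 6, 6).copy()
    out = T.maxpool2x2(Tensor(x))
    for n in range(2):
        for c in range(3):
            for i in range(3):
                for j in range(3):
                    assert out.data[n, c, i, j] == x[
                        n, c, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max()
    xt = Tensor(x, requires_grad=True)

    probe = Tensor(np.random.default_rng(0).standard_normal((2, 3, 3, 3)))

    def build():
        xt.grad = None
        return T.tsum(T.mul(T.maxpool2x2(xt), probe))

    _check_grad(build, [xt], tol=5e-3, eps=0.01)


def test_mean_concat_slice_transpose_gradients(rng):
    """Composite mirroring the coordinate-attention plumbing."""
    x = Tensor(rng.standard_normal((2, 3, 4, 5)), requires_grad=True)

    def build():
        x.grad = None
        ph = T.tmean(x, axis=3, keepdims=True)           # (2,3,4,1)
        pw = T.transpose(T.tmean(x, axis=2, keepdims=True), 2, 3)  # (2,3,5,1)
        f = T.concat([ph, pw], axis=2)                    # (2,3,9,1)
        fh = T.getitem(f, (slice(None), slice(None), slice(0, 4)))
        fw = T.getitem(f, (slice(None), slice(None), slice(4, 9)))
        y = T.add(T.tsum(T.mul(fh, fh)), T.tsum(T.mul(fw, fw)))
        return y

    _check_grad(build, [x])


def test_cross_entropy_matches_closed_form_and_gradient(rng):
    logits = rng.standard_normal((5, 6)).astype(np.float32)
    labels = np.array([0, 3, 5, 2, 2])
    loss = T.cross_entropy(Tensor(logits), labels)
    p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    expect = -np.log(p[np.arange(5), labels]).mean()
    assert loss.item() == pytest.approx(expect, rel=1e-5)

    lt = Tensor(logits, requires_grad=True)

    def build():
        lt.grad = None
        return T.cross_entropy(lt, labels)

    _check_grad(build, [lt], tol=1e-2)


def test_adam_minimises_quadratic():
    p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        p.grad = None
        loss = T.tsum(T.mul(p, p))
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_multi_consumer_gradient_accumulation(rng):
    """A tensor feeding two branches accumulates both contributions."""
    x = Tensor(rng.standard_normal((4,)), requires_grad=True)
    y = T.add(T.mul(x, x), x)      # d/dx = 2x + 1
    T.tsum(y).backward()
    np.testing.assert_allclose(x.grad, 2 * x.data + 1, rtol=1e-5)


def test_conv_module_parameter_shapes(rng):
    conv = Conv2d(8, 16, 3, groups=2, bias=True, rng=rng)
    assert conv.weight.shape == (16, 4, 3, 3)
    assert conv.bias.shape == (16,)
    with pytest.raises(ValueError):
        T.conv2d(Tensor(np.zeros((1, 5, 4, 4), np.float32)), conv.weight,
                 groups=2)
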