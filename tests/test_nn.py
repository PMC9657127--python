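"""The numpy layer stack: convolution, normalisation, pooling, optimiser."""

import numpy as np
import pytest

from crorelu import nn
from crorelu.backbones import SEBlock, SEModuleSpec, se_block
from crorelu.nn import functional as F


def _naive_conv(x, w, stride, pad, groups):
    n, cin, h, wid = x.shape
    cout, cig, kh, kw = w.shape
    sh, sw = stride
    ph, pw = pad
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wid + 2 * pw - kw) // sw + 1
    out = np.zeros((n, cout, ho, wo))
    cog = cout // groups
    for b in range(n):
        for o in range(cout):
            g = o // cog
            for i in range(ho):
                for j in range(wo):
                    patch = xp[b, g * cig:(g + 1) * cig, i * sh:i * sh + kh, j * sw:j * sw + kw]
                    out[b, o, i, j] = (patch * w[o]).sum()
    return out


@pytest.mark.parametrize("cin,cout,k,stride,pad,groups", [
    (3, 5, 3, (1, 1), (1, 1), 1),
    (4, 6, 3, (2, 2), (1, 1), 2),
    (6, 6, 3, (1, 1), (1, 1), 6),   # depthwise
    (3, 4, 1, (2, 2), (0, 0), 1),
    (2, 2, (3, 1), (1, 1), (1, 0), 2),
])
def test_conv2d_matches_naive_loop(rng, cin, cout, k, stride, pad, groups):
    kh, kw = (k, k) if np.isscalar(k) else k
    x = rng.standard_normal((2, cin, 7, 8))
    w = rng.standard_normal((cout, cin // groups, kh, kw))
    got, _ = F.conv2d_forward(x, w, stride, pad, groups)
    np.testing.assert_allclose(got, _naive_conv(x, w, stride, pad, groups), rtol=1e-10)


def test_conv2d_backward_matches_finite_differences(rng):
    x = rng.standard_normal((2, 4, 6, 5))
    w = rng.standard_normal((6, 2, 3, 3))
    proj = rng.standard_normal((2, 6, 3, 3))

    def loss(xv, wv):
        out, _ = F.conv2d_forward(xv, wv, (2, 2), (1, 1), 2)
        return (out * proj).sum()

    out, cache = F.conv2d_forward(x, w, (2, 2), (1, 1), 2)
    gx, gw, _ = F.conv2d_backward(proj, cache)
    eps = 1e-6
    for arr, grad in ((x, gx), (w, gw)):
        flat = arr.reshape(-1)
        for k in rng.choice(flat.size, size=8, replace=False):
            orig = flat[k]
            flat[k] = orig + eps
            lp = loss(x, w)
            flat[k] = orig - eps
            lm = loss(x, w)
            flat[k] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad.reshape(-1)[k]) < 1e-6 * max(1.0, abs(num))


def test_batchnorm_training_standardises_and_tracks(rng):
    bn = nn.BatchNorm2d(3, momentum=0.5)
    x = rng.standard_normal((8, 3, 4, 4)) * 3.0 + 1.0
    out = bn(x)
    np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-7)
    np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
    np.testing.assert_allclose(bn.running_mean, 0.5 * x.mean(axis=(0, 2, 3)), rtol=1e-6)
    bn.eval()
    out2 = bn(x)
    ref = (x - bn.running_mean[None, :, None, None]) / np.sqrt(
        bn.running_var[None, :, None, None] + bn.eps)
    np.testing.assert_allclose(out2, ref, rtol=1e-5)


def test_maxpool_matches_naive(rng):
    pool = nn.MaxPool2d(3, stride=2, padding=1)
    x = rng.standard_normal((2, 3, 7, 7))
    out = pool(x)
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    for b in range(2):
        for c in range(3):
            for i in range(out.shape[2]):
                for j in range(out.shape[3]):
                    assert out[b, c, i, j] == xp[b, c, 2 * i:2 * i + 3, 2 * j:2 * j + 3].max()
    # backward: gradient of sum(out) lands once per pooled window on an argmax
    g = pool.backward(np.ones_like(out))
    assert g.shape == x.shape
    assert g.sum() == out.size


def test_sequential_linear_relu_backward(rng):
    net = nn.Sequential(nn.Linear(4, 3, rng=rng), nn.ReLU(), nn.Linear(3, 2, rng=rng))
    x = rng.standard_normal((5, 4))
    proj = rng.standard_normal((5, 2))
    out = net(x)
    gx = net.backward(proj)
    eps = 1e-6
    for k in range(x.size):
        flat = x.reshape(-1)
        orig = flat[k]
        flat[k] = orig + eps
        lp = (net(x) * proj).sum()
        flat[k] = orig - eps
        lm = (net(x) * proj).sum()
        flat[k] = orig
        assert abs((lp - lm) / (2 * eps) - gx.reshape(-1)[k]) < 1e-6


class TestSqueezeExcitation:
    def test_hand_computed_identity_gate(self):
        """2 channels, reduction 1, identity weights: gate = sigmoid(relu(mean))."""
        x = np.arange(2 * 2 * 2 * 2, dtype=float).reshape(2, 2, 2, 2)
        spec = SEModuleSpec(channels=2, reduction=1, w_reduce=np.eye(2),
                            w_expand=np.eye(2))
        means = x.mean(axis=(2, 3))
        gate = 1.0 / (1.0 + np.exp(-np.maximum(means, 0.0)))
        np.testing.assert_allclose(se_block(x, spec), x * gate[:, :, None, None], rtol=1e-12)

    def test_zero_input_stays_zero(self, rng):
        spec = SEModuleSpec(channels=4, reduction=2,
                            w_reduce=rng.standard_normal((2, 4)),
                            w_expand=rng.standard_normal((4, 2)),
                            b_reduce=rng.standard_normal(2),
                            b_expand=rng.standard_normal(4))
        assert not se_block(np.zeros((1, 4, 3, 3)), spec).any()

    def test_gate_bounded_in_unit_interval(self, rng):
        block = SEBlock(8, reduction=2, rng=rng)
        x = rng.standard_normal((3, 8, 5, 5))
        block(x)
        _, g = block._cache
        assert ((g > 0) & (g < 1)).all()

    def test_module_backward_matches_finite_differences(self, rng):
        block = SEBlock(4, reduction=2, rng=rng)
        for p in block.parameters():
            p.data = p.data.astype(np.float64)
            p.grad = np.zeros_like(p.data)
        x = rng.standard_normal((2, 4, 3, 3))
        proj = rng.standard_normal(x.shape)
        block(x)
        gx = block.backward(proj)
        eps = 1e-6
        flat = x.reshape(-1)
        for k in rng.choice(x.size, size=10, replace=False):
            orig = flat[k]
            flat[k] = orig + eps
            lp = (block(x) * proj).sum()
            flat[k] = orig - eps
            lm = (block(x) * proj).sum()
            flat[k] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gx.reshape(-1)[k]) < 1e-5 * max(1.0, abs(num))


class TestOptim:
    def test_radam_first_step_is_unrectified_mean_step(self):
        p = nn.Parameter(np.array([1.0, -2.0]))
        opt = nn.RAdam([p], lr=0.1)
        p.grad = np.array([0.5, -0.5])
        opt.step()
        # t=1, beta2=0.999 -> variance not yet tractable: plain bias-corrected step
        np.testing.assert_allclose(p.data, [1.0 - 0.1 * 0.5, -2.0 + 0.1 * 0.5])

    def test_radam_descends_quadratic(self):
        p = nn.Parameter(np.array([3.0, -4.0]))
        opt = nn.RAdam([p], lr=0.05)
        for _ in range(500):
            p.grad = p.data.copy()  # f = ||w||^2 / 2
            opt.step()
        assert np.linalg.norm(p.data) < 0.1

    def test_step_decay_schedule(self):
        opt = nn.RAdam([nn.Parameter(np.zeros(1))], lr=1e-4)
        sched = nn.StepLR(opt, step_size=20, gamma=0.1)
        assert sched.lr_at(0) == pytest.approx(1e-4)
        assert sched.lr_at(19) == pytest.approx(1e-4)
        assert sched.lr_at(20) == pytest.approx(1e-5)
        assert sched.lr_at(40) == pytest.approx(1e-6)


def test_cross_entropy_matches_manual(rng):
    logits = rng.standard_normal((4, 3))
    labels = np.array([0, 2, 1, 1])
    loss, grad = F.cross_entropy(logits, labels)
    p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    manual = -np.log(p[np.arange(4), labels]).mean()
    assert loss == pytest.approx(manual, rel=1e-10)
    eps = 1e-6
    flat = logits.reshape(-1)
    for k in range(flat.size):
        orig = flat[k]
        flat[k] = orig + eps
        lp, _ = F.cross_entropy(logits, labels)
        flat[k] = orig - eps
        lm, _ = F.cross_entropy(logits, labels)
        flat[k] = orig
        assert abs((lp - lm) / (2 * eps) - grad.reshape(-1)[k]) < 1e-8
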