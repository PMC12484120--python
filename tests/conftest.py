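"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (nested Python loops, direct
arithmetic) so they are independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mafnet import nn


def naive_dilated_conv2d(x: np.ndarray, w: np.ndarray, d: int) -> np.ndarray:
    """Brute-force stride-1 'same' dilated convolution (no bias)."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    ph, pw = ((kh - 1) * d) // 2, ((kw - 1) * d) // 2
    y = np.zeros((n, cout, h, wd), dtype=np.float64)
    for b in range(n):
        for o in range(cout):
            for p in range(h):
                for q in range(wd):
                    acc = 0.0
                    for c in range(cin):
                        for i in range(kh):
                            for j in range(kw):
                                r, t = p + i * d - ph, q + j * d - pw
                                if 0 <= r < h and 0 <= t < wd:
                                    acc += x[b, c, r, t] * w[o, c, i, j]
                    y[b, o, p, q] = acc
    return y


def naive_confusion(pred: np.ndarray, truth: np.ndarray):
    """Nested-loop pixel tally -> (tp, tn, fp, fn)."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel().tolist(), truth.ravel().tolist()):
        if p and t:
            tp += 1
        elif not p and not t:
            tn += 1
        elif p and not t:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def zero_attention_params(module: nn.Module) -> None:
    """Zero every parameter of attention submodules so all gates read 0.5."""
    from mafnet.attention import ChannelAttention, SEBlock, SpatialAttention

    for m in module.modules():
        if isinstance(m, (SpatialAttention, ChannelAttention, SEBlock)):
            for p in m.parameters():
                p.data = np.zeros_like(p.data)


def identity_conv(conv: nn.Conv2d) -> None:
    """Set a square conv to the identity map (center-tap delta kernel)."""
    w = np.zeros_like(conv.weight.data)
    k = w.shape[2] // 2
    for o in range(min(w.shape[0], w.shape[1])):
        w[o, o, k, k] = 1.0
    conv.weight.data = w
    if conv.bias is not None:
        conv.bias.data = np.zeros_like(conv.bias.data)


# batch-norm eval-mode gain with default buffers (mean 0, var 1)
BN_SCALE = 1.0 / np.sqrt(1.0 + 1e-5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """10 small phantoms: 8 train / 1 val / 1 test at 32x32."""
    from mafnet import PhantomConfig, SegmentationDataset, generate_phantoms

    samples = generate_phantoms(PhantomConfig(n_images=10, size=32, seed=3))
    return SegmentationDataset.from_samples(samples[:8], samples[8:9], samples[9:])
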