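"""Differentiable losses: MSE and the Wang et al. SSIM index.

The SSIM here follows the Gaussian-weighted convention (11-tap sampled
Gaussian window, sigma 1.5, population covariance, 5-pixel border crop), so
its value agrees with ``skimage.metrics.structural_similarity(...,
gaussian_weights=True, sigma=1.5, use_sample_covariance=False)`` to float
precision while remaining differentiable for training.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

_SSIM_SIGMA = 1.5
_SSIM_RADIUS = 5  # int(3.5 * sigma + 0.5), an 11-tap window


def _gaussian_kernel() -> np.ndarray:
    x = np.arange(-_SSIM_RADIUS, _SSIM_RADIUS + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / _SSIM_SIGMA) ** 2)
    g /= g.sum()
    return np.outer(g, g)[None, None]


_KERNEL = Tensor(_gaussian_kernel())
_NOPAD = ((0, 0), (0, 0))


def _blur(x: Tensor) -> Tensor:
    # valid-mode Gaussian filtering; the border crop makes the result
    # independent of any boundary-extension convention
    return T.conv2d(x, _KERNEL, None, pad=_NOPAD)


def mse(x: Tensor, y: Tensor) -> Tensor:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return T.mean_axes(T.square(T.sub(x, y)))


def ssim(x: Tensor, y: Tensor, data_range: float) -> Tensor:
    """Mean SSIM of two (N, C, H, W) stacks, computed per frame and averaged."""
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n, c, h, w = x.shape
    win = 2 * _SSIM_RADIUS + 1
    if h < win or w < win:
        raise ValueError(f"images smaller than the {win}x{win} SSIM window")
    xf = T.reshape(x, (n * c, 1, h, w))
    yf = T.reshape(y, (n * c, 1, h, w))
    ux = _blur(xf)
    uy = _blur(yf)
    uxx = _blur(T.square(xf))
    uyy = _blur(T.square(yf))
    uxy = _blur(T.mul(xf, yf))
    vx = T.sub(uxx, T.square(ux))
    vy = T.sub(uyy, T.square(uy))
    vxy = T.sub(uxy, T.mul(ux, uy))
    c1 = Tensor((0.01 * data_range) ** 2)
    c2 = Tensor((0.03 * data_range) ** 2)
    a1 = T.add(T.mul(Tensor(2.0), T.mul(ux, uy)), c1)
    a2 = T.add(T.mul(Tensor(2.0), vxy), c2)
    b1 = T.add(T.add(T.square(ux), T.square(uy)), c1)
    b2 = T.add(T.add(vx, vy), c2)
    s = T.div(T.mul(a1, a2), T.mul(b1, b2))
    return T.mean_axes(s)
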