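"""Network architectures for dual-tracer reconstruction and separation.

Three composite models share two building blocks:

* **FBPNet** — a learnable frequency-domain filter applied to the sinogram's
  radial axis, a fixed (parameter-free) back-projection, and a shallow
  residual CNN denoiser.  The filter is initialised to the analytic ramp, so
  an untrained network with the denoiser disabled reproduces classic FBP.
* **SeparationNet** — convolution blocks, an Inception-like module with
  global H x 1 and 1 x W kernels (full-row/full-column receptive fields),
  and channel attention over the time dimension; its 2C-channel output is
  split into the two single-tracer dynamic images.

Variants: ``fbpnet_sep`` reconstructs then separates in image space;
``sep_fbpnet`` separates the sinogram first and reconstructs each tracer
with one weight-shared FBPNet; ``fbpnet_dc_sep`` feeds the reconstruction
plus two decay-corrected copies (one per tracer half-life) through separate
Inception stems before a merged separation head.

Channel widths are configuration; the canonical widths are chosen so the
assembled fbpnet_sep / sep_fbpnet models carry ~0.64 M / ~0.66 M trainable
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor
from .acquisition import GeomConfig, system_matrix
from .kinetics import DynamicImage, ScanProtocol
from .recon_classic import fbp_pad_length, ramp_filter

__all__ = [
    "SeparationNetConfig",
    "FBPNetConfig",
    "ModelVariant",
    "SeparationNet",
    "DCSeparationNet",
    "FBPNet",
    "FBPnetSep",
    "SepFBPnet",
    "FBPnetDCSep",
    "assemble_variant",
    "count_parameters",
    "decay_correct_image",
    "decay_correction_factors",
    "CANONICAL_WIDTHS",
]

#: canonical channel widths — sized so the assembled fbpnet_sep and
#: sep_fbpnet models land on their 0.64 M / 0.66 M parameter budgets
CANONICAL_WIDTHS = dict(conv1=32, conv2=25, inception=25, denoiser=183)


@dataclass(frozen=True)
class SeparationNetConfig:
    in_channels: int                    # C, the number of frames
    in_hw: tuple[int, int]              # spatial size (H, W) of the input
    conv1_width: int = 32
    conv2_width: int = 25
    inception_width: int = 25           # per-branch width of the H x 1 / 1 x W pair
    use_inception: bool = True
    use_attention: bool = True

    @property
    def out_channels(self) -> int:
        return 2 * self.in_channels


@dataclass(frozen=True)
class FBPNetConfig:
    geom: GeomConfig
    in_channels: int
    denoiser_width: int = 183


@dataclass(frozen=True)
class ModelVariant:
    kind: str                           # fbpnet_sep | sep_fbpnet | fbpnet_dc_sep
    half_lives: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("fbpnet_sep", "sep_fbpnet", "fbpnet_dc_sep"):
            raise ValueError(f"unknown variant {self.kind!r}")
        if self.kind == "fbpnet_dc_sep" and self.half_lives is None:
            raise ValueError("fbpnet_dc_sep requires both tracer half-lives")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class InceptionGlobal(nn.Module):
    """Parallel H x 1 and 1 x W convolution blocks, concatenated on channels.

    Each output pixel of the two branches sees an entire image column or row,
    providing a global spatial receptive field in a single layer.
    """

    def __init__(self, in_ch: int, branch_width: int, in_hw: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        h, w = in_hw
        if h < 1 or w < 1:
            raise ValueError("spatial size too small for global kernels")
        self.col_branch = nn.ConvBlock(in_ch, branch_width, h, 1, rng)
        self.row_branch = nn.ConvBlock(in_ch, branch_width, 1, w, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return T.concat([self.col_branch(x), self.row_branch(x)], axis=1)


class ChannelAttention(nn.Module):
    """Squeeze-and-excitation style attention over the frame dimension.

    Global max- and average-pooled channel descriptors pass through a shared
    two-layer fully-connected block (width = channel count, no bottleneck),
    are summed, and squashed by a sigmoid into per-channel weights in (0, 1).
    """

    def __init__(self, n_ch: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(n_ch, n_ch, rng)
        self.fc2 = nn.Linear(n_ch, n_ch, rng)
        self.last_weights: np.ndarray | None = None

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(T.relu(self.fc1(v)))

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        mx = T.reshape(T.max_pool_global(x), (n, c))
        av = T.reshape(T.avg_pool_global(x), (n, c))
        w = T.sigmoid(T.add(self._mlp(mx), self._mlp(av)))
        self.last_weights = w.data.copy()
        return T.mul(x, T.reshape(w, (n, c, 1, 1)))


class SeparationNet(nn.Module):
    """Single-stem separation network (Fig-style: conv, Inception, attention,
    conv head, channel split)."""

    def __init__(self, cfg: SeparationNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, c2 = cfg.in_channels, cfg.out_channels
        self.block1 = nn.ConvBlock(c, cfg.conv1_width, 3, 3, rng)
        self.block2 = nn.ConvBlock(cfg.conv1_width, cfg.conv2_width, 3, 3, rng)
        if cfg.use_inception:
            self.inception = InceptionGlobal(cfg.conv2_width,
                                             cfg.inception_width, cfg.in_hw, rng)
        else:
            # local fallback used by the ablation study
            self.inception = nn.ConvBlock(cfg.conv2_width,
                                          2 * cfg.inception_width, 3, 3, rng)
        self.block3 = nn.ConvBlock(2 * cfg.inception_width, c2, 3, 3, rng)
        self.attention = ChannelAttention(c2, rng) if cfg.use_attention else None
        self.block4 = nn.ConvBlock(c2, c2, 3, 3, rng)
        self.out_conv = nn.Conv2d(c2, c2, 3, 3, rng)

    def features(self, x: Tensor) -> Tensor:
        y = self.block3(self.inception(self.block2(self.block1(x))))
        if self.attention is not None:
            y = self.attention(y)
        return self.out_conv(self.block4(y))

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, "
                             f"got {x.shape[1]}")
        y = self.features(x)
        c = self.cfg.in_channels
        return T.narrow(y, 1, 0, c), T.narrow(y, 1, c, 2 * c)


class DCSeparationNet(nn.Module):
    """Separation head with three Inception stems (uncorrected + two
    decay-corrected inputs), merged by concatenation and a 1 x 1 convolution."""

    def __init__(self, cfg: SeparationNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, c2 = cfg.in_channels, cfg.out_channels
        self.stems = []
        for _ in range(3):
            stem = nn.Module()
            stem.block1 = nn.ConvBlock(c, cfg.conv1_width, 3, 3, rng)
            stem.block2 = nn.ConvBlock(cfg.conv1_width, cfg.conv2_width, 3, 3, rng)
            stem.inception = InceptionGlobal(cfg.conv2_width,
                                             cfg.inception_width, cfg.in_hw, rng)
            self.stems.append(stem)
        self.merge = nn.Conv2d(6 * cfg.inception_width, c2, 1, 1, rng)
        self.attention = ChannelAttention(c2, rng)
        self.block4 = nn.ConvBlock(c2, c2, 3, 3, rng)
        self.out_conv = nn.Conv2d(c2, c2, 3, 3, rng)

    def __call__(self, branches: list[Tensor]) -> tuple[Tensor, Tensor]:
        if len(branches) != 3:
            raise ValueError("DC separation expects three input branches")
        feats = [stem.inception(stem.block2(stem.block1(b)))
                 for stem, b in zip(self.stems, branches)]
        y = self.attention(T.relu(self.merge(T.concat(feats, axis=1))))
        y = self.out_conv(self.block4(y))
        c = self.cfg.in_channels
        return T.narrow(y, 1, 0, c), T.narrow(y, 1, c, 2 * c)


class FBPNet(nn.Module):
    """Learnable-filter FBP followed by a residual CNN denoiser.

    The sinogram is zero-padded along the radial axis, multiplied in the
    real-FFT domain by a learnable filter (initialised to the discrete ramp),
    inverse-transformed, and mapped to image space by fixed back-projection;
    the residual denoiser then removes streak noise.  ``make_identity()``
    zeroes the residual and disables the output rectifier, reducing the
    network exactly to classic FBP.
    """

    def __init__(self, cfg: FBPNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        geom = cfg.geom
        self.pad_len = fbp_pad_length(geom.n_bins)
        self.filter = Tensor(ramp_filter(self.pad_len), requires_grad=True)
        # fixed back-projection (no trainable parameters), FBP-normalised
        self._bp = (system_matrix(geom).T * (np.pi / (2.0 * geom.n_angles))).tocsr()
        m = cfg.denoiser_width
        c = cfg.in_channels
        self.dn1 = nn.ConvBlock(c, m, 3, 3, rng)
        self.dn2 = nn.ConvBlock(m, m, 3, 3, rng)
        self.dn3 = nn.Conv2d(m, c, 3, 3, rng)
        self.final_relu = True

    def make_identity(self) -> "FBPNet":
        """Disable the denoiser (zero residual, no output rectifier)."""
        self.dn3.weight.data[...] = 0.0
        self.dn3.bias.data[...] = 0.0
        self.final_relu = False
        return self

    def __call__(self, s: Tensor) -> Tensor:
        geom = self.cfg.geom
        if s.shape[2] != geom.n_bins or s.shape[3] != geom.n_angles:
            raise ValueError("sinogram shape does not match geometry")
        filtered = T.fourier_filter(s, self.filter, self.pad_len)
        img = T.backproject(filtered, self._bp,
                            (geom.image_size, geom.image_size))
        res = self.dn3(self.dn2(self.dn1(img)))
        out = T.add(img, res)
        return T.relu(out) if self.final_relu else out


# ---------------------------------------------------------------------------
# decay correction
# ---------------------------------------------------------------------------

def decay_correction_factors(protocol: ScanProtocol, T_half: float) -> np.ndarray:
    """Per-frame factors 2^(+t_mid/T) undoing physical decay at midpoints."""
    if T_half <= 0:
        raise ValueError("half-life must be positive")
    return 2.0 ** (protocol.midpoints / T_half)


def decay_correct_image(img: DynamicImage, T_half: float) -> DynamicImage:
    """Decay-correct a dynamic image (inverse of the applied decay)."""
    fac = decay_correction_factors(img.protocol, T_half)
    return DynamicImage(img.values * fac, img.protocol, decay_corrected=True)


# ---------------------------------------------------------------------------
# composite variants
# ---------------------------------------------------------------------------

class FBPnetSep(nn.Module):
    """Reconstruct the dual-tracer image with FBPNet, then separate it."""

    kind = "fbpnet_sep"

    def __init__(self, fbpnet: FBPNet, sepnet: SeparationNet):
        super().__init__()
        self.fbpnet = fbpnet
        self.sepnet = sepnet

    def __call__(self, s_dual: Tensor) -> dict[str, Tensor]:
        i_dual = self.fbpnet(s_dual)
        i1, i2 = self.sepnet(i_dual)
        return {"I_dual_hat": i_dual, "I1_hat": i1, "I2_hat": i2}


class SepFBPnet(nn.Module):
    """Separate the dual-tracer sinogram, then reconstruct each single-tracer
    sinogram with one weight-shared FBPNet."""

    kind = "sep_fbpnet"

    def __init__(self, fbpnet: FBPNet, sepnet: SeparationNet):
        super().__init__()
        self.fbpnet = fbpnet
        self.sepnet = sepnet

    def __call__(self, s_dual: Tensor) -> dict[str, Tensor]:
        s1, s2 = self.sepnet(s_dual)
        return {
            "S1_hat": s1,
            "S2_hat": s2,
            "I1_hat": self.fbpnet(s1),
            "I2_hat": self.fbpnet(s2),
        }


class FBPnetDCSep(nn.Module):
    """FBPNet reconstruction, then separation of {uncorrected, decay-corrected
    as tracer 1, decay-corrected as tracer 2} through per-branch stems."""

    kind = "fbpnet_dc_sep"

    def __init__(self, fbpnet: FBPNet, sepnet: DCSeparationNet,
                 protocol: ScanProtocol, half_lives: tuple[float, float]):
        super().__init__()
        self.fbpnet = fbpnet
        self.sepnet = sepnet
        self.half_lives = half_lives
        f1 = decay_correction_factors(protocol, half_lives[0])
        f2 = decay_correction_factors(protocol, half_lives[1])
        self._dc1 = Tensor(f1[None, :, None, None])
        self._dc2 = Tensor(f2[None, :, None, None])

    def __call__(self, s_dual: Tensor) -> dict[str, Tensor]:
        i_dual = self.fbpnet(s_dual)
        branches = [i_dual, T.mul(i_dual, self._dc1), T.mul(i_dual, self._dc2)]
        i1, i2 = self.sepnet(branches)
        return {"I_dual_hat": i_dual, "I1_hat": i1, "I2_hat": i2}


def assemble_variant(variant: ModelVariant | str,
                     geom: GeomConfig = GeomConfig(),
                     n_frames: int = 26,
                     protocol: ScanProtocol | None = None,
                     widths: dict | None = None,
                     seed: int = 0,
                     use_inception: bool = True,
                     use_attention: bool = True) -> nn.Module:
    """Build a model variant with deterministic (seeded) initialisation."""
    if isinstance(variant, str):
        variant = ModelVariant(variant, half_lives=(109.8, 20.4)
                               if variant == "fbpnet_dc_sep" else None)
    w = dict(CANONICAL_WIDTHS)
    if widths:
        w.update(widths)
    rng = np.random.default_rng(seed)
    fb_cfg = FBPNetConfig(geom=geom, in_channels=n_frames,
                          denoiser_width=w["denoiser"])
    n = geom.image_size
    img_cfg = SeparationNetConfig(
        in_channels=n_frames, in_hw=(n, n), conv1_width=w["conv1"],
        conv2_width=w["conv2"], inception_width=w["inception"],
        use_inception=use_inception, use_attention=use_attention)
    if variant.kind == "fbpnet_sep":
        return FBPnetSep(FBPNet(fb_cfg, rng), SeparationNet(img_cfg, rng))
    if variant.kind == "sep_fbpnet":
        sino_cfg = SeparationNetConfig(
            in_channels=n_frames, in_hw=(geom.n_bins, geom.n_angles),
            conv1_width=w["conv1"], conv2_width=w["conv2"],
            inception_width=w["inception"], use_inception=use_inception,
            use_attention=use_attention)
        return SepFBPnet(FBPNet(fb_cfg, rng), SeparationNet(sino_cfg, rng))
    # fbpnet_dc_sep
    if protocol is None:
        protocol = ScanProtocol.default()
    if protocol.n_frames != n_frames:
        raise ValueError("protocol frame count does not match n_frames")
    return FBPnetDCSep(FBPNet(fb_cfg, rng), DCSeparationNet(img_cfg, rng),
                       protocol, variant.half_lives)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars in a model (mode-independent)."""
    return model.count_parameters()
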