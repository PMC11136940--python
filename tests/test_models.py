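"""Architectures: shapes, attention behaviour, parameter budgets, FBP-Net
equivalence with classic FBP, decay correction."""

import numpy as np
import pytest

import dualpet.nn.tensor as T
from dualpet.acquisition import GeomConfig, project
from dualpet.kinetics import DynamicImage, ScanProtocol, apply_decay
from dualpet.models import (CANONICAL_WIDTHS, ChannelAttention, FBPNet,
                            FBPNetConfig, InceptionGlobal, ModelVariant,
                            SeparationNet, SeparationNetConfig,
                            assemble_variant, count_parameters,
                            decay_correct_image)
from dualpet.nn import Conv2d
from dualpet.nn.tensor import Tensor
from dualpet.recon_classic import fbp

RNG = np.random.default_rng(0)
SMALL_GEOM = GeomConfig(image_size=32, n_bins=32, n_angles=60)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def test_inception_concatenates_global_branches():
    inc = InceptionGlobal(3, 4, (12, 10), RNG)
    x = Tensor(RNG.normal(size=(2, 3, 12, 10)))
    y = inc(x)
    assert y.shape == (2, 8, 12, 10)  # 2 x branch width, spatial preserved


def test_inception_row_feature_reaches_every_column():
    """A single bright pixel influences its whole row and column outputs."""
    inc = InceptionGlobal(1, 1, (8, 8), RNG)
    assert inc.row_branch.conv.weight.shape == (1, 1, 1, 8)
    assert inc.col_branch.conv.weight.shape == (1, 1, 8, 1)

    def delta(branch, r, c):
        x = np.zeros((1, 1, 8, 8))
        x[0, 0, r, c] = 10.0
        zero = branch.conv(Tensor(np.zeros_like(x))).data
        return np.abs(branch.conv(Tensor(x)).data - zero)[0, 0]

    # the centre output pixel of a row/column sees the entire row/column
    for c in range(8):
        assert delta(inc.row_branch, 3, c)[3, 3] > 0
    for r in range(8):
        assert delta(inc.col_branch, r, 5)[3, 5] > 0


def test_channel_attention_weights_in_unit_interval():
    ca = ChannelAttention(6, RNG)
    x = Tensor(RNG.normal(size=(3, 6, 5, 5)))
    y = ca(x)
    assert y.shape == x.shape
    assert np.all(ca.last_weights > 0) and np.all(ca.last_weights < 1)


def test_channel_attention_zero_weights_halve_input():
    ca = ChannelAttention(4, RNG)
    for p in (ca.fc1.weight, ca.fc1.bias, ca.fc2.weight, ca.fc2.bias):
        p.data[...] = 0.0
    x = Tensor(RNG.normal(size=(2, 4, 6, 6)))
    y = ca(x)
    assert np.allclose(ca.last_weights, 0.5)
    assert np.allclose(y.data, x.data / 2)


# ---------------------------------------------------------------------------
# separation network
# ---------------------------------------------------------------------------

def _sep_cfg(**kw):
    base = dict(in_channels=4, in_hw=(16, 16), conv1_width=6, conv2_width=5,
                inception_width=5)
    base.update(kw)
    return SeparationNetConfig(**base)


def test_separation_forward_splits_into_two_stacks():
    net = SeparationNet(_sep_cfg(), RNG)
    x = Tensor(RNG.normal(size=(2, 4, 16, 16)))
    i1, i2 = net(x)
    assert i1.shape == (2, 4, 16, 16)
    assert i2.shape == (2, 4, 16, 16)


def test_separation_rejects_wrong_channel_count():
    net = SeparationNet(_sep_cfg(), RNG)
    with pytest.raises(ValueError, match="channels"):
        net(Tensor(np.zeros((1, 3, 16, 16))))


def test_separation_eval_forward_deterministic():
    net = SeparationNet(_sep_cfg(), RNG).eval()
    x = Tensor(RNG.normal(size=(1, 4, 16, 16)))
    a, _ = net(x)
    b, _ = net(x)
    assert np.array_equal(a.data, b.data)


def test_ablations_strictly_reduce_parameters():
    full = SeparationNet(_sep_cfg(), np.random.default_rng(1))
    no_inc = SeparationNet(_sep_cfg(use_inception=False),
                           np.random.default_rng(1))
    no_ca = SeparationNet(_sep_cfg(use_attention=False),
                          np.random.default_rng(1))
    assert no_inc.count_parameters() < full.count_parameters()
    assert no_ca.count_parameters() < full.count_parameters()


# ---------------------------------------------------------------------------
# FBP-Net
# ---------------------------------------------------------------------------

def test_fbpnet_matches_classic_fbp_when_identity():
    """Ramp-initialised filter + identity denoiser == classic FBP to 1e-4."""
    geom = SMALL_GEOM
    yy, xx = np.mgrid[0:32, 0:32]
    disk = (((yy - 15.5) ** 2 + (xx - 15.5) ** 2) <= 100).astype(float)
    prot = ScanProtocol((0.0, 1.0, 2.0))
    img = DynamicImage(np.stack([disk, 3 * disk], axis=2), prot)
    sino = project(img, geom)
    classic = np.moveaxis(fbp(sino, geom).values, 2, 0)[None]

    net = FBPNet(FBPNetConfig(geom=geom, in_channels=2, denoiser_width=4),
                 RNG).make_identity()
    out = net(Tensor(np.moveaxis(sino.values, 2, 0)[None]))
    rel = np.abs(out.data - classic).max() / np.abs(classic).max()
    assert rel < 1e-4


def test_fbpnet_backprojection_has_no_trainable_parameters():
    net = FBPNet(FBPNetConfig(geom=SMALL_GEOM, in_channels=2,
                              denoiser_width=4), RNG)
    # trainable scalars: filter + denoiser convs/BN only
    expected = (net.filter.data.size
                + sum(p.data.size for p in net.dn1.parameters())
                + sum(p.data.size for p in net.dn2.parameters())
                + sum(p.data.size for p in net.dn3.parameters()))
    assert net.count_parameters() == expected


def test_fbpnet_output_shape_and_nonnegativity():
    net = FBPNet(FBPNetConfig(geom=SMALL_GEOM, in_channels=3,
                              denoiser_width=4), RNG)
    s = Tensor(RNG.poisson(10, size=(2, 3, 32, 60)).astype(float))
    out = net(s)
    assert out.shape == (2, 3, 32, 32)
    assert out.data.min() >= 0.0  # final ReLU


# ---------------------------------------------------------------------------
# decay correction
# ---------------------------------------------------------------------------

def test_decay_correct_inverts_applied_decay():
    prot = ScanProtocol(tuple(np.linspace(0, 60, 7)))
    rng_img = RNG.uniform(1, 5, size=(8, 8, 6))
    decayed = DynamicImage(
        apply_decay(rng_img, prot, 20.4), prot)
    restored = decay_correct_image(decayed, 20.4)
    assert np.allclose(restored.values, rng_img, rtol=1e-12)
    assert restored.decay_corrected
    near_identity = decay_correct_image(decayed, 1e12)
    assert np.allclose(near_identity.values, decayed.values, rtol=1e-9)
    with pytest.raises(ValueError):
        decay_correct_image(decayed, -1.0)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _tiny_kwargs():
    prot = ScanProtocol(tuple(np.linspace(0, 60, 4)))
    return dict(geom=SMALL_GEOM, n_frames=3, protocol=prot,
                widths=dict(conv1=6, conv2=4, inception=4, denoiser=6))


@pytest.mark.parametrize("variant", ["fbpnet_sep", "sep_fbpnet",
                                     "fbpnet_dc_sep"])
def test_all_variants_share_the_sinogram_to_images_contract(variant):
    model = assemble_variant(variant, **_tiny_kwargs())
    s = Tensor(RNG.poisson(8, size=(2, 3, 32, 60)).astype(float))
    out = model(s)
    assert out["I1_hat"].shape == (2, 3, 32, 32)
    assert out["I2_hat"].shape == (2, 3, 32, 32)


def test_dc_variant_equal_half_lives_give_equal_branches():
    model = assemble_variant(ModelVariant("fbpnet_dc_sep",
                                          half_lives=(109.8, 109.8)),
                             **_tiny_kwargs())
    assert np.array_equal(model._dc1.data, model._dc2.data)


def test_dc_variant_requires_half_lives():
    with pytest.raises(ValueError, match="half-lives"):
        ModelVariant("fbpnet_dc_sep")


def test_canonical_parameter_budgets():
    """Assembled models round to the 0.64 M / 0.66 M budgets."""
    m1 = assemble_variant("fbpnet_sep")
    m2 = assemble_variant("sep_fbpnet")
    assert round(count_parameters(m1) / 1e6, 2) == 0.64
    assert round(count_parameters(m2) / 1e6, 2) == 0.66


def test_count_parameters_small_conv_and_mode_invariance():
    conv = Conv2d(1, 8, 3, 3, RNG)
    assert sum(p.data.size for p in conv.parameters()) == 80  # 3*3*8 + 8
    model = assemble_variant("fbpnet_sep", **_tiny_kwargs())
    n_train = count_parameters(model.train())
    n_eval = count_parameters(model.eval())
    assert n_train == n_eval


def test_gradients_flow_to_filter_and_all_weights():
    model = assemble_variant("fbpnet_sep", **_tiny_kwargs(), seed=3)
    s = Tensor(RNG.poisson(8, size=(2, 3, 32, 60)).astype(float))
    out = model(s)
    loss = T.add(T.mean_axes(T.square(out["I1_hat"])),
                 T.mean_axes(T.square(out["I2_hat"])))
    T.backward(loss)
    for p in model.parameters():
        assert p.grad is not None
        assert np.all(np.isfinite(p.grad))
    assert np.any(model.fbpnet.filter.grad != 0)
    nonzero = sum(np.any(p.grad != 0) for p in model.parameters())
    assert nonzero == len(model.parameters())
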