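"""Projector, noise model, dose thinning, group assembly and scaling."""

import numpy as np
import pytest

from dualpet.acquisition import (DynamicSinogram, GeomConfig, SampleGroup,
                                 add_randoms_and_noise, make_group, project,
                                 scale_group, system_matrix, thin_counts,
                                 unscale_group)
from dualpet.kinetics import (FDG_INPUT_PARAMS, DynamicImage, KineticParams,
                              ScanProtocol, TracerSpec)
from dualpet.phantoms import PhantomConfig, generate_phantom
from dualpet.workflow import plan_dataset

GEOM = GeomConfig(image_size=32, n_bins=32, n_angles=60)
PROT = ScanProtocol((0.0, 1.0))


def _disk(n=32, r=10):
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (((yy - c) ** 2 + (xx - c) ** 2) <= r * r).astype(float)


def _img(values2d, protocol=PROT):
    return DynamicImage(values2d[:, :, None], protocol)


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

def test_project_zero_image_gives_zero_sinogram():
    sino = project(_img(np.zeros((32, 32))), GEOM)
    assert sino.shape == (32, 60, 1)
    assert np.all(sino.values == 0)


def test_projector_adjoint_identity():
    """<Gx, y> == <x, G^T y> to 1e-6 relative (exact transpose)."""
    G = system_matrix(GEOM)
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(size=G.shape[1])
        y = rng.normal(size=G.shape[0])
        lhs = (G @ x) @ y
        rhs = x @ (G.T @ y)
        assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), 1.0)


def test_projector_linearity():
    rng = np.random.default_rng(1)
    a, b = 2.5, -1.25
    x = rng.random((32, 32))
    y = rng.random((32, 32))
    s_comb = project(_img(a * x + b * y), GEOM).values
    s_sep = a * project(_img(x), GEOM).values + b * project(_img(y), GEOM).values
    assert np.allclose(s_comb, s_sep, rtol=1e-6, atol=1e-9)


def test_per_angle_mass_conservation_for_infield_disk():
    disk = _disk()
    sino = project(_img(disk), GEOM)
    per_angle = sino.values[:, :, 0].sum(axis=0)
    assert np.allclose(per_angle, disk.sum(), rtol=1e-10)


def test_project_size_mismatch_raises():
    with pytest.raises(ValueError, match="does not match geometry"):
        project(DynamicImage(np.zeros((16, 16, 1)), PROT), GEOM)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_noise_zero_clean_zero_frac_gives_zeros():
    clean = DynamicSinogram(np.zeros((32, 60, 1)), PROT)
    out = add_randoms_and_noise(clean, 0.0, 0)
    assert np.all(out.values == 0)
    assert out.noisy


def test_randoms_total_is_exact_fraction():
    sino = project(_img(100 * _disk()), GEOM)
    from dualpet.acquisition import randoms_field
    r = randoms_field(sino, 0.2)
    assert r.sum() == pytest.approx(0.2 * sino.values.sum(), rel=1e-12)
    assert np.ptp(r[:, :, 0]) == 0  # spatially uniform
    with pytest.raises(ValueError):
        randoms_field(sino, -0.1)


def test_noisy_mean_consistent_with_clean_plus_randoms():
    clean = DynamicSinogram(np.full((8, 10, 1), 50.0), PROT)
    draws = np.stack([add_randoms_and_noise(clean, 0.2, s).values
                      for s in range(1000)])
    expected = 50.0 * 1.2
    se = np.sqrt(expected / draws.size)  # SE of the grand mean
    assert np.abs(draws.mean() - expected) < 3 * se
    # per-bin dispersion consistent with Poisson
    disp = draws.var(axis=0) / draws.mean(axis=0)
    assert 0.85 < disp.mean() < 1.15


def test_thinning_identity_total_and_dispersion():
    rng = np.random.default_rng(3)
    counts = DynamicSinogram(rng.poisson(40.0, (16, 20, 1)).astype(float),
                             PROT, noisy=True)
    same = thin_counts(counts, 1.0, 0)
    assert np.array_equal(same.values, counts.values)

    total = counts.values.sum()
    half = thin_counts(counts, 0.5, 1)
    assert abs(half.values.sum() - total / 2) <= 4 * np.sqrt(total / 2)

    # thinning a Poisson field keeps index of dispersion ~ 1
    field = DynamicSinogram(np.full((4, 5, 1), 30.0), PROT)
    thinned = np.stack([
        thin_counts(add_randoms_and_noise(field, 0.0, s), 0.5, 1000 + s).values
        for s in range(1000)])
    disp = thinned.var(axis=0) / thinned.mean(axis=0)
    assert 0.9 < disp.mean() < 1.1


def test_thinning_rejects_bad_fractions_and_nonintegers():
    counts = DynamicSinogram(np.ones((4, 5, 1)), PROT, noisy=True)
    for bad in (0.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            thin_counts(counts, bad, 0)
    frac = DynamicSinogram(np.full((4, 5, 1), 0.5), PROT, noisy=True)
    with pytest.raises(ValueError, match="integer"):
        thin_counts(frac, 0.5, 0)


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------

def _specs():
    kin1 = {r: KineticParams(0.1, 0.13, 0.06, 0.006) for r in range(1, 6)}
    kin2 = {r: KineticParams(0.3, 0.38, 0.08, 0.09) for r in range(1, 6)}
    s1 = TracerSpec("fdg", 109.8, FDG_INPUT_PARAMS, kin1, "irreversible")
    s2 = TracerSpec("fmz", 20.4, FDG_INPUT_PARAMS, kin2, "reversible")
    return s1, s2


@pytest.fixture(scope="module")
def group():
    ph = generate_phantom(0, PhantomConfig(grid_size=32,
                                           roi_mean_sizes=(87, 89, 8, 8, 8),
                                           n_small_rois=1))
    prot = ScanProtocol(tuple(np.linspace(0.0, 60.0, 7)))
    s1, s2 = _specs()
    return make_group(ph, s1, s2, prot, GEOM, seed=4, target_counts=2e5)


def test_group_clean_dual_is_sum_of_singles(group):
    assert np.allclose(group.I_dual.values,
                       group.I1.values + group.I2.values)


def test_group_count_calibration(group):
    # noisy dual total fluctuates around the 2e5 calibration target
    assert group.S_dual.values.sum() == pytest.approx(2e5, rel=0.02)


def test_group_determinism():
    ph = generate_phantom(0, PhantomConfig(grid_size=32,
                                           roi_mean_sizes=(87, 89, 8, 8, 8),
                                           n_small_rois=1))
    prot = ScanProtocol(tuple(np.linspace(0.0, 60.0, 7)))
    s1, s2 = _specs()
    a = make_group(ph, s1, s2, prot, GEOM, seed=4, target_counts=2e5)
    b = make_group(ph, s1, s2, prot, GEOM, seed=4, target_counts=2e5)
    assert np.array_equal(a.S_dual.values, b.S_dual.values)
    assert np.array_equal(a.S1.values, b.S1.values)


def test_sum_noisy_singles_mode():
    ph = generate_phantom(1, PhantomConfig(grid_size=32,
                                           roi_mean_sizes=(87, 89, 8, 8, 8),
                                           n_small_rois=1))
    prot = ScanProtocol(tuple(np.linspace(0.0, 60.0, 5)))
    s1, s2 = _specs()
    g = make_group(ph, s1, s2, prot, GEOM, seed=9, target_counts=1e5,
                   sum_noisy_singles=True)
    assert np.array_equal(g.S_dual.values, g.S1.values + g.S2.values)


def test_default_study_grid_enumerates_880_groups():
    assert len(plan_dataset(22, 40)) == 880
    assert len(set(plan_dataset(22, 40))) == 880


def test_scale_group_normalisation_and_inverse(group):
    scaled = scale_group(group)
    assert scaled.S_dual.values.max() == pytest.approx(3.0, rel=1e-12)
    # image scale uses the sinogram max: ratio of scales is exactly 50
    assert scaled.sino_scale / scaled.img_scale == pytest.approx(50.0)
    back = unscale_group(scaled)
    assert np.allclose(back.S_dual.values, group.S_dual.values, rtol=1e-12)
    assert np.allclose(back.I1.values, group.I1.values, rtol=1e-12)


def test_scale_group_rejects_empty_sinogram():
    empty = SampleGroup(
        S_dual=DynamicSinogram(np.zeros((4, 5, 1)), PROT),
        S1=DynamicSinogram(np.zeros((4, 5, 1)), PROT),
        S2=DynamicSinogram(np.zeros((4, 5, 1)), PROT),
        I_dual=DynamicImage(np.zeros((4, 4, 1)), PROT),
        I1=DynamicImage(np.zeros((4, 4, 1)), PROT),
        I2=DynamicImage(np.zeros((4, 4, 1)), PROT),
        param_set_id=0, slice_id=0)
    with pytest.raises(ValueError, match="all-zero"):
        scale_group(empty)
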