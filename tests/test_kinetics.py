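"""Kinetics: input function, compartment solver, frame sampling, decay."""

import numpy as np
import pytest

from dualpet.kinetics import (FDG_INPUT_PARAMS, DynamicImage,
                              InputFunctionParams, KineticParams, ScanProtocol,
                              TracerSpec, apply_decay, build_activity_image,
                              dual_sum, frame_average, input_function,
                              randomize_params, solve_2tcm)
from dualpet.phantoms import generate_phantom, PhantomConfig

from conftest import FDG_LIKE


PROTOCOL = ScanProtocol.default()


# ---------------------------------------------------------------------------
# input function
# ---------------------------------------------------------------------------

def test_input_function_zero_at_origin_and_decays():
    assert input_function(0.0, FDG_INPUT_PARAMS) == 0.0
    assert input_function(1e4, FDG_INPUT_PARAMS) < 1e-10


def test_input_function_matches_term_by_term_oracle():
    p = FDG_INPUT_PARAMS
    t = 1.0
    expected = ((p.A1 * t - p.A2 - p.A3) * np.exp(p.lam1 * t)
                + p.A2 * np.exp(p.lam2 * t) + p.A3 * np.exp(p.lam3 * t))
    assert input_function(t, p) == pytest.approx(expected, rel=1e-14)


def test_input_function_negative_time_raises():
    with pytest.raises(ValueError):
        input_function(-0.1, FDG_INPUT_PARAMS)


def test_input_function_requires_negative_exponents():
    with pytest.raises(ValueError):
        InputFunctionParams(A1=1, A2=1, A3=1, lam1=0.1, lam2=-1, lam3=-1)


# ---------------------------------------------------------------------------
# compartment solver
# ---------------------------------------------------------------------------

def test_solve_2tcm_matches_rk4_oracle(rk4_reference):
    """Closed-form solution within 0.1% of the fine-step RK4 integration."""
    t = np.linspace(0.0, 60.0, 121)
    state = solve_2tcm(FDG_INPUT_PARAMS, rk4_reference["params"], t)
    idx = np.round(t / rk4_reference["dt"]).astype(int)
    ref = rk4_reference["c"][idx]
    ref_ct = ref.sum(axis=1)
    mask = ref_ct > 1e-9 * ref_ct.max()
    rel = np.abs(state.CT[mask] - ref_ct[mask]) / ref_ct[mask]
    assert rel.max() < 1e-3
    # per-compartment agreement too
    assert np.abs(state.C1[mask] - ref[mask, 0]).max() < 1e-3 * ref[:, 0].max()


def test_solve_2tcm_no_influx_is_zero():
    t = np.linspace(0, 60, 61)
    state = solve_2tcm(FDG_INPUT_PARAMS, KineticParams(K1=0, k2=0.1, k3=0.1), t)
    assert np.all(state.CT == 0)


def test_one_tissue_closed_form():
    """k3=k4=0 reduces to C1 = K1 * exp(-k2 t) convolved with Cp."""
    K1, k2 = 0.1, 0.3
    t = np.linspace(0, 40, 81)
    state = solve_2tcm(FDG_INPUT_PARAMS, KineticParams(K1=K1, k2=k2, k3=0), t)
    tf = np.arange(0, 40.0005, 0.0005)
    cp = input_function(tf, FDG_INPUT_PARAMS)
    for tc in (5.0, 20.0, 40.0):
        m = tf <= tc
        expected = K1 * np.trapezoid(np.exp(-k2 * (tc - tf[m])) * cp[m], tf[m])
        got = state.ct_fn(np.array([tc]))[0]
        assert got == pytest.approx(expected, rel=1e-5)
    assert np.all(state.C2 == pytest.approx(0.0, abs=1e-12))


def test_solve_2tcm_nonnegative_output():
    t = np.linspace(0, 60, 200)
    for k in (FDG_LIKE, KineticParams(0.3, 0.4, 0.08, 0.09),
              KineticParams(0.05, 0.01, 0.0, 0.0)):
        state = solve_2tcm(FDG_INPUT_PARAMS, k, t)
        assert state.C1.min() >= -1e-12
        assert state.C2.min() >= -1e-12


def test_negative_rate_constants_rejected():
    with pytest.raises(ValueError):
        KineticParams(K1=-0.1, k2=0.1, k3=0.1)


# ---------------------------------------------------------------------------
# frame averaging and decay
# ---------------------------------------------------------------------------

def test_frame_average_constant_and_linear():
    class _Const:
        t = np.array([0.0, 60.0])
        ct_fn = staticmethod(lambda t: np.full_like(np.asarray(t, float), 3.7))

    assert frame_average(_Const, PROTOCOL) == pytest.approx(3.7)

    class _Linear:
        t = np.array([0.0, 60.0])
        ct_fn = staticmethod(lambda t: 2.0 * np.asarray(t, float))

    ramp = frame_average(_Linear, ScanProtocol((0.0, 1.0)))
    assert ramp[0] == pytest.approx(1.0, rel=1e-12)  # mean of 2t on [0,1]


def test_frame_average_matches_trapezoid_oracle(rk4_reference):
    t = np.linspace(0, 60, 2)
    state = solve_2tcm(FDG_INPUT_PARAMS, FDG_LIKE, t)
    got = frame_average(state, PROTOCOL)
    edges = PROTOCOL.edges
    for i in [0, 5, 12, 25]:
        tf = np.arange(edges[i], edges[i + 1] + 1e-12, 0.001)
        oracle = np.trapezoid(state.ct_fn(tf), tf) / (edges[i + 1] - edges[i])
        assert got[i] == pytest.approx(oracle, rel=5e-4)


def test_frame_average_beyond_span_raises():
    t = np.linspace(0, 30, 31)
    state = solve_2tcm(FDG_INPUT_PARAMS, FDG_LIKE, t)
    with pytest.raises(ValueError, match="beyond"):
        frame_average(state, PROTOCOL)  # 60-min protocol vs 30-min solution


def test_decay_factor_half_life_and_limits():
    prot = ScanProtocol((0.0, 219.6))  # midpoint exactly at T=109.8
    assert apply_decay(np.ones(1), prot, 109.8)[0] == pytest.approx(0.5)
    assert apply_decay(np.ones(26), PROTOCOL, 1e12) == pytest.approx(1.0)
    fac = apply_decay(np.ones(26), PROTOCOL, 109.8)
    assert fac[-1] == pytest.approx(2 ** (-57.5 / 109.8))
    with pytest.raises(ValueError):
        apply_decay(np.ones(26), PROTOCOL, 0.0)


# ---------------------------------------------------------------------------
# randomisation
# ---------------------------------------------------------------------------

def _fdg_spec():
    return TracerSpec(name="fdg", half_life=109.8,
                      input_fn=FDG_INPUT_PARAMS,
                      roi_kinetics={1: FDG_LIKE}, kinetic_type="irreversible")


def test_randomize_cv_zero_is_identity():
    spec = _fdg_spec()
    out = randomize_params(spec, cv=0.0, seed=0)
    assert out.input_fn == spec.input_fn
    assert out.roi_kinetics == spec.roi_kinetics


def test_randomize_sample_cv_matches_target():
    spec = _fdg_spec()
    draws = np.array([randomize_params(spec, 0.1, s).roi_kinetics[1].K1
                      for s in range(10000)])
    assert draws.std() / draws.mean() == pytest.approx(0.1, abs=0.01)
    assert draws.min() > 0


def test_randomize_deterministic_and_sign_preserving():
    spec = _fdg_spec()
    a = randomize_params(spec, 0.1, 5)
    b = randomize_params(spec, 0.1, 5)
    assert a.input_fn == b.input_fn and a.roi_kinetics == b.roi_kinetics
    assert a.input_fn.lam1 < 0 and a.input_fn.lam2 < 0 and a.input_fn.lam3 < 0


# ---------------------------------------------------------------------------
# activity images
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_phantom():
    return generate_phantom(
        2, PhantomConfig(grid_size=32, roi_mean_sizes=(87, 89, 8, 8, 8),
                         n_small_rois=1))


def _spec(name="fdg", half_life=109.8, rois=(1, 2, 3)):
    kin = {1: FDG_LIKE, 2: KineticParams(0.054, 0.109, 0.045, 0.0058),
           3: KineticParams(0.134, 0.145, 0.078, 0.008)}
    return TracerSpec(name=name, half_life=half_life,
                      input_fn=FDG_INPUT_PARAMS,
                      roi_kinetics={r: kin[r] for r in rois},
                      kinetic_type="irreversible")


def test_build_activity_image_pixels_carry_roi_tacs(small_phantom):
    prot = ScanProtocol(tuple(np.linspace(0, 60, 14)))
    img = build_activity_image(small_phantom, _spec(), prot)
    assert img.values.shape == (32, 32, 13)
    assert np.all(img.values[small_phantom.label_map == 0] == 0)
    # each ROI is a single shared TAC matching the composed pipeline
    state = solve_2tcm(FDG_INPUT_PARAMS, FDG_LIKE, np.linspace(0, 60, 2))
    expected = apply_decay(frame_average(state, prot), prot, 109.8)
    roi_pixels = img.values[small_phantom.label_map == 1]
    assert np.allclose(roi_pixels, expected[None, :])


def test_missing_roi_kinetics_raises(small_phantom):
    prot = ScanProtocol(tuple(np.linspace(0, 60, 5)))
    with pytest.raises(KeyError, match="lacks kinetics"):
        build_activity_image(small_phantom, _spec(rois=(1, 2)), prot)


def test_half_life_only_changes_decay_ratio(small_phantom):
    """Identical kinetics, different half-lives: frame ratio = decay ratio."""
    prot = ScanProtocol(tuple(np.linspace(0, 60, 7)))
    a = build_activity_image(small_phantom, _spec(half_life=109.8), prot)
    b = build_activity_image(small_phantom, _spec(half_life=20.4), prot)
    mask = small_phantom.label_map > 0
    ratio = b.values[mask] / a.values[mask]
    expected = 2.0 ** (-prot.midpoints / 20.4) / 2.0 ** (-prot.midpoints / 109.8)
    assert np.allclose(ratio, expected[None, :], rtol=1e-12)


def test_dual_sum_properties(small_phantom):
    prot = ScanProtocol(tuple(np.linspace(0, 60, 5)))
    i1 = build_activity_image(small_phantom, _spec(), prot)
    i2 = build_activity_image(small_phantom, _spec(half_life=20.4), prot)
    zero = DynamicImage(np.zeros_like(i1.values), prot)
    assert np.array_equal(dual_sum(i1, zero).values, i1.values)
    assert np.array_equal(dual_sum(i1, i2).values, dual_sum(i2, i1).values)
    assert np.array_equal(dual_sum(i1, i2).values, i1.values + i2.values)
    with pytest.raises(ValueError):
        dual_sum(i1, DynamicImage(np.zeros((16, 16, 4)),
                                  ScanProtocol(tuple(np.linspace(0, 60, 5)))))


def test_default_protocol_structure():
    assert PROTOCOL.n_frames == 26
    assert PROTOCOL.total_time == 60.0
    d = PROTOCOL.durations
    assert np.allclose(d[:8], 0.25) and np.allclose(d[8:16], 1.0)
    assert np.allclose(d[16:], 5.0)
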