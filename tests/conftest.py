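"""Shared fixtures: oracles and the (expensive) reduced-scale training run."""

from __future__ import annotations

import numpy as np
import pytest

from dualpet.kinetics import (FDG_INPUT_PARAMS, KineticParams, ScanProtocol,
                              input_function)


FDG_LIKE = KineticParams(K1=0.102, k2=0.130, k3=0.062, k4=0.0068)


def rk4_2tcm(p, k, t_max: float, dt: float) -> np.ndarray:
    """Independent fine-step RK4 integration of the compartment system.

    Returns (n_steps + 1, 2) array of (C1, C2) on the uniform grid."""
    n = int(round(t_max / dt))
    M = np.array([[-(k.k2 + k.k3), k.k4], [k.k3, -k.k4]])

    def f(t, c):
        return M @ c + np.array([k.K1 * input_function(t, p), 0.0])

    c = np.zeros(2)
    out = np.empty((n + 1, 2))
    out[0] = c
    t = 0.0
    for i in range(n):
        k1 = f(t, c)
        k2 = f(t + dt / 2, c + dt / 2 * k1)
        k3 = f(t + dt / 2, c + dt / 2 * k2)
        k4 = f(t + dt, c + dt * k3)
        c = c + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        out[i + 1] = c
    return out


@pytest.fixture(scope="session")
def rk4_reference():
    """RK4 dt=0.001 reference for FDG-like kinetics over the 60-min scan."""
    dt = 0.001
    ref = rk4_2tcm(FDG_INPUT_PARAMS, FDG_LIKE, 60.0, dt)
    return {"params": FDG_LIKE, "dt": dt, "c": ref}


def numerical_grad(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = fn()
        x[idx] = orig - eps
        fm = fn()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


@pytest.fixture(scope="session")
def reduced_run():
    """One reduced-scale end-to-end run: simulate, split, train fbpnet_sep.

    Shared by the learning smoke tests and the acceptance suite; everything
    downstream (predictions, dose sweep) derives from this single run.
    """
    from dualpet.models import assemble_variant
    from dualpet.training import SplitSpec, TrainConfig, run_training, split_dataset
    from dualpet.workflow import PRESETS, predict_groups, scale_group, simulate_dataset

    preset = PRESETS["reduced"]
    raw = simulate_dataset(preset, "fdg", "fmz", seed=1)
    train_raw, test_raw = split_dataset(
        raw, SplitSpec(ratio=preset.split_ratio, seed=1))
    train = [scale_group(g) for g in train_raw]
    test = [scale_group(g) for g in test_raw]
    model = assemble_variant(
        "fbpnet_sep", geom=preset.geom, n_frames=preset.protocol.n_frames,
        protocol=preset.protocol, widths=preset.widths, seed=1)
    result = run_training(model, train, test,
                          TrainConfig(seed=1, **preset.train_config_kwargs))
    preds = predict_groups(result.model, test)
    return {
        "preset": preset,
        "raw": raw,
        "train": train,
        "test": test,
        "test_raw": test_raw,
        "result": result,
        "preds": preds,
    }
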