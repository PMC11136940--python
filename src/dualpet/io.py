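"""Portable array I/O: phantoms, dynamic data and model weights as ``.npz``."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .acquisition import DynamicSinogram, SampleGroup
from .kinetics import DynamicImage, ScanProtocol
from .phantoms import PhantomSlice

__all__ = [
    "save_phantoms", "load_phantoms",
    "save_group", "load_group",
    "save_weights", "load_weights",
]


def save_phantoms(path: str | Path, slices: list[PhantomSlice]) -> None:
    arrays = {f"slice_{s.slice_id:04d}": s.label_map for s in slices}
    np.savez_compressed(path, **arrays)


def load_phantoms(path: str | Path) -> list[PhantomSlice]:
    with np.load(path) as data:
        return [PhantomSlice(label_map=data[k], slice_id=int(k.split("_")[1]))
                for k in sorted(data.files)]


def save_group(path: str | Path, g: SampleGroup) -> None:
    np.savez_compressed(
        path,
        S_dual=g.S_dual.values, S1=g.S1.values, S2=g.S2.values,
        I_dual=g.I_dual.values, I1=g.I1.values, I2=g.I2.values,
        frame_edges=np.asarray(g.S_dual.protocol.frame_edges),
        meta=np.array([g.param_set_id, g.slice_id], dtype=np.int64),
        scales=np.array([g.sino_scale, g.img_scale]),
        half_lives=np.array([g.half_life1, g.half_life2]),
        tracers=np.array([g.tracer1, g.tracer2]),
    )


def load_group(path: str | Path) -> SampleGroup:
    with np.load(path) as d:
        protocol = ScanProtocol(tuple(float(e) for e in d["frame_edges"]))
        return SampleGroup(
            S_dual=DynamicSinogram(d["S_dual"], protocol, noisy=True),
            S1=DynamicSinogram(d["S1"], protocol, noisy=True),
            S2=DynamicSinogram(d["S2"], protocol, noisy=True),
            I_dual=DynamicImage(d["I_dual"], protocol),
            I1=DynamicImage(d["I1"], protocol),
            I2=DynamicImage(d["I2"], protocol),
            param_set_id=int(d["meta"][0]), slice_id=int(d["meta"][1]),
            sino_scale=float(d["scales"][0]), img_scale=float(d["scales"][1]),
            tracer1=str(d["tracers"][0]), tracer2=str(d["tracers"][1]),
            half_life1=float(d["half_lives"][0]),
            half_life2=float(d["half_lives"][1]),
        )


def save_weights(path: str | Path, model) -> None:
    np.savez_compressed(path, **model.state_dict())


def load_weights(path: str | Path, model) -> None:
    with np.load(path) as d:
        model.load_state_dict({k: d[k] for k in d.files})
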