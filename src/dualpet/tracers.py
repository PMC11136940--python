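"""Loading tracer specifications from the packaged (or a user) YAML library."""

from __future__ import annotations

from importlib import resources

import yaml

from .kinetics import InputFunctionParams, KineticParams, TracerSpec

__all__ = ["load_tracer_library", "load_tracer"]


def _parse_spec(entry: dict) -> TracerSpec:
    return TracerSpec(
        name=entry["name"],
        half_life=float(entry["half_life"]),
        kinetic_type=entry["kinetic_type"],
        input_fn=InputFunctionParams(**{k: float(v)
                                        for k, v in entry["input_fn"].items()}),
        roi_kinetics={int(r): KineticParams(**{k: float(v) for k, v in kp.items()})
                      for r, kp in entry["roi_kinetics"].items()},
    )


def load_tracer_library(path: str | None = None) -> dict[str, TracerSpec]:
    """Load all tracer specs; ``path`` overrides the packaged defaults."""
    if path is None:
        text = (resources.files("dualpet") / "data" / "tracers.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {key: _parse_spec(entry) for key, entry in raw["tracers"].items()}


def load_tracer(key: str, path: str | None = None) -> TracerSpec:
    lib = load_tracer_library(path)
    if key not in lib:
        raise KeyError(f"unknown tracer {key!r}; available: {sorted(lib)}")
    return lib[key]
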