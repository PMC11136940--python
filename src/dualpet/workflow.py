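"""End-to-end experiment drivers: simulate -> train -> separate -> evaluate.

Scale presets bundle every module's configuration.  ``full`` is the
reference scale (128 x 128 phantoms, 26 frames, 22 parameter sets x 40 phantoms, 300 +
100 + 100 epochs) and is GPU-month territory on this CPU stack; ``reduced``
(32 x 32, 13 frames, 5 x 10 groups, 10 + 10 + 20 epochs) exercises every
pipeline property on a desktop CPU in minutes and is what the test suite
runs; ``tiny`` is a seconds-scale smoke preset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn.tensor import Tensor
from .acquisition import (DynamicSinogram, GeomConfig, SampleGroup, make_group,
                          scale_group, thin_counts)
from .evaluation import (MacroParam, image_metrics, logan_vt,
                         macro_relative_error, patlak_ki, roi_tac,
                         tac_bias_std)
from .kinetics import (DynamicImage, ScanProtocol, input_function,
                       randomize_params)
from .models import assemble_variant, count_parameters, decay_correct_image
from .phantoms import PhantomConfig, generate_phantom_set
from .recon_classic import mlem, osem
from .tracers import load_tracer_library
from .training import (LOSS_PRESETS, SplitSpec, TrainConfig, augment_swap,
                       composite_loss, run_training, split_dataset)

__all__ = [
    "ScalePreset",
    "PRESETS",
    "ExperimentConfig",
    "plan_dataset",
    "simulate_dataset",
    "predict_groups",
    "evaluate_groups",
    "dose_sweep",
    "run_experiment",
    "ablation_matrix",
]

DOSE_LEVELS = (1.0, 1 / 2, 1 / 3, 1 / 5)


@dataclass(frozen=True)
class ScalePreset:
    name: str
    grid: int
    n_bins: int
    n_angles: int
    frame_durations: tuple[float, ...]
    n_param_sets: int
    n_phantoms: int
    widths: dict
    epochs: tuple[int, int, int]
    batches: tuple[int, int]
    target_counts: float
    split_ratio: int
    roi_mean_sizes: tuple[int, ...]
    n_small_rois: int = 3
    lr: float = 1e-4  # desk-scale presets raise this: far fewer Adam steps

    @property
    def protocol(self) -> ScanProtocol:
        return ScanProtocol(tuple(np.concatenate(
            [[0.0], np.cumsum(self.frame_durations)])))

    @property
    def geom(self) -> GeomConfig:
        return GeomConfig(image_size=self.grid, n_bins=self.n_bins,
                          n_angles=self.n_angles)

    @property
    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(grid_size=self.grid,
                             roi_mean_sizes=self.roi_mean_sizes,
                             n_small_rois=self.n_small_rois)

    @property
    def train_config_kwargs(self) -> dict:
        return dict(pretrain_fbp_epochs=self.epochs[0],
                    pretrain_sep_epochs=self.epochs[1],
                    joint_epochs=self.epochs[2],
                    pretrain_batch=self.batches[0],
                    joint_batch=self.batches[1],
                    lr=self.lr)


PRESETS: dict[str, ScalePreset] = {
    "full": ScalePreset(
        name="full", grid=128, n_bins=128, n_angles=160,
        frame_durations=tuple([0.25] * 8 + [1.0] * 8 + [5.0] * 10),
        n_param_sets=22, n_phantoms=40,
        widths=dict(conv1=32, conv2=25, inception=25, denoiser=183),
        epochs=(300, 100, 100), batches=(4, 16), target_counts=1e7,
        split_ratio=10, roi_mean_sizes=(1393, 1427, 78, 110, 130)),
    "reduced": ScalePreset(
        name="reduced", grid=32, n_bins=32, n_angles=60,
        frame_durations=tuple([0.5] * 4 + [2.0] * 4 + [10.0] * 5),
        n_param_sets=5, n_phantoms=10,
        widths=dict(conv1=12, conv2=8, inception=8, denoiser=16),
        epochs=(10, 10, 20), batches=(4, 16), target_counts=3e5,
        split_ratio=4, roi_mean_sizes=(87, 89, 8, 8, 8), n_small_rois=1,
        lr=1e-3),
    "tiny": ScalePreset(
        name="tiny", grid=32, n_bins=32, n_angles=60,
        frame_durations=tuple([1.0] * 3 + [19.0] * 3),
        n_param_sets=3, n_phantoms=2,
        widths=dict(conv1=6, conv2=4, inception=4, denoiser=6),
        epochs=(2, 2, 3), batches=(2, 4), target_counts=1e5,
        split_ratio=2, roi_mean_sizes=(87, 89, 8, 8, 8), n_small_rois=1,
        lr=1e-3),
}


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: int                      # 1..4
    preset: str = "reduced"
    seed: int = 0
    tracer_pairs: tuple[tuple[str, str], ...] = (("fdg", "fmz"),)
    variants: tuple[str, ...] = ("fbpnet_sep",)
    dose_levels: tuple[float, ...] = DOSE_LEVELS

    def __post_init__(self):
        if self.experiment not in (1, 2, 3, 4):
            raise ValueError("experiment id must be 1..4")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

def plan_dataset(n_param_sets: int, n_phantoms: int) -> list[tuple[int, int]]:
    """Enumerate the (parameter set, phantom slice) group grid."""
    return [(p, s) for p in range(n_param_sets) for s in range(n_phantoms)]


def simulate_dataset(preset: ScalePreset, tracer1: str, tracer2: str,
                     seed: int, tracer_path: str | None = None,
                     cv: float = 0.10) -> list[SampleGroup]:
    """Simulate all (parameter set x phantom) groups of one tracer pair.

    Each parameter set is an independent 10%-CV Gaussian randomisation of the
    tracer library values, shared across all phantom slices; groups are
    returned in raw (unscaled) units.
    """
    lib = load_tracer_library(tracer_path)
    base1, base2 = lib[tracer1], lib[tracer2]
    root = np.random.SeedSequence(seed)
    ph_seed, params_seed, noise_seed = root.spawn(3)
    phantoms = generate_phantom_set(
        preset.n_phantoms, int(ph_seed.generate_state(1)[0] % 2**31),
        preset.phantom_config)
    param_rngs = [np.random.default_rng(s) for s in params_seed.spawn(preset.n_param_sets)]
    noise_rngs = [np.random.default_rng(s)
                  for s in noise_seed.spawn(preset.n_param_sets * preset.n_phantoms)]
    protocol = preset.protocol
    geom = preset.geom
    groups = []
    for p_id, prng in enumerate(param_rngs):
        spec1 = randomize_params(base1, cv, prng)
        spec2 = randomize_params(base2, cv, prng)
        for s_id, phantom in enumerate(phantoms):
            g = make_group(phantom, spec1, spec2, protocol, geom,
                           seed=noise_rngs[p_id * preset.n_phantoms + s_id],
                           target_counts=preset.target_counts,
                           param_set_id=p_id)
            groups.append(g)
    return groups


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def _to_nchw(sino_or_img) -> np.ndarray:
    return np.moveaxis(sino_or_img.values, 2, 0)[None]


def predict_groups(model, groups: list[SampleGroup]) -> list[dict]:
    """Run a trained model on scaled groups; returns per-group prediction
    dicts with DynamicImage values in the groups' scaled units."""
    model.eval()
    out = []
    for g in groups:
        preds = model(Tensor(_to_nchw(g.S_dual)))
        rec = {}
        for key in ("I1_hat", "I2_hat", "I_dual_hat"):
            if key in preds:
                rec[key] = DynamicImage(
                    np.moveaxis(preds[key].data[0], 0, 2), g.S_dual.protocol)
        out.append(rec)
    return out


def evaluate_groups(preds: list[dict], groups: list[SampleGroup]) -> pd.DataFrame:
    """Tidy per-group image-quality metrics for both tracers."""
    rows = []
    for pr, g in zip(preds, groups):
        for tracer_idx, (key, label) in enumerate(
                [("I1_hat", g.I1), ("I2_hat", g.I2)], start=1):
            mse, ssim, psnr = image_metrics(pr[key], label)
            rows.append(dict(param_set=g.param_set_id, slice=g.slice_id,
                             tracer=getattr(g, f"tracer{tracer_idx}"),
                             mse=mse, ssim=ssim, psnr=psnr))
    return pd.DataFrame(rows)


def dose_sweep(model, raw_test_groups: list[SampleGroup],
               dose_levels=DOSE_LEVELS, seed: int = 0) -> pd.DataFrame:
    """Evaluate a frozen model on count-thinned test data.

    Thinning acts on the raw (integer-count) dual sinograms; every thinned
    group is re-normalised by its own dual-sinogram maximum before inference,
    exactly as the standard-dose data were.
    """
    frames = []
    rng = np.random.default_rng(seed)
    for dose in dose_levels:
        scaled = []
        for g in raw_test_groups:
            thinned = thin_counts(g.S_dual, dose, rng) if dose < 1 else g.S_dual
            g_d = SampleGroup(S_dual=thinned, S1=g.S1, S2=g.S2, I_dual=g.I_dual,
                              I1=g.I1, I2=g.I2, param_set_id=g.param_set_id,
                              slice_id=g.slice_id, tracer1=g.tracer1,
                              tracer2=g.tracer2, half_life1=g.half_life1,
                              half_life2=g.half_life2)
            scaled.append(scale_group(g_d))
        preds = predict_groups(model, scaled)
        df = evaluate_groups(preds, scaled)
        df["dose"] = dose
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def macro_parameter_report(preds: list[dict], groups: list[SampleGroup],
                           phantoms: dict[int, object],
                           specs: dict[str, object]) -> pd.DataFrame:
    """Patlak Ki / Logan VT from predicted vs label ROI TACs (last 10 frames,
    or all frames when the protocol is shorter)."""
    rows = []
    for pr, g in zip(preds, groups):
        phantom = phantoms[g.slice_id]
        prot = g.I1.protocol
        window = min(10, prot.n_frames)
        for idx, (key, label, tname, half_life) in enumerate([
                ("I1_hat", g.I1, g.tracer1, g.half_life1),
                ("I2_hat", g.I2, g.tracer2, g.half_life2)], start=1):
            spec = specs[tname]
            cp = input_function(prot.midpoints, spec.input_fn)
            kind = "Ki" if spec.kinetic_type == "irreversible" else "VT"
            fit = patlak_ki if kind == "Ki" else logan_vt
            for roi in phantom.rois:
                tac_p = roi_tac(decay_correct_image(pr[key], half_life),
                                phantom, roi)
                tac_l = roi_tac(decay_correct_image(label, half_life),
                                phantom, roi)
                try:
                    v_p = fit(tac_p, cp, prot.midpoints, window)
                    v_l = fit(tac_l, cp, prot.midpoints, window)
                    err = macro_relative_error(
                        MacroParam(roi, kind, v_p, window),
                        MacroParam(roi, kind, v_l, window))
                except ValueError:
                    continue
                rows.append(dict(param_set=g.param_set_id, slice=g.slice_id,
                                 tracer=tname, roi=roi, kind=kind,
                                 pred=v_p, label=v_l, rel_err_pct=err))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _checksum(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _train_variant(variant: str, preset: ScalePreset, train, test, seed: int,
                   half_lives=None):
    model = assemble_variant(
        variant, geom=preset.geom, n_frames=preset.protocol.n_frames,
        protocol=preset.protocol, widths=preset.widths, seed=seed)
    if half_lives is not None and variant == "fbpnet_dc_sep":
        pass  # half-lives fixed at assembly
    cfg = TrainConfig(seed=seed, **preset.train_config_kwargs)
    return run_training(model, train, test, cfg)


def _prepare(groups):
    return [scale_group(g) for g in groups]


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Chain simulate -> train -> separate -> evaluate for one experiment.

    Returns a report dict (metrics tables as DataFrames plus a manifest);
    when ``out_dir`` is given, writes metrics.csv and manifest.json there.
    """
    preset = PRESETS[cfg.preset]
    t1, t2 = cfg.tracer_pairs[0]
    raw = simulate_dataset(preset, t1, t2, cfg.seed)
    assert len(raw) == len(plan_dataset(preset.n_param_sets, preset.n_phantoms))
    train_raw, test_raw = split_dataset(
        raw, SplitSpec(ratio=preset.split_ratio, seed=cfg.seed))
    train, test = _prepare(train_raw), _prepare(test_raw)

    report: dict = {"experiment": cfg.experiment, "preset": cfg.preset,
                    "seed": cfg.seed, "n_groups": len(raw),
                    "n_train": len(train), "n_test": len(test)}
    manifest = {
        "config": asdict(cfg), "preset": asdict(preset),
        "data_checksum": _checksum([g.S_dual.values for g in raw]),
        "split": sorted({g.param_set_id for g in test_raw}),
    }

    if cfg.experiment == 1:
        metrics = []
        results = {}
        for variant in ("fbpnet_sep", "sep_fbpnet"):
            res = _train_variant(variant, preset, train, test, cfg.seed)
            df = evaluate_groups(predict_groups(res.model, test), test)
            df["model"] = variant
            metrics.append(df)
            results[variant] = res
        # MLEM baseline on the noisy single-tracer sinograms
        rows = []
        for g in test:
            for idx, (sino, label, tname) in enumerate(
                    [(g.S1, g.I1, g.tracer1), (g.S2, g.I2, g.tracer2)], 1):
                rec = mlem(sino, preset.geom, n_iter=50)
                mse, ssim, psnr = image_metrics(rec, label)
                rows.append(dict(param_set=g.param_set_id, slice=g.slice_id,
                                 tracer=tname, mse=mse, ssim=ssim, psnr=psnr,
                                 model="mlem"))
        metrics.append(pd.DataFrame(rows))
        report["metrics"] = pd.concat(metrics, ignore_index=True)
        report["results"] = results

    elif cfg.experiment == 2:
        report["metrics"], report["results"] = ablation_matrix_run(
            preset, train, test, cfg.seed)

    elif cfg.experiment == 3:
        res = _train_variant("fbpnet_sep", preset, train, test, cfg.seed)
        report["metrics"] = dose_sweep(res.model, test_raw,
                                       cfg.dose_levels, seed=cfg.seed + 1)
        report["results"] = {"fbpnet_sep": res}

    elif cfg.experiment == 4:
        lib = load_tracer_library()
        metrics, macro = [], []
        results = {}
        for pair in cfg.tracer_pairs:
            raw_p = (raw if pair == (t1, t2)
                     else simulate_dataset(preset, *pair, cfg.seed))
            tr_raw, te_raw = split_dataset(
                raw_p, SplitSpec(ratio=preset.split_ratio, seed=cfg.seed))
            tr, te = _prepare(tr_raw), _prepare(te_raw)
            # same phantom set the simulation used (same seed derivation)
            phantoms = {s.slice_id: s for s in generate_phantom_set(
                preset.n_phantoms,
                int(np.random.SeedSequence(cfg.seed).spawn(3)[0]
                    .generate_state(1)[0] % 2**31),
                preset.phantom_config)}
            hl = (lib[pair[0]].half_life, lib[pair[1]].half_life)
            for variant in ("fbpnet_sep", "fbpnet_dc_sep"):
                tr_v = augment_swap(tr) if variant == "fbpnet_dc_sep" else tr
                res = _train_variant(variant, preset, tr_v, te, cfg.seed,
                                     half_lives=hl)
                preds = predict_groups(res.model, te)
                df = evaluate_groups(preds, te)
                df["model"] = variant
                df["pair"] = "/".join(pair)
                metrics.append(df)
                mp = macro_parameter_report(preds, te, phantoms, lib)
                if len(mp):
                    mp["model"] = variant
                    mp["pair"] = "/".join(pair)
                    macro.append(mp)
                results[(variant, pair)] = res
        report["metrics"] = pd.concat(metrics, ignore_index=True)
        report["macro"] = (pd.concat(macro, ignore_index=True)
                           if macro else pd.DataFrame())
        report["results"] = results

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["metrics"].to_csv(out / "metrics.csv", index=False)
        if "macro" in report and len(report["macro"]):
            report["macro"].to_csv(out / "macro_parameters.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    report["manifest"] = manifest
    return report


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def build_ablations(preset: ScalePreset, seed: int = 0) -> dict[str, nn.Module]:
    """The four separation ablations (structure only, untrained)."""
    kw = dict(geom=preset.geom, n_frames=preset.protocol.n_frames,
              protocol=preset.protocol, widths=preset.widths, seed=seed)
    return {
        "conv": assemble_variant("fbpnet_sep", use_inception=False,
                                 use_attention=False, **kw),
        "conv+inc": assemble_variant("fbpnet_sep", use_inception=True,
                                     use_attention=False, **kw),
        "conv+ca": assemble_variant("fbpnet_sep", use_inception=False,
                                    use_attention=True, **kw),
        "conv+inc+ca": assemble_variant("fbpnet_sep", **kw),
    }


def _train_separation_only(sepnet, inputs: np.ndarray, l1: np.ndarray,
                           l2: np.ndarray, epochs: int, batch: int,
                           lr: float, beta: float, seed: int):
    from .nn import tensor as T
    rng = np.random.default_rng(seed)
    opt = nn.Adam(sepnet.parameters(), lr=lr)
    for _ in range(epochs):
        idx_all = rng.permutation(len(inputs))
        for i in range(0, len(inputs), batch):
            idx = idx_all[i:i + batch]
            opt.zero_grad()
            p1, p2 = sepnet(Tensor(inputs[idx]))
            loss = T.add(composite_loss(p1, Tensor(l1[idx]), beta),
                         composite_loss(p2, Tensor(l2[idx]), beta))
            T.backward(loss)
            opt.step()
    return sepnet


def ablation_matrix_run(preset: ScalePreset, train, test, seed: int):
    """Train and evaluate the separation ablations plus the OSEM front-end
    variant on bit-identical data."""
    metrics = []
    results = {}
    for name, model in build_ablations(preset, seed).items():
        cfg = TrainConfig(seed=seed, **preset.train_config_kwargs)
        res = run_training(model, train, test, cfg)
        df = evaluate_groups(predict_groups(res.model, test), test)
        df["model"] = f"fbpnet_sep({name})"
        metrics.append(df)
        results[name] = res

    # OSEM-Sep: frozen OSEM(6, 5) reconstruction front end, trained separation
    def osem_inputs(groups):
        return np.stack([
            np.moveaxis(osem(g.S_dual, preset.geom, 6, 5).values, 2, 0)
            for g in groups])

    sep = build_ablations(preset, seed)["conv+inc+ca"].sepnet
    w = LOSS_PRESETS["fbpnet_sep"]
    tr_in = osem_inputs(train)
    epochs = preset.epochs[1] + preset.epochs[2]
    _train_separation_only(
        sep, tr_in,
        np.stack([np.moveaxis(g.I1.values, 2, 0) for g in train]),
        np.stack([np.moveaxis(g.I2.values, 2, 0) for g in train]),
        epochs, preset.batches[0], 1e-4, w.beta_sep, seed)
    sep.eval()
    rows = []
    te_in = osem_inputs(test)
    for x, g in zip(te_in, test):
        p1, p2 = sep(Tensor(x[None]))
        for pred, label, tname in ((p1, g.I1, g.tracer1), (p2, g.I2, g.tracer2)):
            img = DynamicImage(np.moveaxis(pred.data[0], 0, 2), g.I1.protocol)
            mse, ssim, psnr = image_metrics(img, label)
            rows.append(dict(param_set=g.param_set_id, slice=g.slice_id,
                             tracer=tname, mse=mse, ssim=ssim, psnr=psnr,
                             model="osem_sep(conv+inc+ca)"))
    metrics.append(pd.DataFrame(rows))
    return pd.concat(metrics, ignore_index=True), results


def ablation_matrix(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Convenience wrapper: Experiment 2 with the given config."""
    return run_experiment(ExperimentConfig(
        experiment=2, preset=cfg.preset, seed=cfg.seed,
        tracer_pairs=cfg.tracer_pairs), out_dir)
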