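"""Losses, dataset splitting, augmentation, and the three-phase training
schedule (reconstruction pretrain, separation pretrain, joint fine-tune).

The per-output loss is a weighted mix of MSE and structural dissimilarity,

    L(x_hat, x) = beta * MSE(x_hat, x) + (1 - beta) * [1 - SSIM(x_hat, x)],

and the model loss combines a reconstruction term and a separation term,
L_total = lambda_FBP * L_FBP + lambda_Sep * L_Sep.  For the image-domain
variants L_FBP compares the intermediate dual-tracer reconstruction and
L_Sep the two separated images; for the sinogram-domain variant L_Sep
compares the separated sinograms and L_FBP the reconstructed images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor
from .acquisition import SampleGroup

__all__ = [
    "LossWeights",
    "TrainConfig",
    "SplitSpec",
    "TrainResult",
    "composite_loss",
    "total_loss",
    "split_dataset",
    "augment_swap",
    "run_training",
    "LOSS_PRESETS",
]


@dataclass(frozen=True)
class LossWeights:
    beta_fbp: float = 0.5
    beta_sep: float = 0.95
    lambda_fbp: float = 1.0
    lambda_sep: float = 10.0

    def __post_init__(self):
        if not (0 <= self.beta_fbp <= 1 and 0 <= self.beta_sep <= 1):
            raise ValueError("beta coefficients must lie in [0, 1]")
        if self.lambda_fbp < 0 or self.lambda_sep < 0:
            raise ValueError("lambda weights must be non-negative")


#: default loss coefficients per variant
LOSS_PRESETS = {
    "fbpnet_sep": LossWeights(beta_fbp=0.5, beta_sep=0.95,
                              lambda_fbp=1.0, lambda_sep=10.0),
    "fbpnet_dc_sep": LossWeights(beta_fbp=0.5, beta_sep=0.95,
                                 lambda_fbp=1.0, lambda_sep=10.0),
    "sep_fbpnet": LossWeights(beta_fbp=0.5, beta_sep=0.99,
                              lambda_fbp=1.0, lambda_sep=1.0),
}


@dataclass(frozen=True)
class TrainConfig:
    pretrain_fbp_epochs: int = 300
    pretrain_sep_epochs: int = 100
    joint_epochs: int = 100
    pretrain_batch: int = 4
    joint_batch: int = 16
    lr: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if min(self.pretrain_fbp_epochs, self.pretrain_sep_epochs,
               self.joint_epochs, self.pretrain_batch, self.joint_batch) < 1:
            raise ValueError("epochs and batch sizes must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split by parameter set: all phantom slices appear on both
    sides, physiological parameter sets never do."""

    ratio: int = 10     # train:test ratio in parameter sets
    seed: int = 0


@dataclass
class TrainResult:
    model: nn.Module
    variant: str
    history: dict[str, list[float]] = field(default_factory=dict)
    val_sep_before_joint: float = float("nan")
    val_sep_after_joint: float = float("nan")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def composite_loss(x_hat: Tensor, x: Tensor, beta: float,
                   data_range: float | None = None) -> Tensor:
    """beta * MSE + (1 - beta) * (1 - SSIM); SSIM data range from the label."""
    if x_hat.shape != x.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {x.shape}")
    terms = []
    if beta > 0:
        terms.append(T.mul(Tensor(beta), F.mse(x_hat, x)))
    if beta < 1:
        if data_range is None:
            data_range = float(x.data.max() - x.data.min())
        if data_range == 0:
            data_range = 1.0
        dssim = T.sub(Tensor(1.0), F.ssim(x_hat, x, data_range))
        terms.append(T.mul(Tensor(1.0 - beta), dssim))
    out = terms[0]
    for t in terms[1:]:
        out = T.add(out, t)
    return out


def sep_loss(variant: str, preds: dict, labels: dict, w: LossWeights) -> Tensor:
    """The separation term of the total loss for a variant."""
    if variant == "sep_fbpnet":
        if "S1_hat" not in preds or "S2_hat" not in preds:
            raise KeyError("sinogram-domain variant needs S1_hat/S2_hat")
        return T.add(composite_loss(preds["S1_hat"], labels["S1"], w.beta_sep),
                     composite_loss(preds["S2_hat"], labels["S2"], w.beta_sep))
    return T.add(composite_loss(preds["I1_hat"], labels["I1"], w.beta_sep),
                 composite_loss(preds["I2_hat"], labels["I2"], w.beta_sep))


def fbp_loss(variant: str, preds: dict, labels: dict, w: LossWeights) -> Tensor:
    """The reconstruction term of the total loss for a variant."""
    if variant == "sep_fbpnet":
        return T.add(composite_loss(preds["I1_hat"], labels["I1"], w.beta_fbp),
                     composite_loss(preds["I2_hat"], labels["I2"], w.beta_fbp))
    if "I_dual_hat" not in preds:
        raise KeyError("image-domain variant needs the I_dual_hat intermediate")
    return composite_loss(preds["I_dual_hat"], labels["I_dual"], w.beta_fbp)


def total_loss(variant: str, preds: dict, labels: dict,
               w: LossWeights | None = None) -> Tensor:
    if w is None:
        w = LOSS_PRESETS[variant]
    lf = fbp_loss(variant, preds, labels, w)
    ls = sep_loss(variant, preds, labels, w)
    return T.add(T.mul(Tensor(w.lambda_fbp), lf),
                 T.mul(Tensor(w.lambda_sep), ls))


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_dataset(groups: list[SampleGroup],
                  spec: SplitSpec = SplitSpec()) -> tuple[list[SampleGroup],
                                                          list[SampleGroup]]:
    """Random train/test split by parameter set (never by phantom slice)."""
    param_ids = sorted({g.param_set_id for g in groups})
    if len(param_ids) < spec.ratio + 1:
        raise ValueError(f"need at least {spec.ratio + 1} parameter sets for a "
                         f"{spec.ratio}:1 split, got {len(param_ids)}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(param_ids)
    n_test = max(1, round(len(param_ids) / (spec.ratio + 1)))
    test_ids = set(int(i) for i in perm[:n_test])
    train = [g for g in groups if g.param_set_id not in test_ids]
    test = [g for g in groups if g.param_set_id in test_ids]
    return train, test


def swap_group(g: SampleGroup) -> SampleGroup:
    """Exchange the two tracer roles; the dual-tracer data is unchanged."""
    return replace(g, S1=g.S2, S2=g.S1, I1=g.I2, I2=g.I1,
                   tracer1=g.tracer2, tracer2=g.tracer1,
                   half_life1=g.half_life2, half_life2=g.half_life1)


def augment_swap(groups: list[SampleGroup],
                 combos: set[tuple[str, str]] | None = None) -> list[SampleGroup]:
    """Append tracer-swapped copies of groups (all, or selected combinations)."""
    out = list(groups)
    for g in groups:
        if combos is None or (g.tracer1, g.tracer2) in combos:
            out.append(swap_group(g))
    return out


# ---------------------------------------------------------------------------
# tensors from groups
# ---------------------------------------------------------------------------

def _stack(groups: list[SampleGroup], attr: str) -> np.ndarray:
    """(N, C, a, b) stack of a sinogram/image attribute across groups."""
    return np.stack([np.moveaxis(getattr(g, attr).values, 2, 0) for g in groups])


def _batches(n: int, batch: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch):
        yield idx[i:i + batch]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _dc_branches(model, x: Tensor) -> list[Tensor]:
    return [x, T.mul(x, model._dc1), T.mul(x, model._dc2)]


def eval_sep_loss(model, variant: str, data: dict, w: LossWeights) -> float:
    """Validation separation loss of the full model (eval mode)."""
    model.eval()
    preds = model(Tensor(data["S_dual"]))
    labels = {k: Tensor(v) for k, v in data.items()}
    val = sep_loss(variant, preds, labels, w).item()
    model.train()
    return val


def run_training(model, train_groups: list[SampleGroup],
                 val_groups: list[SampleGroup],
                 cfg: TrainConfig = TrainConfig(),
                 weights: LossWeights | None = None) -> TrainResult:
    """Three-phase schedule: FBPNet pretrain, separation pretrain, joint.

    Groups must already be normalised (see ``acquisition.scale_group``).
    Pretraining decouples the two sub-networks: the FBP network learns
    (S_dual -> I_dual) and the separation network learns from noise-free
    labels; the joint phase then fine-tunes everything end to end with the
    composite total loss, starting from the pretrained weights.
    """
    if not train_groups:
        raise ValueError("empty training dataset")
    variant = model.kind
    if weights is None:
        weights = LOSS_PRESETS[variant]
    rng = np.random.default_rng(cfg.seed)

    keys = ("S_dual", "S1", "S2", "I_dual", "I1", "I2")
    tr = {k: _stack(train_groups, k) for k in keys}
    va = {k: _stack(val_groups, k) for k in keys} if val_groups else None
    history: dict[str, list[float]] = {"fbp_pretrain": [], "sep_pretrain": [],
                                       "joint": [], "val_sep": []}

    # ---- phase A: FBP-Net pretraining -----------------------------------
    fbp_params = model.fbpnet.parameters()
    opt = nn.Adam(fbp_params, lr=cfg.lr)
    if variant == "sep_fbpnet":
        # the shared FBPNet reconstructs single-tracer sinograms
        xa = np.concatenate([tr["S1"], tr["S2"]])
        ya = np.concatenate([tr["I1"], tr["I2"]])
    else:
        xa, ya = tr["S_dual"], tr["I_dual"]
    for _ in range(cfg.pretrain_fbp_epochs):
        ep = 0.0
        nb = 0
        for idx in _batches(len(xa), cfg.pretrain_batch, rng):
            opt.zero_grad()
            out = model.fbpnet(Tensor(xa[idx]))
            loss = composite_loss(out, Tensor(ya[idx]), weights.beta_fbp)
            T.backward(loss)
            opt.step()
            ep += loss.item()
            nb += 1
        history["fbp_pretrain"].append(ep / nb)

    # ---- phase B: separation pretraining --------------------------------
    sep_params = model.sepnet.parameters()
    opt = nn.Adam(sep_params, lr=cfg.lr)
    for _ in range(cfg.pretrain_sep_epochs):
        ep = 0.0
        nb = 0
        for idx in _batches(len(tr["S_dual"]), cfg.pretrain_batch, rng):
            opt.zero_grad()
            if variant == "sep_fbpnet":
                p1, p2 = model.sepnet(Tensor(tr["S_dual"][idx]))
                l1, l2 = Tensor(tr["S1"][idx]), Tensor(tr["S2"][idx])
            elif variant == "fbpnet_dc_sep":
                x = Tensor(tr["I_dual"][idx])
                p1, p2 = model.sepnet(_dc_branches(model, x))
                l1, l2 = Tensor(tr["I1"][idx]), Tensor(tr["I2"][idx])
            else:
                p1, p2 = model.sepnet(Tensor(tr["I_dual"][idx]))
                l1, l2 = Tensor(tr["I1"][idx]), Tensor(tr["I2"][idx])
            loss = T.add(composite_loss(p1, l1, weights.beta_sep),
                         composite_loss(p2, l2, weights.beta_sep))
            T.backward(loss)
            opt.step()
            ep += loss.item()
            nb += 1
        history["sep_pretrain"].append(ep / nb)

    # ---- phase C: joint fine-tuning --------------------------------------
    if va is not None:
        history["val_sep"].append(eval_sep_loss(model, variant, va, weights))
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    for _ in range(cfg.joint_epochs):
        ep = 0.0
        nb = 0
        for idx in _batches(len(tr["S_dual"]), cfg.joint_batch, rng):
            opt.zero_grad()
            preds = model(Tensor(tr["S_dual"][idx]))
            labels = {k: Tensor(tr[k][idx]) for k in keys if k != "S_dual"}
            loss = total_loss(variant, preds, labels, weights)
            T.backward(loss)
            opt.step()
            ep += loss.item()
            nb += 1
        history["joint"].append(ep / nb)
        if va is not None:
            history["val_sep"].append(eval_sep_loss(model, variant, va, weights))

    res = TrainResult(model=model, variant=variant, history=history)
    if va is not None:
        res.val_sep_before_joint = history["val_sep"][0]
        res.val_sep_after_joint = history["val_sep"][-1]
    return res
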