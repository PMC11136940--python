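"""Image-quality metrics, ROI time-activity curves, and graphical kinetic
analysis (Patlak net-uptake rate Ki, Logan total distribution volume VT).

SSIM uses the Gaussian-weighted convention of Wang et al. (11-tap window,
sigma 1.5, population covariance) through scikit-image.  Graphical analysis
operates on decay-corrected TACs: the Patlak plot regresses C_T(t)/C_P(t)
against the normalised plasma integral and reads Ki off the slope, while the
Logan plot regresses the normalised tissue integral against the normalised
plasma integral to read off VT.  Both use the last 10 frames by default,
where the linearised regimes hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .kinetics import DynamicImage
from .phantoms import PhantomSlice

__all__ = [
    "ROITac",
    "MacroParam",
    "image_metrics",
    "framewise_metrics",
    "ssim_index",
    "roi_tac",
    "tac_bias_std",
    "patlak_ki",
    "logan_vt",
    "macro_relative_error",
]

DEFAULT_FIT_FRAMES = 10


@dataclass
class ROITac:
    roi_id: int
    values: np.ndarray          # per-frame mean activity
    protocol: object

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.protocol.n_frames:
            raise ValueError("TAC length does not match protocol")


@dataclass
class MacroParam:
    roi_id: int
    kind: str                   # "Ki" (1/min) or "VT" (unitless)
    value: float
    fit_frames: int = DEFAULT_FIT_FRAMES


# ---------------------------------------------------------------------------
# image metrics
# ---------------------------------------------------------------------------

def ssim_index(pred: np.ndarray, label: np.ndarray,
               data_range: float | None = None) -> float:
    """Gaussian-weighted SSIM of one 2-D frame."""
    if data_range is None:
        data_range = float(label.max() - label.min()) or 1.0
    return float(structural_similarity(
        pred, label, data_range=data_range, gaussian_weights=True,
        sigma=1.5, use_sample_covariance=False))


def _check_pair(pred: DynamicImage, label: DynamicImage) -> None:
    if pred.values.shape != label.values.shape:
        raise ValueError("prediction and label shapes differ")


def framewise_metrics(pred: DynamicImage,
                      label: DynamicImage) -> dict[str, np.ndarray]:
    """Per-frame MSE, SSIM and PSNR vectors (length = frame count)."""
    _check_pair(pred, label)
    c = pred.values.shape[2]
    peak = float(label.values.max())
    rng = float(label.values.max() - label.values.min()) or 1.0
    mse = np.empty(c)
    ssim = np.empty(c)
    psnr = np.empty(c)
    for f in range(c):
        diff = pred.values[:, :, f] - label.values[:, :, f]
        mse[f] = float(np.mean(diff**2))
        ssim[f] = ssim_index(pred.values[:, :, f], label.values[:, :, f], rng)
        psnr[f] = (np.inf if mse[f] == 0
                   else 10.0 * np.log10(peak**2 / mse[f]))
    return {"mse": mse, "ssim": ssim, "psnr": psnr}


def image_metrics(pred: DynamicImage,
                  label: DynamicImage) -> tuple[float, float, float]:
    """(MSE, SSIM, PSNR) of a dynamic volume.

    MSE is the elementwise mean, SSIM the frame average, PSNR derives from
    the global MSE with peak = label maximum (infinite for a perfect match).
    """
    fw = framewise_metrics(pred, label)
    mse = float(fw["mse"].mean())
    ssim = float(fw["ssim"].mean())
    peak = float(label.values.max())
    psnr = np.inf if mse == 0 else 10.0 * np.log10(peak**2 / mse)
    return mse, ssim, psnr


# ---------------------------------------------------------------------------
# ROI TACs
# ---------------------------------------------------------------------------

def roi_tac(img: DynamicImage, phantom: PhantomSlice, roi: int) -> ROITac:
    """Frame-wise mean activity over one ROI's pixels."""
    mask = phantom.label_map == roi
    if not mask.any():
        raise ValueError(f"ROI {roi} is empty in this phantom")
    return ROITac(roi_id=roi, values=img.values[mask].mean(axis=0),
                  protocol=img.protocol)


def tac_bias_std(preds: list[DynamicImage], labels: list[DynamicImage],
                 phantom: PhantomSlice, roi: int,
                 floor_frac: float = 1e-3) -> tuple[float, float]:
    """Mean absolute bias (%) and within-ROI variation (%) of predicted TACs.

    bias% averages |pred - label| / label over frames and samples (frames
    whose label mean falls below ``floor_frac`` of the TAC peak excluded);
    std% averages the across-ROI-pixel standard deviation of the prediction
    divided by the label ROI mean.
    """
    mask = phantom.label_map == roi
    if not mask.any():
        raise ValueError(f"ROI {roi} is empty in this phantom")
    biases, stds = [], []
    for pred, label in zip(preds, labels):
        lab_tac = label.values[mask].mean(axis=0)
        pred_tac = pred.values[mask].mean(axis=0)
        pred_std = pred.values[mask].std(axis=0)
        valid = lab_tac > floor_frac * lab_tac.max()
        if not valid.any():
            raise ValueError("all frames below the label floor")
        biases.append(np.mean(np.abs(pred_tac[valid] - lab_tac[valid])
                              / lab_tac[valid]) * 100.0)
        stds.append(np.mean(pred_std[valid] / lab_tac[valid]) * 100.0)
    return float(np.mean(biases)), float(np.mean(stds))


# ---------------------------------------------------------------------------
# graphical analysis
# ---------------------------------------------------------------------------

def _cum_trapz_from_zero(vals: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral on frame midpoints, anchored at t=0
    where the curves start from zero."""
    tt = np.concatenate([[0.0], t])
    vv = np.concatenate([[0.0], vals])
    return np.cumsum(np.diff(tt) * 0.5 * (vv[:-1] + vv[1:]))


def _fit_slope(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) < 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("degenerate graphical plot: abscissa is constant")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def patlak_ki(ct: ROITac | np.ndarray, cp: np.ndarray, t_mid: np.ndarray,
              window: int = DEFAULT_FIT_FRAMES) -> float:
    """Patlak net uptake rate Ki (1/min) from decay-corrected TACs.

    OLS of y = C_T(t)/C_P(t) against x = int_0^t C_P / C_P(t) over the last
    ``window`` frames; the slope estimates Ki = K1*k3/(k2+k3) for an
    irreversible tracer.
    """
    ct_vals = ct.values if isinstance(ct, ROITac) else np.asarray(ct, float)
    cp = np.asarray(cp, dtype=np.float64)
    icp = _cum_trapz_from_zero(cp, t_mid)
    sl = slice(len(ct_vals) - window, len(ct_vals))
    if np.any(cp[sl] <= 0):
        raise ValueError("plasma curve must be positive on the fit window")
    x = icp[sl] / cp[sl]
    y = ct_vals[sl] / cp[sl]
    return _fit_slope(x, y)


def logan_vt(ct: ROITac | np.ndarray, cp: np.ndarray, t_mid: np.ndarray,
             window: int = DEFAULT_FIT_FRAMES) -> float:
    """Logan total distribution volume VT from decay-corrected TACs.

    OLS of y = int_0^t C_T / C_T(t) against x = int_0^t C_P / C_T(t) over the
    last ``window`` frames; the slope estimates VT = (K1/k2)(1 + k3/k4) for a
    reversible tracer.
    """
    ct_vals = ct.values if isinstance(ct, ROITac) else np.asarray(ct, float)
    cp = np.asarray(cp, dtype=np.float64)
    icp = _cum_trapz_from_zero(cp, t_mid)
    ict = _cum_trapz_from_zero(ct_vals, t_mid)
    sl = slice(len(ct_vals) - window, len(ct_vals))
    if np.any(ct_vals[sl] <= 0):
        raise ValueError("tissue curve must be positive on the fit window")
    x = icp[sl] / ct_vals[sl]
    y = ict[sl] / ct_vals[sl]
    return _fit_slope(x, y)


def macro_relative_error(pred: MacroParam, truth: MacroParam) -> float:
    """Signed relative error (%) of an estimated macro-parameter."""
    if pred.kind != truth.kind or pred.roi_id != truth.roi_id:
        raise ValueError("macro-parameters do not refer to the same quantity")
    if truth.value == 0:
        raise ValueError("true macro-parameter is zero")
    return (pred.value - truth.value) / truth.value * 100.0
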