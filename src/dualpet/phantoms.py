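"""Procedural 2-D brain-like phantoms.

Each phantom is an integer label map on a 128 x 128 grid (configurable) with
up to five regions of interest: two large interleaved tissue regions (an
outer cortical band, ROI 1, and an inner core, ROI 2) inside a head-like
ellipse, plus up to three small elliptical lesions (ROIs 3-5) embedded in the
core.  ROI pixel counts are drawn uniformly within +/-30% of the target mean
sizes 1393, 1427, 78, 110 and 130 pixels, so an ensemble of phantoms
reproduces those averages without any external anatomical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomConfig", "PhantomSlice", "generate_phantom", "generate_phantom_set"]

#: target mean pixel counts for ROIs 1..5
DEFAULT_ROI_MEANS = (1393, 1427, 78, 110, 130)


@dataclass(frozen=True)
class PhantomConfig:
    grid_size: int = 128
    roi_mean_sizes: tuple[int, ...] = DEFAULT_ROI_MEANS
    size_spread: float = 0.30  # uniform half-width, fraction of the mean
    n_small_rois: int = 3      # lesions, labels 3..(2 + n_small_rois)

    def size_range(self, roi: int) -> tuple[float, float]:
        mean = self.roi_mean_sizes[roi - 1]
        return (1 - self.size_spread) * mean, (1 + self.size_spread) * mean

    def __post_init__(self):
        if not 0 <= self.n_small_rois <= 3:
            raise ValueError("n_small_rois must be in 0..3")
        if self.grid_size < 32:
            raise ValueError("grid too small for a head phantom")


@dataclass
class PhantomSlice:
    """Integer ROI label map: 0 = background, 1..5 = ROI index."""

    label_map: np.ndarray
    slice_id: int
    roi_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map, dtype=np.int64)
        labels = set(np.unique(self.label_map)) - {0}
        if not labels <= {1, 2, 3, 4, 5}:
            raise ValueError("labels must lie in {0,..,5}")
        if not {1, 2} <= labels:
            raise ValueError("ROIs 1 and 2 must be present")
        recount = {int(r): int((self.label_map == r).sum()) for r in sorted(labels)}
        if self.roi_sizes and self.roi_sizes != recount:
            raise ValueError("roi_sizes inconsistent with label map")
        self.roi_sizes = recount

    @property
    def rois(self) -> list[int]:
        return sorted(self.roi_sizes)


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _fit_ellipse_to_count(base_mask: np.ndarray, h: int, w: int, cy: float,
                          cx: float, aspect: float, angle: float,
                          target: float) -> np.ndarray:
    """Ellipse (intersected with base_mask) whose pixel count ~= target."""
    rx = np.sqrt(target * aspect / np.pi)
    for _ in range(25):
        mask = _ellipse_mask(h, w, cy, cx, rx / aspect, rx, angle) & base_mask
        n = mask.sum()
        if n == 0:
            rx *= 1.5
            continue
        if abs(n - target) <= max(2.0, 0.01 * target):
            break
        rx *= np.sqrt(target / n)
    return mask


def generate_phantom(seed: int, config: PhantomConfig | None = None) -> PhantomSlice:
    """Generate one labelled phantom slice, deterministic in ``seed``."""
    config = config or PhantomConfig()
    n = config.grid_size
    rng = np.random.default_rng(seed)

    # sample targets slightly inside the configured range so that pixel
    # discretisation cannot push realised counts out of range
    margin = 0.92

    def draw_target(roi: int) -> float:
        mean = config.roi_mean_sizes[roi - 1]
        half = margin * config.size_spread * mean
        return rng.uniform(mean - half, mean + half)

    small_targets = [draw_target(3 + i) for i in range(config.n_small_rois)]
    target1 = draw_target(1)
    target2 = draw_target(2)
    needed = target1 + target2 + sum(small_targets)
    head_area_frac = 0.45  # ROIs occupy at most ~45% of the head ellipse
    if needed > head_area_frac * np.pi * (0.45 * n) * (0.38 * n):
        raise ValueError("configured ROI sizes cannot be packed into the grid")

    # head-like ellipse centred with jitter
    cy = n / 2 + rng.uniform(-0.02, 0.02) * n
    cx = n / 2 + rng.uniform(-0.02, 0.02) * n
    ry = rng.uniform(0.42, 0.47) * n
    rx = rng.uniform(0.34, 0.42) * n
    tilt = rng.uniform(-0.3, 0.3)
    head = _ellipse_mask(n, n, cy, cx, ry, rx, tilt)

    # inner core (ROI 2 + lesions): fit an ellipse holding target2 + lesions
    core_aspect = rng.uniform(0.8, 1.25)
    core_angle = rng.uniform(0, np.pi)
    core = _fit_ellipse_to_count(head, n, n, cy, cx, core_aspect, core_angle,
                                 target2 + sum(small_targets))

    # cortical band (ROI 1): annulus between the core and an outer ellipse
    outer_aspect = core_aspect
    outer = _fit_ellipse_to_count(head, n, n, cy, cx, outer_aspect, core_angle,
                                  target1 + core.sum())
    band = outer & ~core

    label = np.zeros((n, n), dtype=np.int64)
    label[band] = 1
    label[core] = 2

    # small lesions inside the core, non-overlapping
    core_idx = np.argwhere(core)
    for i, target in enumerate(small_targets):
        roi_label = 3 + i
        lo, hi = config.size_range(roi_label)
        placed = False
        for _ in range(200):
            cyi, cxi = core_idx[rng.integers(len(core_idx))]
            aspect = rng.uniform(0.7, 1.4)
            angle = rng.uniform(0, np.pi)
            rr = np.sqrt(target * aspect / np.pi)
            best = None
            best_err = np.inf
            for _ in range(12):  # refine radius to the target pixel count
                cand = _ellipse_mask(n, n, cyi, cxi, rr / aspect, rr, angle)
                cnt = cand.sum()
                err = abs(cnt - target)
                if lo <= cnt <= hi and err < best_err and np.all(label[cand] == 2):
                    best, best_err = cand, err
                    if err <= 1.0:
                        break
                rr *= np.sqrt(target / max(cnt, 1)) if cnt else 1.3
            if best is not None:
                label[best] = roi_label
                placed = True
                break
        if not placed:
            raise ValueError("could not place small ROI inside the core")

    return PhantomSlice(label_map=label, slice_id=int(seed))


def generate_phantom_set(n: int, seed: int,
                         config: PhantomConfig | None = None) -> list[PhantomSlice]:
    """Generate ``n`` distinct phantom slices with seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    slices = []
    for i, child in enumerate(child_seeds):
        ph = generate_phantom(child, config)
        ph.slice_id = i
        slices.append(ph)
    return slices
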