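"""Tomographic data acquisition: forward projection, randoms, Poisson noise,
dose reduction, and assembly of matched training groups.

The projector is an idealized 2-D parallel-beam Radon transform implemented
as an explicit sparse matrix (pixel-driven with linear bin interpolation), so
its adjoint is the exact matrix transpose — the property the EM
reconstructions and the adjoint tests rely on.  Default geometry: 128 radial
bins x 160 angles over 180 degrees, matching the sinogram shape of the
simulated scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .kinetics import DynamicImage, ScanProtocol, TracerSpec, build_activity_image, dual_sum, randomize_params

__all__ = [
    "GeomConfig",
    "DynamicSinogram",
    "SampleGroup",
    "system_matrix",
    "project",
    "add_randoms_and_noise",
    "thin_counts",
    "make_group",
    "scale_group",
    "unscale_group",
]


@dataclass(frozen=True)
class GeomConfig:
    """Parallel-beam geometry: image size, radial bins and angles over 180 deg."""

    image_size: int = 128
    n_bins: int = 128
    n_angles: int = 160

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0)


@dataclass
class DynamicSinogram:
    """bins x angles x C expected or Poisson-sampled counts."""

    values: np.ndarray
    protocol: ScanProtocol
    noisy: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("sinogram must be bins x angles x C")
        if self.values.shape[2] != self.protocol.n_frames:
            raise ValueError("frame count does not match protocol")

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "DynamicSinogram":
        return DynamicSinogram(self.values.copy(), self.protocol, self.noisy)


@dataclass
class SampleGroup:
    """The matched sextet of one (parameter set, phantom slice) combination."""

    S_dual: DynamicSinogram
    S1: DynamicSinogram
    S2: DynamicSinogram
    I_dual: DynamicImage
    I1: DynamicImage
    I2: DynamicImage
    param_set_id: int
    slice_id: int
    sino_scale: float = 1.0
    img_scale: float = 1.0
    tracer1: str = ""
    tracer2: str = ""
    half_life1: float = 0.0
    half_life2: float = 0.0


# ---------------------------------------------------------------------------
# system matrix
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def system_matrix(geom: GeomConfig) -> sp.csr_matrix:
    """Sparse (bins*angles) x (H*W) projection matrix.

    Pixel-driven: each pixel's centre is projected onto the detector axis at
    every angle and splat linearly onto the two neighbouring radial bins, so
    per-angle bin sums conserve the image mass for in-field pixels.
    """
    n = geom.image_size
    nb = geom.n_bins
    centers = geom.bin_centers
    s0 = centers[0]
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - (n - 1) / 2.0).ravel()
    y = (yy - (n - 1) / 2.0).ravel()
    rows, cols, vals = [], [], []
    pix = np.arange(n * n)
    for a, th in enumerate(geom.angles):
        s = x * np.cos(th) + y * np.sin(th)
        f = s - s0
        b0 = np.floor(f).astype(np.int64)
        w1 = f - b0
        for b, w in ((b0, 1.0 - w1), (b0 + 1, w1)):
            ok = (b >= 0) & (b < nb) & (w > 0)
            rows.append(a + b[ok] * geom.n_angles)
            cols.append(pix[ok])
            vals.append(w[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    G = sp.csr_matrix((vals, (rows, cols)),
                      shape=(nb * geom.n_angles, n * n))
    return G


def project(image: DynamicImage, geom: GeomConfig) -> DynamicSinogram:
    """Frame-by-frame parallel-beam projection (linear in the image)."""
    h, w, c = image.values.shape
    if h != geom.image_size or w != geom.image_size:
        raise ValueError(f"image size {h}x{w} does not match geometry "
                         f"{geom.image_size}")
    G = system_matrix(geom)
    flat = image.values.reshape(h * w, c)
    sino = (G @ flat).reshape(geom.n_bins, geom.n_angles, c)
    return DynamicSinogram(sino, image.protocol, noisy=False)


def backproject_matrix(geom: GeomConfig) -> sp.csr_matrix:
    """Unfiltered back-projection operator (H*W) x (bins*angles)."""
    return system_matrix(geom).T.tocsr()


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def randoms_field(clean: DynamicSinogram, randoms_frac: float) -> np.ndarray:
    """Spatially uniform per-frame randoms with total = frac * total(clean)."""
    if randoms_frac < 0:
        raise ValueError("randoms fraction must be non-negative")
    nb, na, c = clean.values.shape
    frame_tot = clean.values.sum(axis=(0, 1))
    return np.broadcast_to(randoms_frac * frame_tot / (nb * na),
                           (nb, na, c)).copy()


def add_randoms_and_noise(clean: DynamicSinogram, randoms_frac: float = 0.2,
                          seed: int | np.random.Generator = 0) -> DynamicSinogram:
    """Poisson counts with mean = clean + uniform randoms (20% by default)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mean = clean.values + randoms_field(clean, randoms_frac)
    noisy = rng.poisson(mean).astype(np.float64)
    return DynamicSinogram(noisy, clean.protocol, noisy=True)


def thin_counts(noisy: DynamicSinogram, keep: float,
                seed: int | np.random.Generator = 0) -> DynamicSinogram:
    """Binomial thinning: keep each event independently with probability
    ``keep``, preserving the Poisson character with scaled mean."""
    if not 0 < keep <= 1:
        raise ValueError("keep fraction must be in (0, 1]")
    if keep == 1.0:
        return noisy.copy()
    counts = noisy.values
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("thinning requires integer counts")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    thinned = rng.binomial(counts.astype(np.int64), keep).astype(np.float64)
    return DynamicSinogram(thinned, noisy.protocol, noisy=True)


# ---------------------------------------------------------------------------
# group assembly
# ---------------------------------------------------------------------------

def make_group(phantom, spec1: TracerSpec, spec2: TracerSpec,
               protocol: ScanProtocol, geom: GeomConfig,
               seed: int | np.random.Generator = 0,
               randoms_frac: float = 0.2,
               target_counts: float = 1e7,
               randomize_cv: float = 0.0,
               param_set_id: int = 0,
               sum_noisy_singles: bool = False) -> SampleGroup:
    """Build the matched sextet (S_dual, S1, S2, I_dual, I1, I2).

    ``target_counts`` calibrates the global count level so a standard-dose
    dual-tracer sinogram totals that many events (randoms included).  With
    ``sum_noisy_singles`` False (default) the dual sinogram receives its own
    Poisson realisation of the summed clean expectation; True instead sums
    the two noisy single-tracer sinograms.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if randomize_cv > 0:
        spec1 = randomize_params(spec1, randomize_cv, rng)
        spec2 = randomize_params(spec2, randomize_cv, rng)
    i1 = build_activity_image(phantom, spec1, protocol)
    i2 = build_activity_image(phantom, spec2, protocol)
    idual = dual_sum(i1, i2)

    clean1 = project(i1, geom)
    clean2 = project(i2, geom)
    clean_dual = DynamicSinogram(clean1.values + clean2.values, protocol)

    total = clean_dual.values.sum() * (1.0 + randoms_frac)
    if total <= 0:
        raise ValueError("phantom produced an empty sinogram")
    count_scale = target_counts / total
    for s in (clean1, clean2, clean_dual):
        s.values *= count_scale

    s_dual = (DynamicSinogram(np.zeros_like(clean_dual.values), protocol)
              if sum_noisy_singles else
              add_randoms_and_noise(clean_dual, randoms_frac, rng))
    s1 = add_randoms_and_noise(clean1, randoms_frac, rng)
    s2 = add_randoms_and_noise(clean2, randoms_frac, rng)
    if sum_noisy_singles:
        s_dual = DynamicSinogram(s1.values + s2.values, protocol, noisy=True)

    return SampleGroup(
        S_dual=s_dual, S1=s1, S2=s2, I_dual=idual, I1=i1, I2=i2,
        param_set_id=param_set_id, slice_id=phantom.slice_id,
        tracer1=spec1.name, tracer2=spec2.name,
        half_life1=spec1.half_life, half_life2=spec2.half_life,
    )


def scale_group(g: SampleGroup) -> SampleGroup:
    """Normalise a group: sinograms by max(S_dual)/3, images by max(S_dual)/150.

    Both scales derive from the dual sinogram maximum, so the image scale is
    the sinogram scale divided by 50; the factors are stored for inversion.
    """
    m = g.S_dual.values.max()
    if m <= 0:
        raise ValueError("cannot scale a group with an all-zero dual sinogram")
    sino_scale = m / 3.0
    img_scale = m / 150.0
    out = replace(g, sino_scale=g.sino_scale * sino_scale,
                  img_scale=g.img_scale * img_scale)
    for name in ("S_dual", "S1", "S2"):
        sino = getattr(g, name)
        setattr(out, name, DynamicSinogram(sino.values / sino_scale,
                                           sino.protocol, sino.noisy))
    for name in ("I_dual", "I1", "I2"):
        img = getattr(g, name)
        setattr(out, name, DynamicImage(img.values / img_scale, img.protocol,
                                        img.decay_corrected))
    return out


def unscale_group(g: SampleGroup) -> SampleGroup:
    """Invert :func:`scale_group`, restoring raw units."""
    out = replace(g, sino_scale=1.0, img_scale=1.0)
    for name in ("S_dual", "S1", "S2"):
        sino = getattr(g, name)
        setattr(out, name, DynamicSinogram(sino.values * g.sino_scale,
                                           sino.protocol, sino.noisy))
    for name in ("I_dual", "I1", "I2"):
        img = getattr(g, name)
        setattr(out, name, DynamicImage(img.values * g.img_scale, img.protocol,
                                        img.decay_corrected))
    return out
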