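"""Tracer kinetics: plasma input functions, the two-tissue compartment model,
frame sampling and radioactive decay.

A dynamic PET frame value at a pixel is the frame-time average of the
undecayed tissue concentration C_T(t) produced by the two-tissue compartment
model, multiplied by the physical-decay factor 2^(-t/T) of the tracer
(evaluated at the frame midpoint).  The compartment system

    dC1/dt = K1*Cp(t) - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    C_T    = C1 + C2

is linear with a tri-exponential forcing term, so it is solved in closed form
by eigen-decomposition of the 2x2 rate matrix and analytic convolution of
exponentials; a fine-step Runge-Kutta integration serves as the independent
oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InputFunctionParams",
    "KineticParams",
    "TracerSpec",
    "ScanProtocol",
    "DynamicImage",
    "CompartmentState",
    "FDG_INPUT_PARAMS",
    "input_function",
    "solve_2tcm",
    "frame_average",
    "apply_decay",
    "decay_factors",
    "randomize_params",
    "build_activity_image",
    "dual_sum",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunctionParams:
    """Parameters of the tri-exponential plasma input function.

    Cp(t) = (A1*t - A2 - A3) e^(lam1 t) + A2 e^(lam2 t) + A3 e^(lam3 t)

    A1 in uCi/mL/min; A2, A3 in uCi/mL; lam1..lam3 in 1/min (all negative).
    """

    A1: float
    A2: float
    A3: float
    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self):
        if not (self.lam1 < 0 and self.lam2 < 0 and self.lam3 < 0):
            raise ValueError("input-function exponents lam1..lam3 must be negative")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("A1", "A2", "A3", "lam1", "lam2", "lam3")}


#: Published arterial input function parameters for 18F-FDG in human subjects.
FDG_INPUT_PARAMS = InputFunctionParams(
    A1=851.1, A2=21.88, A3=20.81, lam1=-4.134, lam2=-0.1191, lam3=-0.01043
)


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue compartment rate constants, all in 1/min and >= 0."""

    K1: float
    k2: float
    k3: float
    k4: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4])


@dataclass(frozen=True)
class TracerSpec:
    """A tracer: physical half-life, input function and per-ROI kinetics."""

    name: str
    half_life: float  # min
    input_fn: InputFunctionParams
    roi_kinetics: dict[int, KineticParams]
    kinetic_type: str  # "irreversible" | "reversible"

    def __post_init__(self):
        if self.half_life <= 0:
            raise ValueError("half-life must be positive")
        if self.kinetic_type not in ("irreversible", "reversible"):
            raise ValueError(f"unknown kinetic type {self.kinetic_type!r}")


@dataclass(frozen=True)
class ScanProtocol:
    """Ordered frame boundaries in minutes, starting at 0."""

    frame_edges: tuple[float, ...]

    def __post_init__(self):
        edges = np.asarray(self.frame_edges)
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("frame edges must start at 0 and strictly increase")

    @classmethod
    def default(cls) -> "ScanProtocol":
        """60-min scan in 26 frames: 8 x 15 s, 8 x 60 s, 10 x 300 s."""
        durations = [0.25] * 8 + [1.0] * 8 + [5.0] * 10
        return cls(tuple(np.concatenate([[0.0], np.cumsum(durations)])))

    @property
    def n_frames(self) -> int:
        return len(self.frame_edges) - 1

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.frame_edges)

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total_time(self) -> float:
        return float(self.frame_edges[-1])


@dataclass
class DynamicImage:
    """H x W x C stack of activity frames (uCi/mL) with its scan protocol."""

    values: np.ndarray
    protocol: ScanProtocol
    decay_corrected: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("dynamic image must be H x W x C")
        if self.values.shape[2] != self.protocol.n_frames:
            raise ValueError("frame count does not match protocol")

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "DynamicImage":
        return DynamicImage(self.values.copy(), self.protocol, self.decay_corrected)


@dataclass
class CompartmentState:
    """Solution of the compartment system on a time grid, plus the analytic
    continuous-time tissue curve for exact frame integration."""

    t: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    ct_fn: object = field(repr=False)  # vectorized t -> C_T(t)

    @property
    def CT(self) -> np.ndarray:
        return self.C1 + self.C2


# ---------------------------------------------------------------------------
# input function
# ---------------------------------------------------------------------------

def input_function(t, p: InputFunctionParams):
    """Evaluate the tri-exponential plasma input function Cp(t) (uCi/mL)."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("input function is defined for t >= 0 only")
    cp = ((p.A1 * t - p.A2 - p.A3) * np.exp(p.lam1 * t)
          + p.A2 * np.exp(p.lam2 * t)
          + p.A3 * np.exp(p.lam3 * t))
    return cp if cp.shape else float(cp)


# ---------------------------------------------------------------------------
# closed-form 2TCM solution
# ---------------------------------------------------------------------------

def _phi(mu, t):
    """phi(mu, t) = integral_0^t e^(mu s) ds, stable for small mu."""
    mu = np.asarray(mu, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    small = np.abs(mu * t) < 1e-8
    mu_safe = np.where(small, 1.0, mu)
    exact = np.expm1(mu_safe * t) / mu_safe
    series = t * (1.0 + mu * t / 2.0 + (mu * t) ** 2 / 6.0)
    return np.where(small, series, exact)


def _psi(mu, t):
    """psi(mu, t) = integral_0^t s e^(mu s) ds, stable for small mu."""
    mu = np.asarray(mu, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    small = np.abs(mu * t) < 1e-6
    mu_safe = np.where(small, 1.0, mu)
    exact = (t * np.exp(mu_safe * t) - _phi(mu_safe, t)) / mu_safe
    series = t**2 * (0.5 + mu * t / 3.0 + (mu * t) ** 2 / 8.0)
    return np.where(small, series, exact)


def _exp_conv(theta: float, t: np.ndarray, p: InputFunctionParams) -> np.ndarray:
    """E(theta, t) = integral_0^t e^(-theta (t - s)) Cp(s) ds, analytically.

    Cp is a sum of (a*s + b) e^(lam s) terms, so each contribution reduces to
    the stable helpers phi/psi evaluated at mu = lam + theta.
    """
    terms = [
        (p.A1, p.lam1, True),            # A1 * s * e^(lam1 s)
        (-(p.A2 + p.A3), p.lam1, False),
        (p.A2, p.lam2, False),
        (p.A3, p.lam3, False),
    ]
    out = np.zeros_like(np.asarray(t, dtype=np.float64))
    damp = np.exp(-theta * t)
    for coef, lam, linear in terms:
        mu = lam + theta
        out = out + coef * damp * (_psi(mu, t) if linear else _phi(mu, t))
    return out


def solve_2tcm(p: InputFunctionParams, k: KineticParams,
               t_grid: np.ndarray) -> CompartmentState:
    """Solve the two-tissue compartment model with zero initial conditions.

    Returns compartment concentrations on ``t_grid`` together with an
    analytic callable for C_T(t) used by :func:`frame_average`.
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and strictly increase")
    K1, k2, k3, k4 = k.K1, k.k2, k.k3, k.k4

    if K1 == 0.0:
        zero = lambda t: np.zeros_like(np.asarray(t, dtype=np.float64))
        z = np.zeros_like(t_grid)
        return CompartmentState(t=t_grid, C1=z, C2=z.copy(), ct_fn=zero)

    # rate matrix M = [[-(k2+k3), k4], [k3, -k4]]; solution is
    # C(t) = K1 * V diag(E(theta_j, t)) V^-1 e1 with eigenvalues -theta_j
    M = np.array([[-(k2 + k3), k4], [k3, -k4]])
    evals, V = np.linalg.eig(M)
    # the discriminant (k2+k3+k4)^2 - 4*k2*k4 is always >= 0, so the spectrum
    # is real; strip any numerically-spurious imaginary part
    evals, V = evals.real, V.real
    thetas = -evals
    if abs(thetas[0] - thetas[1]) < 1e-9 * max(1.0, abs(thetas[0])):
        # near-defective rate matrix: nudge apart (error O(1e-9) in rates)
        k4n = k4 * (1 + 1e-7) + 1e-12
        M = np.array([[-(k2 + k3), k4n], [k3, -k4n]])
        evals, V = np.linalg.eig(M)
        evals, V = evals.real, V.real
        thetas = -evals
    coef = np.linalg.solve(V, np.array([K1, 0.0]))

    def components(t):
        t = np.asarray(t, dtype=np.float64)
        e = np.stack([_exp_conv(thetas[0], t, p), _exp_conv(thetas[1], t, p)])
        c = V @ (coef[:, None] * e.reshape(2, -1))
        return c.reshape(2, *t.shape)

    def ct_fn(t):
        c = components(t)
        return c[0] + c[1]

    c = components(t_grid)
    return CompartmentState(t=t_grid, C1=c[0], C2=c[1], ct_fn=ct_fn)


# ---------------------------------------------------------------------------
# frame sampling and decay
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


def frame_average(state: CompartmentState, protocol: ScanProtocol) -> np.ndarray:
    """Per-frame time-average of C_T over each frame interval.

    Uses 32-point Gauss-Legendre quadrature per frame on the analytic tissue
    curve, which is exact to float precision for the smooth bi-exponential
    solutions involved.
    """
    if protocol.total_time > state.t[-1] + 1e-9:
        raise ValueError("protocol extends beyond the solved time span")
    edges = protocol.edges
    lo, hi = edges[:-1], edges[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    # (frames, nodes) evaluation points
    pts = mid[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = state.ct_fn(pts)
    return (vals * _GL_WEIGHTS[None, :]).sum(axis=1) * 0.5


def decay_factors(protocol: ScanProtocol, T: float) -> np.ndarray:
    """Per-frame decay factors 2^(-t_mid / T) at the frame midpoints."""
    if T <= 0:
        raise ValueError("half-life must be positive")
    return 2.0 ** (-protocol.midpoints / T)


def apply_decay(tac: np.ndarray, protocol: ScanProtocol, T: float) -> np.ndarray:
    """Multiply a per-frame activity vector by the physical decay factors."""
    tac = np.asarray(tac, dtype=np.float64)
    if tac.shape[-1] != protocol.n_frames:
        raise ValueError("TAC length does not match protocol")
    return tac * decay_factors(protocol, T)


# ---------------------------------------------------------------------------
# parameter randomisation (inter-subject variability)
# ---------------------------------------------------------------------------

def _draw_like(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Gaussian draw with sd = cv*|mean|; redrawn until the sign matches the
    mean (rate constants stay >= 0, decay exponents stay negative)."""
    if cv == 0.0 or mean == 0.0:
        return mean
    for _ in range(1000):
        val = rng.normal(mean, cv * abs(mean))
        if val * mean > 0:
            return val
    raise RuntimeError("sign-consistent draw failed")  # pragma: no cover


def randomize_params(means: TracerSpec, cv: float = 0.10,
                     seed: int | np.random.Generator = 0) -> TracerSpec:
    """Randomise input-function and per-ROI kinetic parameters.

    Each parameter is drawn independently from a Gaussian centred at its mean
    with standard deviation ``cv`` times the absolute mean (default 10%,
    emulating inter-subject physiological variability).
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ifp = means.input_fn
    new_if = InputFunctionParams(**{name: _draw_like(val, cv, rng)
                                    for name, val in ifp.as_dict().items()})
    new_kin = {}
    for roi, kp in sorted(means.roi_kinetics.items()):
        new_kin[roi] = KineticParams(
            K1=_draw_like(kp.K1, cv, rng),
            k2=_draw_like(kp.k2, cv, rng),
            k3=_draw_like(kp.k3, cv, rng),
            k4=_draw_like(kp.k4, cv, rng),
        )
    return replace(means, input_fn=new_if, roi_kinetics=new_kin)


# ---------------------------------------------------------------------------
# activity images
# ---------------------------------------------------------------------------

def roi_frame_tac(spec: TracerSpec, roi: int, protocol: ScanProtocol,
                  decayed: bool = True) -> np.ndarray:
    """Frame-averaged (optionally decayed) TAC for one ROI of a tracer."""
    if roi not in spec.roi_kinetics:
        raise KeyError(f"tracer {spec.name!r} has no kinetics for ROI {roi}")
    t_grid = np.linspace(0.0, protocol.total_time, 2)
    state = solve_2tcm(spec.input_fn, spec.roi_kinetics[roi], t_grid)
    tac = frame_average(state, protocol)
    if decayed:
        tac = apply_decay(tac, protocol, spec.half_life)
    return tac


def build_activity_image(phantom, spec: TracerSpec,
                         protocol: ScanProtocol) -> DynamicImage:
    """Noise-free single-tracer dynamic image from a labelled phantom.

    Every pixel of ROI r carries the decayed, frame-averaged tissue TAC of
    ROI r; background pixels are zero.
    """
    label_map = phantom.label_map
    rois = sorted(int(r) for r in np.unique(label_map) if r != 0)
    missing = [r for r in rois if r not in spec.roi_kinetics]
    if missing:
        raise KeyError(f"tracer {spec.name!r} lacks kinetics for ROIs {missing}")
    h, w = label_map.shape
    values = np.zeros((h, w, protocol.n_frames))
    for roi in rois:
        tac = roi_frame_tac(spec, roi, protocol, decayed=True)
        values[label_map == roi] = tac
    return DynamicImage(values, protocol, decay_corrected=False)


def dual_sum(i1: DynamicImage, i2: DynamicImage) -> DynamicImage:
    """Dual-tracer activity image as the pixel-wise sum of two tracers."""
    if i1.values.shape != i2.values.shape:
        raise ValueError("image shapes do not match")
    if i1.protocol.frame_edges != i2.protocol.frame_edges:
        raise ValueError("scan protocols do not match")
    return DynamicImage(i1.values + i2.values, i1.protocol,
                        decay_corrected=i1.decay_corrected and i2.decay_corrected)
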