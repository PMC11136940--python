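# Methods

`dualpet` simulates simultaneous dual-tracer dynamic PET data, reconstructs
and separates the two tracers' dynamic images with a
reconstruction–separation neural network, and evaluates image quality and
kinetic-parameter recovery. This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## The measurement model

A dynamic PET scan acquires, per time frame, a sinogram of coincidence
counts. For two simultaneously injected tracers the detector cannot tell the
tracers apart (both emit 511-keV annihilation photons), so the measurement is

    S_dual(t) ~ Poisson{ G [I1(t) + I2(t)] + r(t) },

where `G` is the system (projection) matrix, `I1`, `I2` are the two
single-tracer activity images and `r(t)` is the randoms background. Scatter
is not modelled. Separation is possible only because the two tracers differ
in kinetics and/or physical half-life, i.e. in their temporal signatures.

Each pixel's activity follows a two-tissue compartment model driven by a
plasma input function `Cp(t)`:

    dC1/dt = K1*Cp − (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 − k4*C2,      C_T = C1 + C2,

multiplied by the physical decay factor `2^(−t/T)` with half-life `T`. The
input function is tri-exponential,
`Cp(t) = (A1*t − A2 − A3) e^(λ1 t) + A2 e^(λ2 t) + A3 e^(λ3 t)`; the FDG
parameters are the published human arterial values (A1 = 851.1 µCi/mL/min,
A2 = 21.88, A3 = 20.81 µCi/mL, λ = −4.134, −0.1191, −0.01043 min⁻¹).

**Solver.** The compartment system is linear with exponential-polynomial
forcing, so it is solved in closed form: eigen-decomposition of the 2×2 rate
matrix and analytic convolution of exponentials, with series fallbacks for
near-degenerate exponents (`|μt| < 1e−8`) and a nudge for a numerically
defective rate matrix. Agreement with a fine-step RK4 integration
(dt = 0.001 min) is ~1e−12 relative, far inside the 0.1% contract the tests
assert.

**Frame sampling.** Frame values are frame-time *averages* of the continuous
curve (32-point Gauss–Legendre per frame on the analytic solution), matching
how a scanner integrates counts; decay is evaluated at frame midpoints. Both
conventions are choices — instantaneous midpoint sampling would change label
values by <1% for the default framing.

**Scan protocol.** 60 min in 26 frames (8×15 s, 8×60 s, 10×300 s).

## Phantoms

The phantom ensemble consists of 40 two-dimensional 128×128 brain slices
with up to five ROIs averaging 1393, 1427, 78, 110 and 130 pixels.
`dualpet` generates them procedurally: a head-like ellipse, an outer cortical band
(ROI 1) and inner core (ROI 2) fitted iteratively to target pixel counts,
and up to three small elliptical lesions (ROIs 3–5) embedded in the core.
Target counts are drawn uniformly within ±30% of the means (slightly
shrunken so pixel discretisation cannot leave the range), so a seed ensemble
reproduces the average ROI sizes. The phantoms reproduce ROI count/size
statistics only — no anatomical realism is claimed, and results on them do
not transfer to anatomically structured images.

## Acquisition

The projector is an idealized 2-D parallel-beam Radon transform over 180°
(default 128 radial bins × 160 angles) built as an explicit sparse matrix,
pixel-driven with linear bin interpolation. Consequences: the adjoint is the
exact transpose (used by EM reconstruction and asserted to 1e−6), per-angle
bin sums conserve image mass, and no attenuation, arc correction, detector
blur or scanner-specific geometry is modelled.

Randoms are added as a spatially uniform per-frame background totalling 20%
of the clean counts (uniformity is the weakest assumption consistent with "a
20% randoms fraction"), then Poisson noise is drawn. The dual sinogram
receives its own Poisson realisation of the summed clean expectation by
default; summing two noisy single-tracer sinograms instead is available via
`make_group(..., sum_noisy_singles=True)` since either reading is defensible.
The global count level is calibrated so a standard-dose dual sinogram totals
~1e7 events at full scale. Low-dose data are produced by binomial thinning,
which preserves the Poisson character exactly.

Per group, sinograms are normalised by `max(S_dual)/3` and images by
`max(S_dual)/150` (both derived from the dual sinogram, ratio exactly 50),
with the factors stored for inversion.

## Classic reconstruction

FBP uses the band-limited (Kak–Slaney) discrete ramp — its DC response is
slightly positive, avoiding the cupping of a naive |f| ramp — with optional
Hann apodisation, zero-padding to the next power of two ≥ 2×bins, and the
matched transpose back-projector scaled by π/(2·n_angles). MLEM uses the
standard multiplicative update (uniform positive start, 50 iterations
default); OSEM interleaves angle subsets by stride (6 iterations × 5 subsets
default) and reduces exactly to MLEM for one subset.

## Networks

Built on `dualpet.nn`, a small numpy reverse-mode autodiff engine written
for this package (convolution, batch normalisation, linear, pooling, a
learnable frequency-domain filter layer, a fixed sparse back-projection
layer, and a differentiable Gaussian-weighted SSIM). Every primitive's
gradient is finite-difference checked in the tests.

* **FBPNet**: learnable filter on the radial-frequency axis (initialised to
  the ramp, shared across angles and frames) → fixed back-projection (no
  trainable parameters) → residual CNN denoiser (two hidden conv blocks +
  skip, ReLU output). With the denoiser zeroed and the output rectifier off
  it reproduces classic FBP to float precision.
* **SeparationNet**: two 3×3 conv blocks → Inception-like module with global
  H×1 and 1×W kernels (concatenated) → 3×3 conv block to 2C channels →
  channel attention → 3×3 conv block → 3×3 output conv → split into two
  C-channel dynamic images.
* **Channel attention**: global max- and average-pooled descriptors through
  a *shared* two-layer FC stack of width 2C (no bottleneck), summed, then a
  sigmoid; the weights multiply channels. The shared-stack/sum wiring is the
  dominant convention for this attention family (the SE/CBAM lineage), and
  the one assumed here.
* **Variants**: `fbpnet_sep` = FBPNet → SeparationNet on images;
  `sep_fbpnet` = SeparationNet on sinograms → one weight-shared FBPNet per
  separated sinogram; `fbpnet_dc_sep` = FBPNet → three branches
  {uncorrected, decay-corrected as tracer 1, decay-corrected as tracer 2}
  through per-branch conv+Inception stems, merged by concatenation + 1×1
  conv, then attention and the shared head.

**Channel widths.** Only the total parameter budgets of the two models are
fixed (0.64 M and 0.66 M); the canonical width config (conv1 32, conv2 25,
inception 25, denoiser 183) was solved from the parameter-count formula so
the assembled models carry 641,255 (→ 0.64 M) and 661,255 (→ 0.66 M)
trainable scalars. The 20,000
parameter difference between the two variants is exactly the extra 32 angles
seen by the sinogram-domain 1×W branch (32 × 25 × 25), which is also how the
width 25 was identified.

## Training

Per-output loss `L = β·MSE + (1−β)·[1 − SSIM]`; total loss
`λ_FBP·L_FBP + λ_Sep·L_Sep`. Image-domain variants: β_FBP = 0.5,
β_Sep = 0.95, λ_FBP = 1, λ_Sep = 10 (L_FBP on the dual reconstruction, L_Sep
on the two images). Sinogram-domain variant: β_Sep = 0.99, λ_Sep = 1 (L_Sep
on the separated sinograms, L_FBP on the two images). SSIM inside the loss
uses an 11-tap Gaussian window (σ = 1.5), population covariance, a 5-pixel
border crop, and the label volume's dynamic range — numerically identical to
the scikit-image reference configuration, computed per frame and averaged.

Schedule: FBPNet pretrained on (S_dual → I_dual) — for the sinogram-domain
variant, on single-tracer pairs — then the separation network pretrained on
noise-free labels (decoupling the phases), then joint fine-tuning from the
pretrained weights with the total loss. Adam, no weight decay, no schedule,
no early stopping. Datasets are split 10:1 by physiological parameter set
(all phantom slices on both sides, no parameter set on both), and the
decay-correction variant's training set is augmented with tracer-swapped
copies (swapping leaves S_dual unchanged).

## Scale presets and what the smoke tests show

Full-scale training (128×128×26, 800 groups, 300+100+100 epochs) is far
beyond a single-CPU test run, so the package defines presets:

| preset  | grid | angles | frames | groups | epochs     | lr   |
|---------|------|--------|--------|--------|------------|------|
| full    | 128  | 160    | 26     | 880    | 300/100/100| 1e-4 |
| reduced | 32   | 60     | 13     | 50     | 10/10/20   | 1e-3 |
| tiny    | 32   | 60     | 6      | 6      | 2/2/3      | 1e-3 |

The reduced/tiny presets raise the Adam learning rate to 1e−3: the
full-scale rate of 1e−4 is tied to a ~1e5-step schedule, and with ~300 steps the same rate
cannot move the output layers across the data's 0–150 dynamic range. At
reduced scale the suite verifies *mechanisms*, not headline numbers: joint
fine-tuning cuts the validation separation loss by well over 30%, the
separated outputs beat the trivial predictor Î1 = Î2 = Î_dual/2 (half of the
model's own reconstruction) on SSIM for both tracers, and SSIM degrades
monotonically across the 1, 1/2, 1/3, 1/5 dose series. Full-scale accuracy
figures (SSIM approaching 0.998 and the like) additionally require
anatomically structured phantoms, tracer-specific kinetic libraries and
GPU-scale training; they are out of reach of, and not claimed by, the
desk-scale presets.

## Tracer library

`src/dualpet/data/tracers.yaml` ships five tracers (FDG, FMZ, MET, AV45,
FLT) with their physical half-lives and kinetic types, the published FDG
input function, and literature-plausible per-ROI rate constants (shipped as
configuration, not code, so they can be replaced by study-specific values).
Non-FDG input functions reuse the tri-exponential form with tracer-specific
parameters. For the reversible tracers the rate constants were chosen so the
slow eigenmode time constant is ~15 min: Logan graphical analysis assumes
quasi-equilibrium within the scan, and kinetics with, say, a 49-min time
constant carry an intrinsic ~20% negative VT bias over a 60-min protocol no
matter how the estimator is implemented. Parameter-set randomisation applies
independent Gaussians with sd = 10% of each mean, redrawn on sign flips.

## Kinetic quantification

ROI TACs are frame-wise means over ROI pixels, decay-corrected
(`×2^(+t_mid/T)`) before graphical analysis. Patlak: slope of `C_T/C_P` vs
`∫C_P/C_P` estimates Ki = K1·k3/(k2+k3) (irreversible tracers). Logan: slope
of `∫C_T/C_T` vs `∫C_P/C_T` estimates VT = (K1/k2)(1+k3/k4) (reversible
tracers). Integrals are trapezoids on frame midpoints anchored at zero; fits
use the last 10 frames. On noise-free TACs both recover the analytic values
within 5% (Patlak ~1%, Logan ~1.5% with the shipped kinetics).

TAC bias is reported as the mean absolute relative deviation over frames and
samples (frames whose label falls below 0.1% of the TAC peak excluded);
variation as the across-ROI-pixel standard deviation divided by the label
ROI mean. Bias/variation summaries of this kind are often reported without
a formula; the definitions here are explicit so the numbers are
reproducible.

## Known limitations

- 2-D, attenuation-free, scatter-free, idealized parallel-beam geometry.
- Procedural phantoms: ROI statistics only; no anatomy. No cross-phantom
  generalisation is claimed — separation networks of this kind are known
  not to transfer across phantom families.
- No blood-volume fraction or metabolite correction in the kinetics.
- The numpy training stack is single-threaded CPU code: correct and
  deterministic, but not performant at full scale.
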