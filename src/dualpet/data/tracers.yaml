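# Default tracer library.
#
# The 18F-FDG input-function parameters are the published human arterial
# values; the remaining tracers reuse the same tri-exponential functional
# form with literature-plausible parameters, and the per-ROI two-tissue
# rate constants are representative values for each tracer class
# (configuration, not code: edit freely).
#
# Units: half_life min; A1 uCi/mL/min; A2, A3 uCi/mL; lam* 1/min; K1..k4 1/min.
tracers:
  fdg:
    name: 18F-FDG
    half_life: 109.8
    kinetic_type: irreversible
    input_fn: {A1: 851.1, A2: 21.88, A3: 20.81, lam1: -4.134, lam2: -0.1191, lam3: -0.01043}
    roi_kinetics:
      1: {K1: 0.102, k2: 0.130, k3: 0.062, k4: 0.0068}
      2: {K1: 0.054, k2: 0.109, k3: 0.045, k4: 0.0058}
      3: {K1: 0.134, k2: 0.145, k3: 0.078, k4: 0.0080}
      4: {K1: 0.095, k2: 0.125, k3: 0.058, k4: 0.0060}
      5: {K1: 0.072, k2: 0.118, k3: 0.051, k4: 0.0055}
  fmz:
    name: 11C-FMZ
    half_life: 20.4
    kinetic_type: reversible
    input_fn: {A1: 700.0, A2: 18.0, A3: 15.0, lam1: -4.5, lam2: -0.25, lam3: -0.012}
    roi_kinetics:
      # clearance fast enough that the Logan plot linearises within a
      # 60-min scan (slow-eigenmode time constant ~15 min)
      1: {K1: 0.340, k2: 0.380, k3: 0.080, k4: 0.090}
      2: {K1: 0.190, k2: 0.340, k3: 0.060, k4: 0.080}
      3: {K1: 0.300, k2: 0.360, k3: 0.070, k4: 0.085}
      4: {K1: 0.260, k2: 0.370, k3: 0.065, k4: 0.080}
      5: {K1: 0.220, k2: 0.350, k3: 0.060, k4: 0.085}
  met:
    name: 11C-MET
    half_life: 20.4
    kinetic_type: irreversible
    input_fn: {A1: 600.0, A2: 25.0, A3: 12.0, lam1: -3.8, lam2: -0.15, lam3: -0.015}
    roi_kinetics:
      1: {K1: 0.095, k2: 0.150, k3: 0.050, k4: 0.004}
      2: {K1: 0.060, k2: 0.120, k3: 0.038, k4: 0.003}
      3: {K1: 0.120, k2: 0.160, k3: 0.065, k4: 0.005}
      4: {K1: 0.085, k2: 0.140, k3: 0.048, k4: 0.004}
      5: {K1: 0.075, k2: 0.130, k3: 0.042, k4: 0.003}
  av45:
    name: 18F-AV45
    half_life: 109.8
    kinetic_type: reversible
    input_fn: {A1: 750.0, A2: 20.0, A3: 10.0, lam1: -4.0, lam2: -0.2, lam3: -0.02}
    roi_kinetics:
      1: {K1: 0.230, k2: 0.340, k3: 0.060, k4: 0.075}
      2: {K1: 0.160, k2: 0.300, k3: 0.055, k4: 0.070}
      3: {K1: 0.210, k2: 0.320, k3: 0.060, k4: 0.072}
      4: {K1: 0.190, k2: 0.330, k3: 0.050, k4: 0.068}
      5: {K1: 0.175, k2: 0.310, k3: 0.055, k4: 0.070}
  flt:
    name: 18F-FLT
    half_life: 109.8
    kinetic_type: irreversible
    input_fn: {A1: 500.0, A2: 15.0, A3: 10.0, lam1: -3.5, lam2: -0.12, lam3: -0.009}
    roi_kinetics:
      1: {K1: 0.110, k2: 0.190, k3: 0.062, k4: 0.005}
      2: {K1: 0.070, k2: 0.160, k3: 0.045, k4: 0.004}
      3: {K1: 0.140, k2: 0.210, k3: 0.080, k4: 0.006}
      4: {K1: 0.100, k2: 0.180, k3: 0.055, k4: 0.005}
      5: {K1: 0.085, k2: 0.170, k3: 0.050, k4: 0.004}
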