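# Methods

## Model and procedure

The pulmonary blood volume follows the indicator-dilution identity
`PBV = V_stroke / RR · PTT`: the stroke volume is ejected once per RR
interval, so the lung holds `PTT / RR` stroke volumes of blood. The three
inputs come from two acquisitions — cine imaging of the left ventricle
for `V_stroke`, and a fast dynamic tracer series for `PTT` and `RR`.

### Arrival times and PTT

Per voxel, the signal-time curve is smoothed with a Savitzky–Golay
filter (150 ms window, order 2) and the wash-in is fitted with the
four-parameter sigmoid

```
signal(t) = D + (A − D) / (1 + (t/C)^B),   t > 0
```

with `A` (baseline) and `D` (plateau) held fixed and only the steepness
`B` and inflection abscissa `C` optimized by trust-region nonlinear least
squares. The arrival time is the intersection of the tangent at the
inflection point with the baseline level, which has the closed form
`t0 = C (1 − 2/B)`; its standard deviation follows by first-order
propagation of the (B, C) covariance through the gradient
`(2C/B², 1 − 2/B)`, covariance term included. For `B ≤ 2` the
construction yields `t0 ≤ 0` and the estimate is flagged unstable.

Estimator choices where the procedure leaves a gap:

* `A` is the mean of the smoothed pre-bolus window (default 400 ms,
  covering ≈18 frames).
* `D` is the *plateau mean* — the average of smoothed samples within 2%
  of the smoothed maximum — rather than the maximum itself. The maximum
  of a noisy record is selection-biased upward; with the plateau mean the
  Monte-Carlo bias of the recovered transit time drops from ≈ −0.7 ms to
  ≈ −0.3 ms (400 phantom seeds, noise sd 1% of the RV peak), making the
  estimator unbiased at the resolution of the method.
* The fit window runs from the first positive sample time to the
  smoothed peak: the model is monotone and represents only the wash-in.
* Initialization `B₀ = 5`, `C₀` at the half-height crossing; bounds
  `B ∈ (0, 100]`, `C` inside the fit window.

The PTT is the difference of mean arrival times over the RV and LV ROIs
(1 mm² in-plane, centered on the voxel with the maximal smoothed peak
signal; ties resolved by scan order, x fastest). Its *maximal error
limit* adds linearly the arrival-time spread across each ROI and the
mean fit-derived standard deviation; single-voxel ROIs contribute only
the latter. At 1 mm resolution the standardized 1 mm² ROI is a single
voxel; the extent is configurable because larger ROIs trade arrival
spread for noise averaging.

### RR interval

The tracer signal in the LV is amplitude-modulated at the heart rate.
The curve is detrended by subtracting its own 150 ms Savitzky–Golay
smoothing (which passes ≈70% of a 7.5 Hz carrier into the residual while
removing the bolus trend), Hann-tapered over the post-arrival window,
and zero-padded to a spectral bin width ≤ 0.05 Hz. The RR is
`1000 / f_peak` for the maximal in-band magnitude (default band 4–15 Hz,
the physiological range of the anesthetized mouse), with the peak
refined by quadratic interpolation of the log-magnitudes around the
argmax bin — without the refinement the bin quantization alone (≈0.045
Hz) is the dominant RR error. A peak is only accepted if it exceeds 12×
the median in-band magnitude; pure white noise reaches peak/median
ratios of about 10, so smaller peaks are indistinguishable from the
noise floor and are reported as an error rather than an RR. Ties among
equal maxima resolve to the lowest frequency for determinism.

The cine-derived RR is simply the phase count between two successive
maximal contractions times the phase interval (5 ms).

### Volumetry

Ventricular volumes are Simpson-style sums: lumen contour areas
(shoelace formula on the ordered vertices, scaled by the squared pixel
spacing; self-intersecting polygons rejected via a geometric validity
check) summed over short-axis slices and multiplied by the slice
thickness, so mm² × mm = µl. Identification of the diastolic and
systolic phases is observer input, not an algorithm; the cine phantom
supplies its truth phases.

### Error budget

The reported uncertainty is a worst-case linear ("maximal error") sum,
not a quadrature sum:

```
ΔPBV = PTT/RR·(ΔV_dia + ΔV_sys)  +  V_stroke/RR·ΔPTT  +  V_stroke/RR·PTT·ΔRR_rel
```

with ΔV taken as 5% of the mean volumes and ΔRR as a relative 3% (the
units of the printed identity only balance with a relative RR error;
this reproduces the budget decomposition exactly). The fit-derived
arrival-time uncertainty uses delta-method (quadrature) propagation
internally; the budget combines the resulting ΔPTT linearly, consistent
with the maximal-error convention.

## Synthetic data

The phantom generator emulates the first-pass signal structure of a
sub-second bolus at 21.5 ms frames on a 24×24×12 grid of 1 mm³ voxels:

* Region curves are **gamma-variates**
  `y = peak · x^α e^{α(1−x)}, x = (t − arrival)/t_p`, the standard
  indicator-dilution shape, parameterized by (arrival, FWHM, peak); the
  time-to-peak is solved numerically from the FWHM via the
  shape-dependent width factor.
* Shape `α = 1` (sharp, near-linear wash-in foot). This is a deliberate
  choice: the tangent-at-inflection construction locates a sharp foot to
  sub-millisecond accuracy, while flatter feet (α = 2, 3) displace the
  tangent arrival by 40–90 ms from the true onset at 578 ms FWHM. Since
  the phantom's purpose is ground-truth recovery at one-frame
  resolution, the foot must be sharp — matching the deliberately sharp
  experimental bolus (1 µl in under one second).
* The **LV curve is a gamma-variate of the same family** with the
  configured wider FWHM (1042 ms), exact arrival `rv_arrival + PTT` and
  58% of the RV peak. An earlier design dispersed the RV kernel by
  convolution with a positive-support transport kernel; any kernel wide
  enough to broaden 578 → 1042 ms delays the visible wash-in foot by its
  bulk mean (~+390 ms in the tangent arrival), which makes the
  first-nonzero "truth" unrecoverable by the very method under test.
  Parameterizing the arrival directly keeps truth exact by construction.
* The lung curve interpolates delay, width and amplitude between the
  ventricles (defaults: 45% of the transit delay, 40% amplitude).
* **Cardiac modulation** is an additive sinusoid at `1000/RR` Hz, gated
  to the post-arrival window of the LV curve, at 1% of the LV peak by
  default. The depth is bounded above by an internal consistency
  requirement: the 150 ms smoother passes part of a 7.5 Hz ripple, and
  residual ripple on the shallow LV down-flank displaces the
  half-maximum crossing (≈ −8/−14/−19 ms at depth 0.01/0.02/0.03); at
  0.01 the smoothed FWHM stays within half a frame of the configured
  value while the spectral peak remains orders of magnitude above the
  floor on noiseless data.
* Noise is additive Gaussian, independent per voxel; every output is a
  pure function of (config, seed).

The cine phantom produces 64-vertex polygonal ellipse contours per slice
and phase, with lumen areas oscillating between the systolic and
diastolic envelopes at the configured RR (135 ms by default, an integer
number of 5 ms phases). Default semi-axis profiles taper
ellipsoid-like from base to apex and are scaled so the summed diastolic
and systolic volumes are ≈45.2 µl and ≈13.5 µl. Truth volumes are
analytic (`Σ πab·thickness` at the truth phases), so the ~0.1% polygonal
approximation error appears only in the measured areas.

What the phantoms do **not** emulate: recirculation and wash-out
overlap, partial-volume mixtures at chamber boundaries, motion,
spatially correlated reconstruction noise, and modulation waveforms more
complex than a sinusoid. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated signal model, not
robustness to every in-vivo artifact.

## Numerical choices and degenerate inputs

* Times are ms, volumes µl, coordinates 0-based with x fastest;
  intervals half-open. The first frame sits at one frame interval so the
  sigmoid's `t > 0` domain is always respected.
* Savitzky–Golay windows are converted to the nearest odd frame count
  (minimum 3; 150 ms → 7 frames at 21.5 ms) with mirror padding at the
  record edges.
* FWHM crossings are linearly interpolated between bracketing samples;
  the left crossing is the first up-crossing and the right crossing the
  last down-crossing in the record, which tolerates ripple around the
  half level. Unresolvable flanks raise an explicit error.
* Degenerate fits: zero contrast (`A = D`) raises a low-contrast error;
  non-convergence raises; `B ≤ 2` flags the arrival unstable. Voxelwise
  mapping skips failed voxels instead of aborting, excluding them from
  the quality mask.
* A nonpositive PTT (LV not lagging RV) is nonphysiological and raises.
* The covariance of (B, C) is the Jacobian-based estimate
  `s²(JᵀJ)⁻¹` at the optimum, symmetrized; a singular `JᵀJ` falls back
  to the pseudoinverse.

## Problem sizes

The default phantom (24×24×12×256, three box-shaped region masks) and
all Monte-Carlo checks (50 seeds for fit-bias tests) run in seconds on a
single CPU; the full test suite completes in well under a minute. These
sizes were chosen to match the study conditions (grid, frame interval)
while keeping every recovery experiment cheap to repeat.

## Known limitations

* The sigmoid wash-in model cannot represent wash-out; the fit window
  must end at the peak, and arrival estimates degrade if recirculation
  contaminates the wash-in.
* With the default 1% modulation depth, the spectral RR becomes
  undetectable once voxel noise approaches the modulation amplitude
  (~0.6 signal units); the estimator then raises rather than guessing.
* The tangent-arrival construction is exact for sharp-footed boli but
  systematically late for strongly dispersed ones; comparisons across
  chambers partially cancel this, which is why PTT is more accurate than
  either absolute arrival.
* The error budget is a worst-case bound, not a confidence interval;
  it is deliberately conservative.
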