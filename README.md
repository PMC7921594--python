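# bolustrack

First-pass bolus arrival-time analysis and pulmonary blood volume (PBV)
estimation for dynamic small-animal tracer imaging.

## The problem

The blood contained in the pulmonary circulation — arteries, capillaries
and veins of the lung — is a hemodynamic parameter of interest in mouse
models of cardiac and pulmonary disease, but it cannot be measured
directly in vivo. It can, however, be computed from three measurable
quantities by the classical indicator-dilution identity

```
PBV = V_stroke / RR · PTT
```

where `V_stroke = V_diastole − V_systole` is the left-ventricular stroke
volume from short-axis cine volumetry, `RR` is the length of one cardiac
cycle, and `PTT` is the pulmonary transit time: the time a tracer bolus
needs to travel from the right ventricle (RV) through the lungs to the
left ventricle (LV). Each heartbeat ejects one stroke volume, so the
blood volume of the lung is the stroke volume times the number of beats
elapsed during the transit.

`bolustrack` implements the analysis chain for a fast dynamic 3D
acquisition (~21.5 ms per volume, ~1 mm³ voxels) of a sub-second tracer
bolus in the mouse:

* **Savitzky–Golay temporal smoothing** (150 ms window) of voxel
  signal-time curves to average out cardiac pulsation, and **FWHM
  characterization** of the bolus profile;
* **arrival-time estimation** by fitting the sigmoid wash-in model
  `signal(t) = D + (A − D)/(1 + (t/C)^B)` with baseline `A` and plateau
  `D` fixed, and intersecting the tangent at the inflection point with
  the baseline level: `t0 = C·(1 − 2/B)`, with uncertainty from the
  (B, C) covariance;
* **PTT** as the difference of mean arrival times of standardized 1 mm²
  ROIs placed on the maximal signals in the two ventricles;
* **RR estimation** from the dominant spectral peak of the cardiac
  modulation of the LV tracer signal (and independently from cine phase
  counting);
* **cine volumetry** by summing contoured lumen areas over short-axis
  slices times the slice thickness;
* a **maximal-error budget**: the worst-case linear sum
  `ΔPBV = PTT/RR·(ΔV_dia + ΔV_sys) + V_stroke/RR·ΔPTT + V_stroke/RR·PTT·ΔRR`;
* a **synthetic-data module** that generates 4D first-pass phantoms
  (gamma-variate boli with known arrival times, cardiac modulation,
  noise) and cine contour studies with exact ground truth, so the whole
  chain is testable without any acquisition.

## Worked example

Simulate a phantom with the default study conditions (PTT 745 ms, RR
133 ms, RV/LV bolus FWHM 578/1042 ms, 24×24×12 grid at 21.5 ms frames),
analyze it, and print the report:

```sh
bolustrack simulate --seed 1 --output-dir demo
bolustrack analyze --config demo/config.json --output demo/report.json
bolustrack report demo/report.json
```

```
PTT               744.2 ms (± 2.5 ms max error)
RR (tracer)       133.0 ms
RR (cine)         135.0 ms
V_diastole         45.0 µl
V_systole          13.5 µl
V_stroke           31.5 µl
EF                 70.0 %
PBV               176.3 µl
max error budget: stroke 16.4 + transit 0.6 + RR 5.3 = 22.2 µl (13%)
```

The recovered transit time (744.2 ms) is within one frame interval of
the phantom's true 745 ms, the tracer-derived RR matches the generated
133 ms cardiac modulation, and the volumetry reproduces the true cine
phantom volumes to the polygonal contour approximation (~0.2%). The PBV
of 176.3 µl then follows from the identity above, and the error budget
shows the volumetric terms dominating the worst-case uncertainty.

The same stages are available as a library (`bolustrack.synthetic`,
`bolustrack.timecurve`, `bolustrack.arrival`, `bolustrack.cardiac`,
`bolustrack.hemodynamics`, `bolustrack.pipeline`) — see
`docs/methods.md` for the model details and design choices.

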