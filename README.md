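# respigate

Respiratory self-gated, free-breathing 3D radial cardiac MRI as a tested,
simulation-backed pipeline.

During free breathing the left-ventricular (LV) end-diastolic volume varies
with intrathoracic pressure: the septum shifts toward the LV at
mid-inspiration (minimum pressure, minimum LV size) and away from it at
mid-expiration (maximum pressure, maximum LV size). Measuring that variation
requires sorting a continuously acquired 3D radial acquisition into
cardiac-phase x respiratory-phase bins — which in turn requires a reliable
respiratory signal derived from the data itself. `respigate` implements and
contrasts the two self-gating strategies used for this problem:

* **projection-based gating** — a superior–inferior (SI) navigator spoke
  acquired every 25th TR is Fourier-transformed into a head–foot projection;
  coil-wise PCA, LOWESS smoothing, spectral-clustering combination and
  polynomial detrending yield a signal *proportional to respiratory
  amplitude*, so mid-inspiration/mid-expiration anchors can be placed at the
  true half-amplitude points of every individual cycle;
* **k-space-center gating** — the k = 0 sample of every imaging spoke,
  combined against a reference spoke and band-pass filtered, yields a
  *phase-only* signal; anchors must sit at fixed cycle fractions (28% / 88%)
  and the fixed pass band makes the cycle division fragile when the
  respiratory rate drifts.

The package covers the whole chain for studying this contrast on known
ground truth:

1. **Trajectory** — double golden-angle 3D radial spoke tables,
   `alpha = 2*pi*frac(m*phi2)`, `beta = arccos(frac(m*phi1))`, with the
   conventional golden means `(0.4656, 0.6823)` (mean consecutive-spoke
   angle ~92°) and the small-increment pair `(0.0102, 0.0219)` (~7°, for
   eddy-current suppression), SI-navigator interleaving, radial-Nyquist and
   acceleration arithmetic.
2. **Phantom simulator** — an analytic breathing, beating torso (uniform
   ellipsoids with closed-form Fourier transforms, band-limited complex coil
   sensitivities, complex Gaussian noise) with per-cycle ground truth:
   quasi-periodic `sin^4` respiration, a diaphragm that translates with lung
   volume, and an LV septal–lateral axis driven by an airflow-based pressure
   surrogate so that the programmed diameter contrast appears exactly
   between the two anchor states.
3. **Binning** — Hilbert-phase cycle division at 2π wraps, amplitude or
   fixed-fraction anchors, 15%-of-cycle respiratory windows, 70–82.5% RR
   end-diastolic window.
4. **Reconstruction** — Kaiser–Bessel gridding NUFFT (adjoint-exact),
   Ram-Lak and Pipe–Menon density compensation, adaptive (Walsh) coil maps,
   CG-SENSE with 4 iterations, lossless k-space-rotation reformatting,
   complex thick-slab summation.
5. **Metrics** — NAAD image uniformity `1 - sum|s_i - mu|/(mu N)`, blood-pool
   segmentation, sub-voxel LV diameters, Simpson volumes, respiratory
   variation `100 (v_max - v_min)/v_max`.

## Worked example

Trajectory statistics from the command line:

```bash
$ respigate trajectory --phi1 0.4656 --phi2 0.6823 --n-spokes 20000 --si-every 0 --no-include-si
{ "mean_deg": 92, "sd_deg": 14, ... }
```

A complete simulate → gate → bin → reconstruct → measure run (90 s of
breathing, 36,000 spokes, 32³ grid at 6 mm — desk-scale settings):

```python
from respigate import run_pipeline

report = run_pipeline({
    "trajectory": {"n_spokes_total": 36_000, "si_every": 25,
                   "matrix": 32, "n_readout": 32, "voxel_mm": 6.0},
    "phantom": {"duration": 90.0, "seed": 17},
    "recon": {"n_iter": 4, "sens_spokes": 5_000},
})
for method, entry in report["methods"].items():
    print(method,
          round(entry["mid_inspiration"]["septal_lateral_mm"], 1),
          round(entry["mid_expiration"]["septal_lateral_mm"], 1),
          round(entry["respiratory_variation_septal_lateral_pct"], 1))
```

prints (phantom programmed with a 10% septal–lateral variation):

```
projection 49.8 54.7 9.0
kspace 54.1 51.1 5.5
```

Projection gating recovers the programmed contrast with the correct
ordering (mid-inspiration smaller). The k-space method here *reverses* the
two phases (its phase-only signal has no amplitude or polarity anchor) and
under-recovers the contrast — the failure mode that motivates the
projection method. Each bin entry also reports spoke counts, the
acceleration factor relative to radial Nyquist, NAAD, and LV volume in ml.

The same stages are exposed as subcommands (`respigate simulate`, `gate`,
`run`, ...) operating on a self-contained HDF5 acquisition container.

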