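# Methods

This note records the models, conventions and numerical choices behind
`respigate`, and what the synthetic experiments do and do not demonstrate.

## Trajectory

Spoke `m` points along `(sin b cos a, sin b sin a, cos b)` with
`a = 2*pi*frac(m*phi_azimuth)` and `b = arccos(frac(m*phi_polar))`; the polar
fraction is uniform on [0, 1), so directions cover the +z hemisphere
uniformly and the full-diameter readouts cover the sphere. In both supported
golden-mean pairs — conventional `(0.4656, 0.6823)` and small-increment
`(0.0102, 0.0219)` — the *smaller* mean drives the polar angle. The pairs
are sometimes quoted in the opposite order; the assignment used here is the
one validated by the consecutive-angle statistics it produces (92.2 ± 13.5°
and 7.1 ± 8.0° over 250,000 spokes, directed-ray convention; with the
every-25th SI navigator interleaved, 89.4 ± 17.2° and 11.2 ± 16.8°).

Conventions that matter:

* **Directed rays.** The angle between consecutive spokes is
  `arccos(u_i . u_{i+1})` without folding at 90°; an undirected convention
  would cap the conventional-pair mean at 90° instead of the observed ~92°.
* **Population SD**, integer-degree reporting.
* **Golden index advances over imaging spokes only**; the navigator does not
  consume a golden step, so the imaging trajectory is identical with and
  without gating. (The SI-inclusive statistics differ by < 0.02° between
  this and the every-TR convention, so the choice is not observable there.)
* **frac() in exact rational arithmetic** when the golden mean has a short
  decimal form, so `frac(10^6 * 0.0219)` is exactly 0; otherwise 80-bit
  extended precision (error < 1e-13 for m up to a few million).
* **Readout samples** at `k = (i - n//2)/n` cycles/voxel: full diameter,
  exactly one sample at k = 0 (the k-space-center gating method depends on
  it). Timing: one spoke per TR (2.5 ms default), navigator every 25th TR =
  every 62.5 ms (16 Hz); a sometimes-quoted 64 ms/15.7 Hz figure is
  inconsistent with 25 x 2.5 ms and is not used.
* **Radial Nyquist** `round(pi/2 * N^2)` full-diameter spokes at matrix N.

## Phantom simulator

Five axis-aligned uniform ellipsoids: chest-wall shell (intensity 0.30
outside the thorax interior), lung-dark interior (0.05), liver (0.20),
myocardium (0.20) and LV blood pool (0.70). The intensities are chosen
bSSFP-like (bright blood, intermediate muscle/fat, dark lungs) and so that a
threshold at half the blood-pool intensity isolates the LV cavity from the
liver, myocardium and chest wall. Geometry fits a 192 mm field of view.

**Respiration** is a concatenation of cycles with durations
~ Normal(4 s, 0.6 s) truncated above 0.5 s (optionally with a linear drift
of the mean period, for the rate-drift experiments) and amplitudes
~ Normal(12 mm, 3.6 mm) truncated positive. Each cycle has shape
`s(u) = A sin^4(pi u)`: fast inspiration, slower expiration, and a long
end-expiratory dwell. This asymmetry is deliberate — with it, the true
half-amplitude anchors sit at 31.8% / 68.2% of the cycle while fixed-phase
anchors sit at 28% / 88%, so amplitude- and phase-based anchoring are
measurably different strategies. The diaphragm (liver edge) translates
footward by `s(t)`.

**LV septal-lateral drive.** At both half-amplitude anchors the instantaneous
lung volume is the same (`s = A/2`), so an LV size tied to displacement
would show no anchor-to-anchor contrast at all. Physiologically the LV
follows intrathoracic *pressure*, whose extremes occur near peak
inspiratory/expiratory flow. The simulator therefore drives the
septal-lateral blood-pool semi-axis with the per-cycle-normalized airflow
`h(u) = sin^3(pi u) cos(pi u) / (3*sqrt(3)/16)` in [-1, 1]:
`a_sl = 26 mm * (1 - f * (1 + h)/2)` with `f = septal_shift_fraction`
(default 0.10). The mid-inspiration/mid-expiration diameter ratio is then
`(1 - f)` up to the ~0.8% difference between the anchor fractions and the
flow extrema. `phantom_state` called directly defaults to the simpler
displacement-linked drive (end-expiration/end-inspiration ratio
`1/(1 - f)`), which is convenient for static geometry checks.

**Cardiac cycling**: R-peaks from a jittered RR process (1 ± 0.05 s); the
blood pool contracts by up to 22% in radius around phase 0.35 and is
essentially at rest in the end-diastolic window (0.70–0.825).

**k-space** is exact: each uniform ellipsoid contributes
`amp * V * 3(sin x - x cos x)/x^3` at `x = 2*pi*|diag(a,b,c) k|` with a
phase ramp for its center; motion is frozen within a spoke (TR 2.5 ms is far
below all motion time scales). Coil sensitivities are band-limited
plane-wave series (27 lowest frequencies of a 384 mm period) obtained by
trigonometric interpolation of Gaussian profiles on a ring; each plane wave
shifts the ellipsoid transform in k-space, so coil weighting stays exact,
and the same series is the ground-truth map for scoring estimation. Complex
Gaussian noise (default SD 2e-4 of the object DC) is added per sample. All
randomness flows from one seeded generator in a fixed draw order
(respiratory cycles, RR, coil model, then noise in fixed 4096-spoke chunks),
making acquisitions bitwise reproducible. The simulator hot path evaluates
the kernel in float32 (relative error ~1e-6, far below the noise floor);
`analytic_kspace` keeps float64 for oracle use.

The bellows channel is the true waveform delayed by 0.3 s and low-passed at
0.8 Hz — the delay is a free simulator parameter mimicking the phase shift
of an abdominal belt, not a measured value.

## Self-gating

**Projection method** (amplitude-bearing): magnitude 1D projections of the
SI navigators per coil (phase discarded — robust to bSSFP phase); coil-wise
PCA over (time x position) with per-position mean removal, two components
per coil; LOWESS with a 6-sample window (0.375 s at 16 Hz — well below
respiratory periods), local linear, tricube weights, no robustness
iterations; spectral clustering (2 clusters, |Pearson r| affinity) of all
components, keeping the cluster with the higher product of internal
coherence and 0.1–0.5 Hz band-power fraction, sign-aligned to its medoid and
averaged after z-scoring; BIC-selected polynomial detrend (order 2–4,
manual override available). Polarity is fixed so inspiration is positive,
by anti-correlating with the projection centroid track (bright abdominal
mass moves footward on inspiration); the centroid is smoothed over ~1 s so
cardiac mass redistribution cannot flip the sign.

**k-space method** (phase-only): k = 0 sample per imaging spoke and coil;
`Re <v_ref, v(t)>` against the first imaging spoke (magnitude optional);
linear resampling to a uniform 16 Hz base; zero-phase 4th-order Butterworth
band-pass, default 0.1–0.5 Hz. The band is deliberately fixed per run: a
drifting respiratory rate against a fixed band is precisely the fragility
this method exhibits, and the simulator reproduces both failure modes —
cycle misdivision under rate drift, and per-cycle signal amplitude
essentially uncorrelated with breathing depth (|r| < 0.5) under phase-stable
amplitude-varying breathing.

## Binning

Cycle boundaries at the -pi -> pi wraps of the Hilbert-transform phase
(boundaries = end-expiration), linearly interpolated between samples; cycles
outside 1–15 s are discarded as gating failures. Amplitude anchors search
the cycle-start/end minima over the first/last 25% of the cycle and place
the anchor at the first half-amplitude crossing of the rising/falling limb
(linear interpolation); phase anchors sit at 28% / 88% of the cycle.
Respiratory windows are closed intervals of 15% of *that cycle's* duration
centered on each anchor (overlaps resolved to the nearer anchor); the
cardiac window is half-open [70%, 82.5%) of the enclosing RR interval.
Navigator spokes are never reconstructed.

## Reconstruction

Kaiser–Bessel convolution gridding with Beatty's kernel shape parameter and
quadrature-exact deapodization. Two operating points:

* standalone NUFFT / adjoint gridding: width 7 at 2.0x oversampling —
  worst-case forward error vs the direct non-uniform DFT measured below
  1e-6 on <= 16^3 instances;
* CG-SENSE system operator: width 4 at 1.5x oversampling — the iterative
  solve is insensitive to the kernel's aliasing floor and this is ~3x
  faster.

Density compensation: analytic radial cell volumes (`2*pi*k^2*dk` per sample
and the zero-radius spherical cell for the center), optionally refined by
the Pipe–Menon fixed point `w <- w / (C w)`, which also flattens the local
angular density fluctuations of golden-angle patterns (these otherwise
leave ~5% speckle in a fully sampled adjoint reconstruction). CG-SENSE
solves `(E^H D E) x = E^H D s` with zero initialization and exactly 4
iterations; sensitivities come from the first 10,000 imaging spokes,
regridded at low resolution (maps are smooth), combined by the Walsh
eigenvector method with a 3-voxel covariance smoothing, phase-referenced to
coil 0, interpolated to the target grid, unit-RSS inside a 5%-of-max mask.
Reformatting rotates the k-space coordinates before gridding (the object
appears at `R @ center`; sensitivity maps must be expressed in the same
rotated frame); thick slices are complex sums of 4 thin slices (noise grows
by sqrt(4), signal by 4).

Amplitude calibration: simulated samples carry mm^3 units, so
reconstructions divide by the voxel volume; a unit-intensity object
reconstructs near unit intensity, which the phantom oracles rely on.

## Metrics

NAAD is computed after separable smoothing with a unit-sum 9-point raised
cosine (Hann) window per axis — the kernel's dimensionality/normalization is
a package convention — on voxels >= 25% of the (smoothed) maximum. Phantom
blood-pool segmentation thresholds at half the robust peak intensity (99.5th
percentile) and keeps the largest connected component; manual contouring is
out of scope. Diameters through the slice centroid are measured two ways:
on binary masks (outermost half-level crossings, the interface for external
masks) and on the reconstruction's intensity profile at the segmentation
threshold, which resolves the edge to a fraction of a voxel and is what the
phantom pipeline reports. Volumes are Simpson sums of slice areas;
respiratory variation is `100 (v_max - v_min)/v_max`.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the pipeline recovers known motion and
geometry from exactly-generated k-space under realistic breathing
variability, noise and undersampling, and that the projection-vs-k-space
contrast (accurate amplitude-anchored binning vs fragile fixed-band
phase-anchored binning) emerges mechanistically. The phantom does not
emulate bSSFP contrast/banding, eddy-current artifacts, receiver-chain
nonidealities, arrhythmia beyond RR jitter, through-plane cardiac motion,
or the inter-patient variability of real cohorts; absolute volumes and
in-vivo effect sizes are therefore illustrative, not predictive.

## Problem sizes

Unit tests run on 24,000-spoke one-minute acquisitions at 48^3 / 4 mm; the
self-gating and binning acceptance checks use the full 250,000-spoke
ten-minute protocol at the same grid; the end-to-end method-contrast run
uses 96,000 spokes over four minutes at 64^3 / 3 mm (bins of ~1,800 spokes);
the full clinical matrix (176^3, 2 mm) is supported but not exercised in the
default suite.
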