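# Methods

## Scope and modelling stance

spikebeam is a validation environment for spike source localization, not a
clinical tool. Everything runs on concentric-sphere volume conductors with
analytic forward solutions, because every inverse operation the package
implements (beamforming, dipole scanning, covariance regularization,
conductivity calibration, resection scoring) is agnostic to how the
leadfield was produced, while spheres admit independent closed-form oracles
that make the physics testable to machine precision. Contrasts between head
models that in realistic settings come from geometry (e.g. a three- versus
six-compartment segmentation) are emulated here as alternative
shell-conductivity profiles of the same sphere.

## Forward models

**Geometry and units.** Right-handed head-centered coordinates in mm;
dipole moments in nA·m; EEG in µV; MEG in fT. Shells are listed innermost
(brain) to outermost (skin); the default three-shell profile is radii
80/85/92 mm with conductivities 0.33/0.01/0.43 S/m (brain/skull/skin). The
skull is identified as the least conductive shell when a calibration needs
to replace its conductivity.

**EEG.** The scalp potential of a current dipole in a layered isotropic
sphere is expanded in spherical harmonics. Per harmonic order n the radial
profile in each shell is `A ρⁿ + B ρ^-(n+1)`; continuity of potential and
radial current at each interface plus a vanishing radial current at the
scalp give a small linear system whose solution yields the surface
coefficient G_n (for equal conductivities G_n reduces to (2n+1)/n, the
homogeneous sphere). The series is truncated at 60 orders by default
(configurable); at the default truncation the gain changes by < 1e-8 when
doubling the order for sources at ordinary depths, but sources within a few
mm of the brain surface need a higher cap. The test oracle is the
homogeneous-sphere closed form obtained by summing the Legendre series
analytically with generating-function identities — an expression
independent of the truncated-series code path. An average reference is
applied to every leadfield column.

**MEG.** The Sarvas closed form for the spherically symmetric conductor.
Two exact properties follow and are asserted: the field is independent of
the conductivity profile, and radial dipole moments are silent. Sensors are
modelled as radial magnetometers on a sphere 20 mm above the scalp;
gradiometer synthesis is hardware-specific and out of scope, and does not
change the inverse mathematics. The test oracle is a Geselowitz
surface-integral evaluation (primary dipole field plus the surface integral
of the closed-form potential) on a dense Fibonacci covering of the
conductor boundary. A source exactly at the sphere center is magnetically
silent; its leadfield columns are zero and a warning is emitted.

**tSVD reduction.** For MEG scans the per-source S×3 gain is reduced to the
two strongest right-singular directions; in the sphere the discarded
direction is radial to within a fraction of a degree (asserted). Ties
between the two smallest singular values are broken by keeping the first
two columns of the SVD's descending ordering.

**Sensor placement** uses a deterministic golden-angle spiral
(hemispheric or full coverage), so geometries are reproducible without a
seed. **Source grids** are Cartesian lattices (lexicographic order) clipped
to a ball `brain radius − margin`; the default margin of 2 mm keeps sources
off the innermost boundary where the series converges slowly.

## Synthetic data

The generator reproduces the statistical structure the analysis depends on,
not the biophysics of epileptic tissue:

- **Spike waveform**: biphasic spike–wave with peak exactly 1.0 at t = 0, a
  monotone 20 ms rising flank (linear by default, cosine optional), 30 ms
  fall and a 150 ms opposite-polarity slow wave at 40 % amplitude.
- **Epochs**: ±0.5 s around the peak at 2400 Hz by default (the sample-rate
  and trial-count defaults follow the recording conditions the pipeline is
  meant to emulate; named presets of 248 and 54 averaged spikes are
  provided). Reduced rates (600–1200 Hz) are used in tests and in the
  acceptance script purely as a problem-size choice; no analysis step
  depends on the rate.
- **Noise**: default temporally AR(1) (coefficient 0.95) with a 30 % iid
  sensor-noise floor, giving the beamformer a non-trivial covariance to
  adapt to; pure iid and leadfield-projected "brain noise" modes are
  selectable. SNR is defined at the spike peak on the best channel:
  per-trial noise std = peak signal amplitude / SNR. The paper-scale spike
  SNR is not documented anywhere we could anchor to, so the default of 5
  (10 for stimulus-locked SEP/SEF) was chosen once as representative of
  averaged-spike work and is not tuned per experiment.
- **Trial variability**: lognormal amplitude jitter (σ = 0.2) and ±5 ms
  uniform latency jitter, on by default. These are what make the
  average-based and event-related covariances genuinely different;
  switching them off makes the two modes nearly equivalent.
- **SEP/SEF**: one focal, mainly tangential source with a Gaussian
  component peaking exactly 20 ms post-stimulus, projected simultaneously
  through an EEG leadfield computed at the "true" skull conductivity and
  the (conductivity-free) MEG leadfield; stimulus-locked, so no jitter.
- **Resection volumes**: balls of grid points around a center; the default
  radius (≈ 6.9 mm) is the radius of a 1.4 cm³ sphere, a small
  thermocoagulation-scale volume.

All randomness flows through `numpy.random.default_rng(seed)`; paired
EEG/MEG simulations share the per-trial amplitude/latency draws (same
physiological events) with independent sensor noise. Ground truth travels
with each dataset.

What passing tests therefore show: the inverse machinery is correct and
well-behaved under the assumed noise model and an exactly known forward
model. What they do not show: robustness to forward-model geometry error,
non-stationary or artifactual noise, spike-marking variability, or
propagation — none of which the generator emulates.

## Preprocessing

Band-pass 2–80 Hz plus 50 Hz notch, two-pass zero-phase Butterworth of
order 6 (forward–backward, doubling the effective order and cancelling
phase; the notch is an IIR notch at Q = 30 applied the same way). Trials
are averaged arithmetically. The localization sample is the middle of the
rising flank of the global field power: the onset is the last pre-peak
sample at or below 20 % of the peak GFP, the midpoint the first sample from
the onset reaching 50 % of the peak GFP. The midpoint level is referenced
to zero rather than to the onset amplitude — on a clean linear 20 ms ramp
this puts the midpoint exactly at −10 ms, which is the behavior a reader of
"middle of the rising flank" expects; both fractions are configurable.
Baseline noise is the per-channel std of the *averaged* data in
−500…−300 ms. For combined EEG/MEG, every channel of data and leadfield is
divided by that channel's baseline std and the two systems are stacked;
the combined system is unit-free and treated exactly like one modality.
Note that this per-channel weighting intentionally changes single-modality
maps too (it is a whitening); only uniform rescaling leaves a dipole-scan
map unchanged.

## Inverse solvers: numerical choices

- Covariance windows default to the full epoch for both estimation modes
  (the choice is exposed; the two modes must use the same window to be
  comparable).
- Matrix inversion is by symmetric eigendecomposition with a relative
  eigenvalue floor of 1e-12. Inverting a rank-deficient covariance without
  loading raises `SingularCovarianceError` telling the user to regularize —
  the α = 0 pathology is surfaced, never silently pseudo-inverted.
- The orientation generalized eigenproblem `(LᵀC⁻²L, LᵀC⁻¹L)` is solved on
  `range(LᵀC⁻¹L)` when that matrix is rank deficient, which it exactly is
  for spherical MEG (the silent radial direction never enters the
  orientation). If the spectrum is fully degenerate (C a scaled identity)
  the deterministic fallback is the dominant right-singular vector of L,
  the matched-filter orientation.
- Two filter normalizations coexist because the unit-norm constraint and
  the scalar denominator `LφᵀC⁻²Lφ` printed in parts of the literature are
  inconsistent (the printed form lacks a square root and has
  `‖W‖ = 1/√(LφᵀC⁻²Lφ)`). The default `unit_norm` variant enforces
  `‖W‖ = 1`; `as_printed` reproduces the literal form. They are parallel
  vectors and are reported separately, never mixed; their power maps are
  not expected to share an argmax.
- Localization uses a single sample of D_avg at the analysis index by
  default; a multi-sample window is supported (power sums over columns).
- Map argmax ties resolve to the lowest source index (relevant because
  near-flat plateaus around the maximum are common in beamformer maps).
- Dipole-scan gof is clipped to [0, 1] against floating-point rounding;
  per-source rank is determined at a 1e-12 relative singular-value
  threshold, so silent (zero-gain) points score gof 0.

## Calibration

The MEG location scan runs once (it cannot depend on σ); per σ only a
single-source EEG leadfield is rebuilt, making the sweep cheap at any grid
resolution. The default σ grid is 10 log-spaced values in
[0.0021, 0.033] S/m, bracketing the published spread of calibrated and
literature skull conductivities and containing the standard 0.01 S/m. The
orientation fit is the full 3-moment least squares (equivalent to
orientation-only optimization at the optimum, with a simpler contract);
its sign convention (largest-magnitude component positive) pushes the sign
into the signed MEG amplitude. Only one conductivity is free — the
compacta:spongiosa ratio 1:3.6 is metadata, since a single-shell skull
cannot represent the two layers geometrically; the package makes no
equivalence claim between that ratio and its effective skull conductivity.

## Evaluation and the sweep

The α grid is 0 to 0.2 in steps of 0.002 (101 values; the common toolbox
default 0.05 lies on the grid). Dipole scans are α-independent and computed
once per sweep. Per-cell failures (e.g. α = 0 on a rank-deficient
covariance) are recorded with their error message instead of aborting the
sweep. Distances are reported at full float precision but are
grid-quantized by nature — with a spacing of s mm, distance curves jump in
steps of order s and cannot be smooth. A consistency invariant asserted
across all sweeps: relative power < 1 implies resection distance 0.

`run_pipeline` ties the stages together for each conductivity profile ×
modality: data are always simulated from the designated *true* profile, and
localized with each profile's leadfield, so profile mismatch is part of
what the sweep shows. The default configuration uses a 10 mm source grid,
54 trials at 1200 Hz and 70/271 EEG/MEG channels — problem sizes chosen so
a full sweep stays interactive on one CPU; the tests and the acceptance
script use similar or smaller sizes (12–14 mm grids, 600–1200 Hz,
54–600 trials, 20 calibration repetitions). The manifest (config + seed +
library versions) replays to bit-identical tables.

## Known limitations

- Spheres only: no realistic geometry, no anisotropy, no layered skull;
  conclusions about *geometric* model contrasts do not transfer.
- Radial magnetometers only; no gradiometer synthesis or sensor noise
  spectra.
- The synthetic noise is stationary and artifact-free; spike marking and
  trial selection are assumed perfect.
- The event-related covariance uses the same epoch window as the
  average-based one; peri-spike windowing is available but not the default.
- Relative power is reported as +inf when the resection contains no map
  power at all (undefined ratio), matching the metric's definition rather
  than masking it.
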