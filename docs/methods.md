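# Methods

## The measurement problem

Retrospective cine reconstruction assigns every acquired k-space line a
position inside a mean cardiac cycle through a bi-phasic time projection:
times within systole are stretched linearly onto the mean systole, times
within diastole onto the mean diastole.  The projection therefore needs the
end-systolic time of the beat each line was acquired in.  `pacmri`
measures that time directly, beat by beat, from a real-time phase-contrast
(RTPC) acquisition of the ascending aorta, and condenses the measurements
into a per-subject linear model ("patient-adapted cardiac model", PACM)

    S = a + b · HR,

with S the electromechanical systole duration in seconds (R wave to end of
forward aortic ejection) and HR the instantaneous heart rate in bpm.
Weissler's historical phonocardiographic regression provides the fixed
global reference constants (men: b = −0.0018 s/bpm, a = 0.456 s; women:
b = −0.0016 s/bpm, a = 0.461 s; residual SD 0.014 s).

## Generative model of the synthetic acquisition

No deposited RTPC raw data exist, so the package ships a generator whose
defaults are the study conditions of a resting adult cohort: 128 beats per
subject, heart rate marginally truncated-normal 67 ± 9.5 bpm within
[44, 114] bpm, and per-beat end-systole drawn from the linear model above
(defaults: Weissler male constants with 5 ms cycle-to-cycle residual SD).

Design choices that deserve justification:

* **Heart-rate dynamics.**  Per-beat heart rates follow a stationary
  Gaussian AR(1) process (lag-1 autocorrelation 0.95) with the marginal
  mean/SD above, rejection-sampled into the bounds.  Resting heart rate
  drifts slowly; independent per-beat draws at SD 9.5 bpm would make
  consecutive RR intervals differ by >20% so often that the ectopic-beat
  screening rule would reject roughly a third of perfectly normal cycles.
  With the autocorrelated process an ectopic-free record passes screening
  in full, and at the default 2% ectopic rate about 7% of cycles are
  discarded (each ectopic also rejects its two neighbours), a realistic
  screening yield.  Regression-protocol cohorts (parameter-recovery and
  goodness-of-fit studies) instead use independent draws
  (`hr_autocorr=0`), because they emulate cycles pooled across many
  subjects, where the heart-rate spread is the cross-subject marginal.

* **Aortic waveform.**  Only the timing of the end of forward systolic
  flow matters downstream, but its *detectability* depends on the terminal
  waveform shape.  The generator uses an asymmetric ejection lobe
  (quarter-sine upstroke over the first 30% of ejection, cosine decay to
  zero) followed by a brief flow reversal of 12% of peak over a quarter of
  the ejection time — the dicrotic-notch backflow of ascending-aorta flow
  at aortic-valve closure.  The downward zero crossing at exactly
  `R + S_i` is steep because the decay slope and the backflow onset slope
  add, which is also what makes "end of forward flow" a physiologically
  well-defined instant.  Peak velocity defaults to 100 cm/s, safely below
  the 150 cm/s velocity-encoding limit.

* **Ectopic beats.**  An ectopic beat replaces its RR by
  `0.6 · min(previous RR, median RR)`, guaranteeing the >20% deviation
  from both comparators that the screening rule tests for.

* **Scene and coils.**  The 1D scene holds the aorta (6 pixels, forward
  flow), up to three confounding vessels with distinct sign/timing
  (descending aorta antiparallel and delayed 40 ms; a slower forward
  vessel delayed 80 ms; a weak late antiparallel vein), a static-tissue
  magnitude band and air.  Two smooth strictly-positive coil-sensitivity
  profiles weight either half of the field of view.  Velocity noise scales
  inversely with magnitude, as phase noise does; the default 3 cm/s at
  unit magnitude corresponds to a typical phase-contrast SNR.

* **Velocity encoding.**  Each echo carries phase
  `toggle · (π / (2·venc)) · v` with the toggle alternating between
  echoes, so the phase difference of an adjacent pair spans
  `(π/venc) · v` and velocities at the encoding limit alias at π.

* **ECG.**  Two leads: a fixed QRS complex per beat plus a
  magneto-hydrodynamic bump synchronous with the ejection window (the
  flow-induced voltage in the static field), white noise, and online
  R-wave detections jittered with SD 10 ms — the regime that makes
  template repositioning necessary.

* **Seeding.**  All randomness derives from one seed through a named
  `SeedSequence` split (rr, ectopic, systole, scene, ecg, jitter, tissue);
  identical configs give bit-identical subjects.

## Reconstruction

Unitary 1D FFT per echo and channel; the central 50% of the field of view
is kept (128 of 256 pixels, half-open centred window).  Velocity comes
from every pair of *adjacent* interleaved echoes (sliding shared velocity
encoding), so frames are spaced one TR = 6.6 ms apart; each frame is the
phase difference of its echo pair scaled by venc/π and signed by the later
echo's toggle, and is time-stamped at the pair midpoint.  A sliding pair
measures the average of the two echoes' velocities; oracle comparisons
against the simulated scene therefore use the pairwise average.  Channels
are combined as a magnitude-weighted mean (magnitude per frame = mean of
the two echo magnitudes; zero-magnitude pixels get velocity 0).  No
velocity-offset correction is applied anywhere: an encoding-dependent
background phase propagates linearly into velocity, and a test pins that
pass-through behaviour.

## Aorta segmentation

The velocity map is decomposed by SVD; for each of the first three
components the spatial loading `σ_i · |u_i|` is thresholded at 25% of its
own maximum, and the three masks are OR-combined.  Kept pixels are grouped
into maximal runs of consecutive indices; each region's course is the
unweighted pixel mean per frame.  The region is selected by power of the
mean-removed course in the cardiac spectral band (subject mean heart
frequency ± 0.03 Hz, plain FFT periodogram — no tapering, so the band edge
stays sharp); candidates need more than 40% of the maximum band power and
a positive mean velocity (the ascending aorta's flow direction), and the
largest candidate in pixels wins, ties breaking to the lowest pixel index.
The subject's mean heart frequency comes from the screened R-R intervals,
not from the course itself.  The same defaults apply to every subject —
the chain has no per-subject tuning.

## ECG refinement and cycle screening

A per-subject QRS template (120 ms window) is the per-lead mean of the
trace around the online detections; each detection is repositioned at the
maximum cross-correlation of the template with the trace, summed over
leads, within ±50 ms (ties earliest; a flat correlation keeps the online
detection).  Cycles are screened in two steps: instantaneous heart rate
outside [30, 120] bpm rejects the cycle alone (a detection error, not
physiology — its neighbours stay); an RR differing by more than 20% from
both the whole-record median RR and the previous RR marks an ectopic beat
and rejects the cycle and both neighbours.  The median is computed once
over the full record, which makes screening idempotent on the accepted
subset.  Every cycle carries exactly one terminal status (`ok`,
`hr_out_of_range`, `ectopic`, `ectopic_neighbor`, `systole_out_of_bounds`,
`unmeasured`), so counts always reconcile.

## End-systole detection

The S wave of each accepted cycle is the frame of maximum projected
velocity within the cycle (ties earliest).  The baseline under the course
is computed in 10 iterations: a zero-phase 4th-order Butterworth low-pass
(0.5 Hz cut-off) of the course seeds the baseline; each iteration then
performs a histogram analysis of the samples still considered non-extreme
— 64 equal-occupancy bins — moves the extreme-value threshold one bin
further in from both sides, sets extreme samples to the current baseline
value at their frame, and re-filters.

Equal-occupancy bins are the load-bearing choice.  The course's value
distribution is dominated by the near-zero diastolic mode, which sits at
the *edge* of the value range; thresholds that walk in over fixed-width
value bins either never suppress the mid-amplitude systolic upstroke
(leaving the baseline at the pulse-weighted mean, ~20% of peak velocity,
and biasing every crossing ~30 ms early) or clamp the diastolic mode
itself.  With occupancy bins the surviving sample set contracts
geometrically onto the mode, and the converged baseline tracks the
diastolic level to well within 5% of the systolic peak.  The construction
is covariant under constant shifts: `baseline(course + c) =
baseline(course) + c`.

End of forward systolic flow is the first frame at or below the baseline
when scanning forward from the S wave, refined to sub-frame precision by
linear interpolation of the course-minus-baseline sign change.  The
systole duration is that crossing minus the cycle's R time; values outside
100–500 ms invalidate the cycle (`systole_out_of_bounds`), a missing
crossing or empty cycle is `unmeasured`.  On noise-free synthetic subjects
the measured durations match truth within one frame (6.6 ms) for every
cycle (RMS 0.4 ms); at default noise the RMS error is ~4 ms.

## Model fitting and quality gate

Valid cycles are split chronologically per subject: the first
`floor(0.8·n)` train, the rest hold out; subjects with fewer than 5 valid
cycles are flagged and excluded.  The PACM is an M-estimator regression of
systole duration on the cycle's own instantaneous heart rate — iteratively
reweighted least squares with Huber weights (tuning 1.345, 95% Gaussian
efficiency); ordinary least squares is available as an oracle and for
pipelines that prefer it.  The quality metric is the SD of the residuals
around the fitted line (n−2 denominator): above 10 ms the subject's model
is flagged bad and the subject excluded.  R² is deliberately *not* the
gate, because a subject with nearly constant systole duration has R² ≈ 0
even when the (constant) model is excellent; with zero heart-rate variance
the fit degenerates gracefully to a robust location with slope 0 and an
undefined R².  Pooled ("PACM averaged") models run the same regression on
all of one sex's training cycles and report two determination
coefficients — per-cycle and on subject-mean points — since the two can
differ strongly for pooled data and summaries are easily misread across
that distinction.

## Evaluation

Bland-Altman agreement (bias, ±1.96 SD limits, bias SE = SD/√n, one-sample
t test of the bias) compares each model's holdout predictions against the
measured systole times.  Before comparison, cycles whose measured systole
deviates from their own subject's PACM prediction by more than 4 robust
SDs are excluded and counted — the physiologically decoupled cases
(abnormally long RR with unchanged systole, as after a non-conducted P
wave, or a systole far beyond any RR-based prediction, as with an
extrasystole).

The bi-phasic projection maps `t ≤ S_i` to `t·S̄/S_i` and diastolic times
linearly onto `[S̄, R̄R̄]`; it is continuous, strictly increasing and
bijective per cycle.  The mean cycle (S̄, R̄R̄) is the mean of the accepted
cycles' systole and RR.  `reconstruct_cine` bins a multi-beat sample
stream into 64 uniform frames of the mean cycle using a chosen per-cycle
end-systole source (measured truth or a model), interpolating and counting
empty bins; the E-wave peak is the maximum absolute course value within
the first third of diastole after S̄.  The synthetic tissue-velocity
stream used for this illustration places its lobes at fixed *fractions* of
the two phases (S lobe spanning systole, E lobe starting 10% into
diastole, lasting 18% of it), i.e. it is exactly consistent with the
bi-phasic decomposition: binning with the true end-systole aligns all
beats, and any bias in the end-systole source de-aligns the narrow E lobe
and attenuates its binned peak monotonically.  A fixed-latency E lobe
would not behave this way (a uniform bias can even sharpen it by pushing
it toward the phase boundary), so the phase-locked stream is the regime in
which the reconstruction comparison is well-posed.  E-peak comparisons use
a one-sided paired Wilcoxon signed-rank test, exact for ≤10 pairs.

## Problem sizes and defaults used in validation

The test-suite and the reproduction script use cohorts the package chose
for statistical resolution: 20 seeded cohorts of 3324 cycles for
parameter recovery (the size of a 31-subject training pool at ~107 cycles
each), 200 replicates of 94 cycles for the emergent goodness of fit of an
echocardiography-sized sample, 50 subjects of 128 beats for detection
accuracy and the residual-SD quality gate (5 ms retained vs 20 ms
excluded), and 50 seeds for the cine E-wave comparison on
high-variability subjects (sd_hr = 12 bpm, record RR SD above ~60 ms).

## Limitations

* The simulator is deliberately minimal MR physics: no relaxation, eddy
  currents, off-resonance or 2D encoding, no respiratory motion of the
  ROI (an optional slow pixel shift would be the natural extension).
  Passing tests demonstrate the correctness of the measurement chain under
  the generative model, not robustness to every artifact of real 3T data
  (aliasing above venc, lung-boundary noise, vessels overlapping the
  aorta's projection — the known failure modes that a quality gate must
  catch in practice).
* Velocity aliasing is permitted by the renderer but no unwrapping is
  implemented; strongly aliased aortic flow would corrupt the course and
  is expected to trip the quality gate rather than be recovered.
* The regressor is the current cycle's instantaneous heart rate; the
  preceding cycle's RR also carries physiological information and is a
  possible refinement.
* Global-model rows for populations other than the resting-adult defaults
  (e.g. the echocardiography-derived row) are used as generator presets,
  not as validation truth.
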