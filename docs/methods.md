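# Methods

`saccadeflow` re-implements, as a tested pipeline, the analysis chain used to
ask how primary visual cortex (V1) distinguishes image motion caused by the
animal's own saccades from motion in the world. The chain runs from raw
video-oculography landmarks to a linear model of how visual and non-visual
(extra-retinal) inputs combine, and is validated end to end on a synthetic
session generator with known ground truth.

## Eye-angle geometry

The angular position of the eye follows the projection relation
`sin(alpha) = d / Rp`, where `d` is the projected distance between the pupil
centre (fitted ellipse) and a fixed corneal reference, and `Rp` is the radius
of the circle the pupil centre sweeps as the eye rotates. `Rp` shrinks
linearly with pupil diameter, `Rp = r - a * Dp` (slope `a` physiologically
0.05–0.25), because the pupil plane recedes from the rotational centre as the
pupil constricts. Calibration swings the camera by known angles `gamma`
about the eye's rotational centre; within one luminance condition the model
`d = Rp * sin(gamma + alpha0)` is linear in
`(Rp cos(alpha0), Rp sin(alpha0))`, so `Rp` comes from ordinary least squares
per condition and `(r, a)` from regressing `Rp` on `Dp`. The estimator
combining multiple swing angles is a design choice of this package (the
procedure is under-specified in general); it is exact in the noiseless case
and unbiased under additive measurement noise. Ellipse fitting uses the
direct least-squares conic fit (`skimage.measure.EllipseModel`). Frames whose
fit fails are emitted as NaN gaps, never interpolated.

## Saccade detection

Two frame-threshold detectors:

* **Head-fixed** (200 Hz, azimuth only): a per-frame displacement above
  0.75°, monotone movement in the same direction for ≥ 3 frames, peak
  amplitude ≥ 3°. Onset/offset are the first/last frame of the monotone run
  (the offset rule is this package's minimal extension of the monotonicity
  rule).
* **Freely moving** (90 Hz, 2-D): a per-frame step above 5.5° (≈ 500°/s,
  above mouse head-movement speeds, excluding vestibulo-ocular image
  stabilisation), onset back-tracked to the first frame above 200°/s,
  duration ≥ 2 frames, successive displacement vectors within 45°.

Thresholds are stored with their native frame duration and rescaled as
velocities for other frame rates. The isolation filter keeps events preceded
by ≥ 500 ms in which no frame-to-frame displacement exceeds 0.2°/frame
("the eye did not move" is otherwise undefined; the floor is configurable).

A consequence of the 5.5°-per-frame trigger worth stating plainly: at
physiological rise times (~27 ms, 10–90%) the largest per-frame displacement
of a smoothstep saccade is ≈ 0.37 × amplitude, so the freely-moving detector
cannot fire for events below roughly 15–17°. Detection-fidelity benchmarks
therefore evaluate the head-fixed detector on events ≥ 5° and the
freely-moving detector on events ≥ 17° — the floor is a property of the
detection rule, not of the implementation.

Kinematics: amplitude is onset-to-plateau displacement (median over 20 ms
after offset); 10–90% and 0–90% rise times come from linearly interpolated
crossings of the displacement profile; mean speed uses the 0–100% duration
(both rise-time conventions are computed because reported values mix them).

## Pseudo-saccades

Pseudo-saccades (rapid grating shifts emulating the retinal consequence of a
saccade; a "nasal" pseudo-saccade is a temporal-direction grating shift) are
scheduled at exponential intervals (mean 1.5 s) with amplitude/direction
resampled jointly from the session's real saccades, and discarded within
500 ms of a real saccade. Each real saccade is then matched to the k = 2
same-direction pseudo-saccades closest in amplitude (ties broken by earliest
onset; without replacement while the pool lasts, then with replacement,
flagged). Matching minimises the absolute amplitude difference.

## Response statistics

Spike counts use half-open windows: response `[0, 100)` ms and baseline
`[-300, -200)` ms from onset. PETHs use 20-ms bins over ±500 ms; population
averages exclude units with baseline < 0.5 Hz (visualisation only — every
statistic uses all units). NT discriminability is the signed Gini
coefficient `2*AROC - 1` over nasal vs temporal count distributions (ties
counted ½; positive = nasal preference), with a two-sided rank-sum p-value
and Benjamini–Hochberg control at 10% across units (the BH adjusted p-value
serves as the q-value; the original q-value estimator is not named).
Head-fixed responsiveness pools three rank-sum comparisons per unit
(response vs baseline per direction, nasal vs temporal) under the same FDR
control; freely-moving responsiveness uses Kruskal–Wallis over 16
response/baseline categories, Tukey's HSD contrasts (family-wise α = 0.05),
and a ≥ 50% mean change versus baseline (a zero baseline counts as "above"
only for a positive response). Binwise pref-vs-non-pref PETH tests are
one-tailed paired signed-rank per 20-ms bin with BH at 10% across bins
(one-tailed per the figure-level convention; responsiveness and
discriminability tests are two-sided — the conservative reading where no
tail is stated).

Putative eye-position units — units whose pre-onset baseline (500 ms)
differs between upcoming nasal and temporal saccades, reflecting the
eye-position/direction correlation rather than a saccade signal — are
flagged by a rank-sum test at α = 0.05 and excluded. Rao's spacing test
(`U = ½ Σ|spacing − 360/n|`) gets its p-value from ≥ 10,000 seeded uniform
resamples. Units are classed regular-spiking iff trough-to-peak > 0.5 ms
(boundary to FS). The L4/L5 border sits 125 µm above the channel with
maximum spontaneous rate (L5: 200 µm below; L4: 150 µm above; beyond these,
L2/3 and L6 by depth); flat or multi-peaked profiles are flagged ambiguous.
Antidromic identification requires > 20% response probability within 5 ms of
the light pulse and < 0.5 ms first-spike latency s.d.

## Population decoding

Single-trial population responses are per-unit spike counts in the 20-ms bin
`[60, 80)` ms after onset (the bin grid is anchored at onset; units with
session mean rate ≤ 0.5 Hz excluded). Training sets come from pseudo-saccade
responses balanced in label and amplitude: greedy nearest-amplitude pairing
without replacement, then pairs differing by more than 1° are dropped so
that counts stay balanced while the amplitude cue is removed. The classifier
standardises per unit, projects onto principal components capped at 20% of
the training-event count, and fits quadratic discriminant analysis with a
covariance ridge (`reg_param = 0.1`) — the single-trial counts are sparse
Poisson draws, and near-full-rank class covariances are otherwise badly
conditioned. Within-condition accuracy uses stratified 10-fold
cross-validation; cross-condition accuracy applies the fitted pipeline to a
fully held-out condition. Permutation feature importance is the increase in
10-fold cross-validated misclassification after permuting one unit's column;
the top-k exclusion analysis permutes all top-importance columns at once.

A methodological point that shapes how the cross-condition result should be
read: for a single fixed population, the accuracy of a pseudo-trained
classifier on grating saccades contains a random alignment term between the
learned weight pattern and that population's non-visual response pattern.
Its sign is arbitrary, it does not vanish with more test events, and it can
make a single population's transfer accuracy land well above (or below)
chance. Averaging over random unit subsets — exactly what the
population-size-curve procedure does — averages this term away, which is
how the cross-condition contrast is evaluated here: per generated
population, accuracy is the subset-averaged value at a fixed subset size,
and conclusions use a t-interval across several independent populations.
Cross-condition test accuracy is reported as balanced (per-class mean)
accuracy, because real-saccade test sets are direction-unbalanced and any
label-biased classifier would otherwise score up to the majority fraction.

## Integration model

Per neuron, the visual input is the mean baseline-subtracted evoked count to
pseudo-saccades, the non-visual input the same for saccades on a grey
screen, and the target the evoked count for saccades on a grating. A single
shared gain is fitted with no intercept, `g = Σxy / Σx²`, under five-fold
cross-validation; held-out predictions are rectified so prediction +
baseline ≥ 0 (rectification at prediction time only, matching a
fit-then-threshold procedure). Explained variance is `(TSS − RSS) / TSS` on
the pooled held-out predictions — this cross-validated convention can go
negative for uninformative predictors. Predictor sets (visual-only,
non-visual-only, sum) are compared on the same folds; an all-zero predictor
set yields an undefined (NaN) fit rather than an error. The layer analysis
fits separate standardised coefficients for the two inputs per layer
(relative non-visual share `|b_nv| / (|b_v| + |b_nv|)`); layers with fewer
than 5 units are reported but skipped.

## Synthetic sessions

The generator emulates the two recording configurations: head-fixed
(200 Hz, saccades ~3.1/min, nasal amplitude ~12.2°, temporal ~8.2°, 10–90%
rise ~22 ms, Gaussian tracking jitter 0.1°) and freely moving (90 Hz,
~44.2/min, ~19°, directions biased toward the horizontal axis). Saccades are
smoothstep displacement profiles with compact support placed by a renewal
process that enforces ≥ 600 ms quiet periods; amplitudes are lognormal
(CV 0.3) truncated at 3°.

Spike trains are inhomogeneous Poisson (1-ms grid). Each unit combines:

* a **non-visual kernel** — support starting 100 ms before saccade onset,
  smoothstep rise to a peak 50 ms after onset, 120-ms exponential decay
  (the response both precedes and outlasts the saccade); cosine direction
  tuning with peak gain 25–80 Hz (saccade bursts of this size, peaking just
  after the saccade, match the example responses the analysis targets) and
  suppression below baseline at the opposite direction (half the peak
  gain); negative rates clip at zero; a per-saccade lognormal motor gain
  (σ = 0.6, mean 1, shared across the population) models
  saccade-to-saccade variability of the corollary discharge;
* a **visual kernel** — exactly zero before a 40-ms latency, 20-ms rise,
  40-ms decay (transient); non-negative for both directions (no
  suppression), peak gain 5–25 Hz, growing monotonically but saturating
  with shift amplitude (`1.5·A/(A+5)`, normalised at 10° — a linear
  dependence would make overall response scale an artifactual direction
  cue, since nasal saccades are systematically larger); per-unit direction
  contrast drawn from a skewed Beta distribution (mean 0.2) coupled to
  visual amplitude, so most units barely discriminate shift direction
  while a strongly responsive minority carries the signal — mirroring the
  observed sparseness of visual direction discrimination relative to
  saccade direction discrimination.

Preferred directions of the two components are drawn independently
(uniform), which is the structural null the correlation analyses test. A
shared lognormal excitability factor (σ = 0.4) scales both components per
unit, so overall responsiveness covaries across inputs while direction
preferences stay independent. Condition logic: grey screen / retina-silenced
→ non-visual only; pseudo-saccades → visual only; grating →
`g × (visual + non-visual)` with `g = 0.62` by default; pulvinar-silenced →
visual only during real saccades. For the integration analysis the response
table applies the generative rule at the level of the measured component
responses, `y = g (x_v + x_nv) + ε`, `ε ~ N(0, 0.05 spikes)`, so the gain is
identifiable and the noiseless case is exactly linear.

All randomness descends from one config seed through named substreams
(trace, units, pseudo schedule, spikes, response noise); a fixed seed gives
bit-identical sessions.

**What the generator does not emulate.** Rates are Poisson (no refractoriness,
bursting, or spike-count correlations beyond the shared kernels); kernels are
identical across units up to amplitude; eye traces have no drift, blinks, or
tracking dropouts; visual responses scale linearly with amplitude and ignore
spatial-frequency content; condition blocks reuse the same saccade times.
Passing tests therefore demonstrate that the analysis chain is correct and
recovers known structure under its own assumptions — not that real
recordings satisfy those assumptions. Effect amplitudes sit at the strong end
of the plausible range so the qualitative contrasts (pre-onset divergence,
near-chance cross-condition transfer, its recovery under silencing) resolve
at single-synthetic-session scale.

## Numerical choices and problem sizes

* Windows half-open in ms; times stored as float seconds.
* Sector binning: eight 45° sectors centred on 0°, 45°, …; boundary angles
  go to the lower sector; argmax ties go to the lower sector index.
* Detection-fidelity benchmarks: 30 seeded sessions per configuration
  (300 s head-fixed, 150 s freely moving), noise s.d. 0.2°; recall,
  precision and mean |onset error| in frames are averaged across sessions.
* Calibration recovery: 500 noisy replicates (d noise s.d. 0.01 mm), truth
  checked against the central 95% of the estimate distribution.
* Gain recovery: 200 replicates of 128 neurons per gain in {0.3, 0.62, 1.0}.
* FDR validation: 1,000 simulated null datasets for the binwise tests and
  for head-fixed responsiveness; the mean false-discovery proportion is
  compared with the 10% target.
* Decoding validation: four populations of 128 units (3,000-s sessions);
  per population, balanced accuracy averaged over 3 balanced training sets
  × 15 random 40-unit subsets; compared across populations with a 95%
  t-interval.
* QDA ridge `reg_param = 0.1`; PCA component cap 20% of training events;
  all standardisation/projection parameters fitted on training folds only.

## Known limitations

* The freely-moving detector's amplitude floor (~17°) is intrinsic to the
  5.5°-per-frame trigger at physiological rise times.
* Cross-condition decoding accuracy on any single population carries the
  alignment term described above; conclusions should always rest on several
  populations.
* The explained-variance convention (`TSS − RSS` on held-out predictions)
  can exceed alternatives that recompute the explained sum of squares
  directly under no-intercept fits, and can be negative.
* `rao_spacing_test` is Monte-Carlo; p-values below 1/(n_resamples+1) are
  reported at that resolution.
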