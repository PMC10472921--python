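# Methods

## The measurement problem

The stomach's myoelectrical slow wave (~0.05 Hz, the *normogastric* band
0.033–0.066 Hz) can be recorded with cutaneous electrogastrography (EGG), and
a set of brain regions has been reported whose resting-state BOLD signal
holds a consistent phase lag to it — a "gastric network".  The quantity of
interest is, per voxel, the phase-locking value

    PLV = | (1/T) Σ_t exp(i (θ_gastric(t) − θ_voxel(t))) | ∈ [0, 1],

where both phases come from the Hilbert transform of narrow-band-filtered
signals.  Narrow-band signals produce non-zero PLV by construction, so the
empirical PLV is referenced to a surrogate null: the gastric phase series is
circularly rotated in time by at least ±60 s, the PLV recomputed for every
admissible rotation, and the per-voxel **PLV-delta** = empirical PLV − median
surrogate PLV is the subject-level effect size (averaged over runs).

## Per-run chain and its conventions

1. **EGG**: resample to 10 Hz (polyphase, anti-aliased) → Welch spectrum
   (200 s Hann windows, 150 s overlap; 0.005 Hz resolution) → in-band peak
   per channel → channel with the largest peak power (second-largest if its
   quality grade is strictly better) → zero-phase FIR band-pass of
   ±0.015 Hz around the peak → Hilbert phase.
2. **BOLD**: voxelwise OLS confound regression (four variants; see below) →
   mask-normalized 3-D Gaussian smoothing (FWHM 3 mm) → the same ±0.015 Hz
   band-pass redesigned at the volume rate (1/TR = 0.5 Hz) → Hilbert phase.
   This order (regress → smooth → band-pass) is part of the contract; the
   operators do not commute.
3. **Alignment**: the gastric phase is decimated to the volume onset grid
   (every 20th sample at TR = 2 s).  Surrogate rotations are applied on the
   *full-length* decimated grid; the first 15 volumes (30 s) are dropped from
   both series only when a PLV is evaluated.  Admissible lags are
   `L … N−L−1` with `L = 60 s/TR + 15 = 45` samples, giving exactly 360
   surrogates for a 15-min run (N = 450) and 210 for a 10-min run (N = 300).
   The all-lag PLV is evaluated as a circular cross-correlation of unit
   phasors via the FFT — algebraically identical (≤1e-12) to rolling and
   recomputing lag by lag, and two orders of magnitude faster.

**Zero-phase filtering.**  The band-pass is a windowed frequency-sampling
FIR (order ≈ 6 cycles of the peak frequency) applied forward-backward, so the
net phase shift is zero — any phase distortion would bias the PLV directly.
The implementation convolves twice with the symmetric kernel on a
reflect-padded signal, which is identical to `filtfilt` output to machine
precision.  Net stop-band attenuation at peak ± 0.030 Hz is ≥ 27 dB across
the plausible peak range.

**EGG quality.**  Three criteria: a *clear* in-band peak in every run, peak
frequency consistent across channels, and consistent across runs.  "Clear"
is operationalized as an interior local maximum whose power is ≥ 4× the
median in-band background, where the background excludes the peak bin and
its two neighbours — a physiological peak spans ~3 of the 7 in-band Welch
bins, and counting its skirts as background would mask genuine peaks.
"Consistent" means a spread ≤ 0.01 Hz.  Grades: 1 (all three), 2 (clear
peak, some inconsistency), 3 (no clear peak → excluded from synchrony
analysis).  All thresholds are exposed parameters.

**Confound-regression variants.**  `main_gsr`: intercept, global signal,
framewise displacement, six motion estimates, their backward-difference
derivatives, the squares of both, and six aCompCor components (33 columns).
`no_gsr` (the default for synchrony maps): the same minus the global signal.
`gsr_retroicor`: `main_gsr` plus six cardiac-phase RETROICOR columns
(cos mφ, sin mφ, m = 1–3, φ from pulse-oximetry systole times).  `minimal`:
intercept + CSF only.  Derivatives/squares are scoped to the six motion
estimates; the exact column set is recorded in the design metadata.  Runs
with mean framewise displacement above the group mean + 2 SD are excluded
(applied per run, which is stricter than per subject).

## Group inference

Subject-level empirical and median-surrogate maps (runs averaged) enter a
paired t-test per voxel (df = n−1; zero-variance voxels get t = 0 and a
flag).  Suprathreshold clusters (one-sided t > 2.3, 26-connectivity by
default) are scored by their **mass** (sum of t values).  Family-wise error
is controlled by a sign-flip max-mass permutation test: each permutation
multiplies every subject's difference map by an independent ±1, and
`p_FWE = (1 + #{null max ≥ mass}) / (1 + n_perm)`.  Ties — including the
sign pattern that reproduces the identity — count as exceedances, with a
1e-9 relative tolerance so the count is invariant to summation order.

**Spin test.**  Spatial similarity of two binary surface maps is the Dice
coefficient over both hemispheres; its null rotates the target's spherical
vertex set by a uniform random rotation R on the right hemisphere and the
sagittally mirrored rotation M·R·M (M = diag(−1,1,1)) on the left, so a
bilaterally symmetric map stays symmetric.  Labels are reassigned to the
nearest original vertex (k-d tree; an exhaustive-search path with
lowest-index tie-break is available and tested to agree — ties have measure
zero under random rotations).

## Confound synchrony and the inflation diagnostic

Each of the ten nuisance series (CSF, WM, global signal, FD, six motion
estimates) is treated exactly like a voxel — band-passed at the volume rate,
Hilbert-transformed, trimmed — so its PLV with the EGG is directly
comparable.  Empirical vs median-surrogate PLVs are compared by paired
t-test over runs (runs, not subjects, are the paired unit; a configurable
choice) with Benjamini–Hochberg correction across the ten confounds.  The
run-level Spearman correlation between a confound's EGG synchrony and the
run's brain-wide mean PLV-delta is computed twice — on minimally
preprocessed data and after strict regression.

**A caveat the simulations expose.**  When the shared artifact dominates the
global signal, strict regression does not merely attenuate the
confound–brain correlation: it reverses it.  Regressing a regressor that is
nearly a pure copy of the gastric-locked artifact removes each voxel's
lag-0-coherent noise direction as well, pushing the empirical PLV slightly
*below* the lagged-surrogate median in proportion to artifact strength
(brain-wide delta ≈ −0.03 at the default settings).  This overcorrection is
a genuine property of OLS with a narrow-band regressor, analogous to the
anticorrelations induced by global signal regression; it is reported as
measured rather than tuned away.

## Reliability battery

Four checks across two runs per subject: (1) Pearson correlation of a scalar
synchrony summary (mean PLV-delta within the FWE-significant cluster mask —
the whole-brain mean dilutes a 27-voxel effect ~64-fold on the default grid
and is not a usable retest summary there); (2) parcel-profile similarity —
Pearson r of parcel-mean maps for every unordered run pair, one-sample t
against zero with df = n_pairs − 1 (documented convention; C(46,2) = 1035
pairs); (3) EGG peak-frequency correlation between recording settings; (4)
connectivity fingerprinting — Pearson r between upper-triangle FC edge
vectors for every run pair, within-subject vs between-subject pairs compared
by independent-samples t-test.

## The synthetic cohort generator

The generator emits data with exactly the statistical structure the analysis
assumes, plus ground truth sufficient to score every stage.

* **Gastric oscillator**: cos of a phase whose instantaneous frequency
  wanders around the subject's peak (OU process, SD 0.003 Hz, τ = 60 s).
  The unbounded phase diffusion matters: a bounded phase drift would keep
  time-shifted copies phase-locked and make the circular-shift null
  degenerate.  Subject peaks ~ N(0.05, 0.005) Hz truncated to the
  normogastric band.
* **EGG**: four channels at amplitudes (3, 1.5, 1, 0.7) × 0.2 mV plus 1/f
  noise (0.05 mV) and a 1.2 Hz cardiac bleed; graded level 1 in ≥ 95% of
  seeds at these defaults.
* **BOLD**: 12×12×12 grid of 3 mm voxels, 450 volumes at TR = 2 s.  Noise is
  AR(1) (ρ = 0.3, SD 1) + white (SD 0.5) + a rank-5 shared-latent term
  (amplitude 0.5) that gives runs an FC structure.  A central block of 27
  voxels is coupled: `a·cos(θ_gastric + voxel lag) + noise`, with `a`
  obtained by inverting the exact Rice-phase mean resultant of a constant
  phasor in complex Gaussian noise, using the in-band noise power computed
  from the noise spectrum and the analysis filter response.  No
  data-dependent tuning: measured PLV hits the target within ±0.05
  (finite-T bias included).  Between-subject coupling SD defaults to 0.15.
* **Confounds / artifact**: ten nuisance columns with AR(1)+white bases
  mapped to realistic units (FD ≥ 0, mm, rad).  The global signal is the
  spatial mean of the generated BOLD run plus small sensor noise — so a
  shared artifact appears in it at full strength and regressing it genuinely
  cleans the data.  With `confound_coupling > 0`, a gastric-locked artifact
  (run-level strength ~ U(0.25, 1) × coupling) is added to all voxels and to
  the motion columns; CSF receives an independent gastric-locked component
  (synchronized with the EGG without leaking into the brain).
* **PPG**: asymmetric systolic pulses at ~70 bpm with 20 ms HRV jitter;
  emitted systole times are ground truth (detector recovers them within
  20 ms median).
* **Stability**: `subject_stability s ∈ [0,1]` correlates run-level draws of
  peak frequency, coupling strength and FC loadings with coefficient s²
  (s = 1 subject-stable, s = 0 redrawn per run).
* All generators are pure functions of (config, seed); regeneration is
  bitwise identical.

**What the generator does not emulate** — and hence what green tests do not
show about real data: biophysical gastric electrophysiology, hemodynamic
response convolution, spatially structured physiological noise (respiration
is absent entirely), scanner drifts, and realistic anatomy (the mask is a
full box; parcels are geometric blocks).  Calibration results (e.g. the 5%
FWE rate) transfer to real data only insofar as subject difference maps are
exchangeable under sign flips.

## Calibration-study design choices

* Type-I calibration uses 100 null cohorts of 8 subjects on the 12³ grid
  with 500 sign-flip permutations; the rejection count is checked against
  the central 95% binomial band around 0.05.
* Retest-reliability recovery uses n = 23 subjects (stable coupling); the
  *null* retest check runs at n = 46, because at n = 23 the null sampling SD
  of r (≈ 0.21) makes |r| < 0.3 hold only ~84% of the time — no generator
  could meet a 90% bar there.  Fingerprint calibration uses 200 cohorts of
  6 subjects with physiological traces disabled (they are not consumed).
* Spin-test calibration: 200 repetitions of independent 1000-vertex
  annotations, 150 rotations each; p-values checked for uniformity by a
  Kolmogorov–Smirnov test at α = 0.01.
* Problem sizes in `scripts/acceptance.py` (e.g. 60 null cohorts, 5 recovery
  seeds) are chosen so the whole script reruns in a few minutes while every
  reported quantity remains a stable estimate.

## Known limitations

* The circular-shift surrogate introduces one wrap-point discontinuity,
  which biases per-voxel delta slightly positive (~+0.01 at T = 435); the
  sign-flip group test remains calibrated because the bias is shared between
  the permutation branches.
* Permutation p-values are coarse below 1/(1+n_perm); with few subjects the
  identity sign pattern recurs and ties the observed statistic (counted
  conservatively as an exceedance).
* The cross-subject surrogate truncates all series to the shortest run.
* Rotational motion estimates are used in radians as delivered; no
  millimetre conversion is applied.
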