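# Methods

This note documents the models, conventions and design choices behind
`boldphysio`, in the order data flows through the pipeline.

## Physiological preprocessing

**Beat detection.** The PPG trace is band-passed at 0.5–2 Hz with a 2nd-order
Butterworth filter applied forward-backward (zero phase), and local maxima at
least 5% of the filtered signal's interquartile range high and 0.25 s apart
are taken as beats. The IQR-based threshold makes detection invariant to gain
differences between recordings.

**IBI cleaning.** Inter-beat intervals outside [0.33, 2.0] s (≈ 30–180 bpm)
or deviating more than 3 scaled median absolute deviations from a 15-beat
running median are flagged and replaced by linear interpolation between
neighboring valid intervals; beat times are rebuilt cumulatively. This is an
automated stand-in for manual artifact review, chosen for reproducibility;
if more than half the intervals are flagged the output carries a quality
flag.

**TR-locked series.** Volume *i* is taken at t = i·TR. Heart rate is
60 / median(IBI) over the 6 s window centered on each volume; respiratory
variation (RV) is the SD of the raw belt trace in the same windows. Windows
at the recording edges are clipped to available data, never padded: padding
would fabricate samples, clipping only widens the estimator's variance at
the first/last couple of volumes. Empty HR windows are interpolated from
neighbors with a logged warning.

**RV normalization.** Bounds at the empirical 1.45th/98.55th percentiles
(exact order statistics with linear interpolation — a binned histogram would
differ negligibly); the mean of in-bounds values is subtracted from data and
bounds; positive values divide by the adjusted upper bound, negative by the
magnitude of the adjusted lower bound. The result is scale-free (≈ ±1),
removing torso-size gain differences.

**Capnograph.** The capnograph is aligned to respiration by exhaustive
one-sample-step search for the shift (± a configurable maximum) minimizing
their Pearson correlation — the two signals are physiologically
anti-correlated. Sign convention: positive shift = capnograph delayed
relative to respiration. End-tidal CO₂ is the breath-wise peak series
(minimum peak separation 1.5 s) linearly interpolated onto the volume grid.

**HRV metrics.** RMSSD in ms; LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) band
power of the IBI series after cubic interpolation onto a uniform 4 Hz grid,
estimated with a Welch periodogram (120 s segments, 50% overlap) and
trapezoidal band integration — standard HRV practice. RMSSD/LF/HF are
reported natural-log transformed (units ln ms, ln ms²); non-positive powers
yield flagged NaN logs. Cohort summary statistics apply a Tukey-fence screen
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) per metric before testing.

## Response functions and regressors

The cardiac (CRF) and respiratory (RRF) impulse responses use their
canonical closed forms (early positive peak, delayed undershoot/trough). The
CO₂ response is a generic peak-normalized double gamma
A₁·(t/(n₁τ₁))^{n₁}e^{n₁−t/τ₁} − A₂·(…); its parameters are *editable
configuration*, defaulting to a positive lobe peaking at 8 s and a small
undershoot near 18 s — a delayed response plausible for older adults. Any
published parameterization can be slotted in.

Each response contributes a basis of three curves (two for CO₂): the
primary, a temporal derivative (central finite difference, 0.02 s step —
fine enough that the numerical derivative matches the analytic one to ~10⁻⁴
relative), and a dispersive derivative [rf(t/w)/w − rf(t)]/(w−1) with
w = 1.1, the sensitivity of the curve to a stretch of its time axis. The
"dispersive" reading of the cardiac basis was chosen because a *spatial*
derivative of a time-domain response function is not meaningful.

Design matrices are built by: linear detrend → z-score → linear upsampling
to a 0.5 s grid (fidelity/cost compromise, configurable) → convolution with
each basis → resampling at volume times → z-score, plus Legendre
polynomials of degree 0..4 as drift terms (degree 0 is the intercept).
Z-scoring before and after convolution makes the columns invariant to affine
rescaling of the raw physiology; whether the original analyses z-scored
before fitting is ambiguous, and this choice is documented rather than
hidden. Zero-variance columns are dropped with a warning.

## Coupling GLMs and PVE

Each in-mask voxel is fit by ordinary least squares under three models:
joint (cardiac + respiratory), cardiac-only, respiratory-only. Cardiac and
respiratory columns are deliberately *not* orthogonalized: shared variance
legitimately appears in both single-signal models.

PVE is computed as a partial R²: 1 − RSS(full)/RSS(drift-only), i.e. the
share of drift-projected voxel variance captured by the physiological
columns. Rationale: preprocessing conventionally removes polynomial trends
before modeling, and leaving drift in the denominator would deflate PVE by
an arbitrary scanner-dependent amount. A `denominator="raw"` switch divides
by total raw variance instead. Values are stored as fractions and clipped to
[0, 1]; zero-variance voxels are NaN. Because both single-signal designs are
nested in the joint design (same drift block), PVE(joint) ≥ PVE(cardiac),
PVE(respiratory) holds exactly per voxel.

## Lagged cross-correlation

Physiological series are *not* convolved before cross-correlation — the
analysis makes no assumption about the coupling dynamics. At lag L (positive
= physiology leads), the physiological series is shifted forward by L, the
overlapping segments are linearly detrended, and Pearson r is computed; the
overlap shrinks with |L| and lags with fewer than 30 overlapping samples
return NaN. Default lag grids: −2..+15 TRs for a 1.4 s-TR acquisition
(−2.8..21.0 s; a printed endpoint of 21.4 s is not a TR multiple, so the
grid stops at 21.0 s) and −1..+9 TRs for a 2.4 s-TR acquisition
(−2.4..21.6 s). Tissue-level curves average BOLD within gray/white/ventricle
masks first and can be linearly upsampled (default 0.2 s for the 2.4 s-TR
profile) to resolve sub-TR peak lags; raw r is stored (no Fisher z), with a
Fisher-z option at the group level.

## Group inference

Map contrasts use pooled-variance two-sample t statistics — pooled rather
than Welch so the statistic is exchangeable under the permutation null.
Optional covariates turn the test into the group-indicator t in a per-voxel
linear model. TFCE integrates e(h,v)^0.5 · h² · dh over midpoint thresholds
h_j = (j−½)dh up to the map maximum (dh = max/100 by default,
26-connectivity); the midpoint rule keeps the default within 1% of a 10×
finer integration. Negative effects are enhanced by applying TFCE to −t.
Familywise-corrected p(v) = (1 + #{perm: max-voxel TFCE ≥ TFCE_obs(v)}) /
(n_perm + 1), with label shuffles preserving group sizes exactly; when fewer
distinct assignments than n_perm exist they are enumerated and the test is
exact. 5000 permutations is the fidelity setting; validation experiments use
500 to keep runtimes in minutes, which only coarsens the p-value floor.

Pre/post designs are handled by per-subject post − pre difference maps,
compared between groups with the same machinery. Tissue lag curves are
compared per lag with t tests at both α/n_lags (Bonferroni) and α
(uncorrected), mirroring the dark/light significance convention of lag-curve
plots. Cohort physiological summaries use Welch t (between groups) and
paired t (pre vs post) — Welch for robustness in summary tables, pooled
inside permutations for exchangeability; the asymmetry is intentional.

## Synthetic cohorts

The generator emulates a two-age-group resting-state study; it defines the
package's reference study conditions and is itself tested code.

* **IBI process**: 60/HR plus sinusoidal LF (nominally 0.1 Hz, jittered
  uniformly ±0.02 Hz per subject) and HF (at the breathing frequency)
  modulation plus a small AR(1) broadband jitter (SD 0.01 s). The per-subject
  LF frequency jitter reflects that the LF rhythm is a band, not a line, and
  keeps group-level cross-correlation peaks identifiable rather than
  periodic.
* **PPG**: one raised-cosine pulse (0.4 s) per beat — the pulse shape only
  needs to be detectable, so the simplest parameter-free choice is used.
* **Respiration**: quasi-sinusoid at the breathing rate with slow amplitude
  modulation; **capnograph**: per-breath plateau values around the mean CO₂,
  gated by respiratory phase (high during exhalation) and delayed by a known
  shift (default 2 s) that the alignment step must recover.
* **BOLD**: per voxel, a weighted sum of response-convolved, latency-shifted,
  gain-scaled physiological drivers + Legendre drift + AR(1) noise
  (coefficient 0.3 — autocorrelated noise makes correlation significance
  behave realistically; stationary SD 1). Latency is applied by shifting the
  convolved regressor on the fine grid before TR sampling, as a delayed
  vascular response would appear. The per-voxel driver amplitude solves a
  quadratic so that var(signal)/var(signal + noise) equals the requested
  `true_pve` *exactly* on the realized series; `true_pve` is therefore the
  drift-free variance fraction, matching how PVE is measured. Tissue masks
  are nested shells (ventricles/white/gray) with baseline fractions
  0.3/0.2/0.4 scaled by the group coupling gain and a ±10% subject jitter.
* **Age defaults** (free parameters chosen once to encode the qualitative
  directions the pipeline should recover, not published magnitudes): old
  group has coupling gain 0.5 vs 1.0, +2 s latency, halved LF/HF amplitudes,
  HR 67 vs 69 bpm, breathing 15.5 vs 17.5 bpm, CO₂ 40 vs 39 mmHg. An
  intervention effect (+0.2 gain, −1 s latency) applies to the post session
  of "Osc+" subjects.

Everything is deterministic given (seed, subject, session); cohorts are
written as gzipped NIfTI (deterministic gzip: byte-identical across runs),
BIDS-style physio TSV + JSON sidecars, a CSV manifest and a ground-truth
table.

What the generator does **not** emulate: head motion, multi-echo artifacts,
spatial autocorrelation of anatomy, neuronally driven networks, vigilance
drift, or measurement noise on the physiological channels beyond what the
estimators need. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not robustness to every
artifact of real recordings.

## Validation experiments (reference conditions)

`boldphysio.validation` fixes the study conditions used by the test suite
and the reproduction script:

* PVE recovery: 200 voxels per designed fraction {0, 0.1, 0.3, 0.5}, 404
  volumes, TR 1.4 s; overall mean absolute error < 0.05 with exact
  nested-model monotonicity.
* Lag recovery: latencies {0, 2.8, 5.6} s, 50 noise seeds, target r 0.6;
  peak-|r| lag on the nearest grid lag in ≥ 95% of voxels.
* FWE calibration: 60 replicate null cohorts (15/group, 6×6×6, 64 volumes,
  500 permutations); familywise false-positive rate at α = 0.05 within
  [0.01, 0.10]. Sixty replicates keep the Monte-Carlo granularity of the
  rate estimate (1/60) well inside that band.
* Power: coupling gain 1.0 vs 0.25, 15/group; ≥ 80% of truly coupled voxels
  at corrected p < 0.05.
* Age-direction replication: 10 cohorts at the documented defaults; young >
  old mean PVE at coupled voxels and a later old gray-matter peak lag
  (measured on 0.2 s-upsampled tissue curves, since the 2 s latency shift
  straddles cells of the raw 1.4 s lag grid) in ≥ 90% of replicates.
* Determinism: two full pipeline runs on a 4-subject cohort are
  byte-identical.

These sizes are the package's chosen desk-scale reference conditions; all
scale with their parameters.

## Numerical conventions and edge cases

* Quantiles: linear interpolation of order statistics, everywhere.
* Variances in the exact-PVE scaling: population (ddof = 0) sample moments.
* TFCE monotonicity (pointwise larger map ⇒ pointwise no-smaller TFCE) holds
  for a shared threshold grid; with per-map dh = max/100 two maps use
  different grids and tiny integration differences can appear.
* Degenerate inputs raise typed errors: flat PPG ("no cardiac rhythm"),
  degenerate RV distributions, < 2 capnograph breaths, rank-deficient
  designs (offending columns named), non-finite TFCE inputs, unmatched
  pre/post subjects (ids listed).
* Zero-variance voxels are masked (NaN) rather than fitted.

## Known limitations

* Response functions are fixed and population-level; no subject- or
  age-specific response estimation (deliberately out of scope).
* The automated IBI artifact rule approximates, but is not identical to,
  interactive visual cleaning.
* PVE of the single-signal models overlaps (shared variance is not
  partitioned); interpret sums with care.
* Permutation tests assume exchangeable subjects under the null; covariate
  handling refits the model per shuffle but does not implement
  residual-permutation schemes.
* The lag-grid endpoint convention truncates to TR multiples; late-lag
  analyses (e.g. 30.8–39.2 s) extend the same grid rather than matching
  non-multiple printed endpoints.
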