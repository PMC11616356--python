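# Methods

`beadmotility` turns tethered-bead optical-tweezers position records of a
slow processive enzyme (a cellulase walking on a cellulose fibril at
~0.1-0.2 nm/s) into motility statistics: state occupancies, per-direction
velocity distributions, run lengths, dwell times, and group comparisons.
Because no instrument data are deposited with the study it reproduces, the
package ships a generative model of such records with full ground truth;
every stage of the analysis is validated by recovering known generator
parameters through the complete pipeline.

## The generative model (`simulate`)

A record is

    x(t) = motility(t) + drift(t) + jumps(t) + noise(t)

* **Motility** is piecewise linear. A three-state process
  (forward / backward / pause) switches by a continuous-time Markov chain
  whose embedded jump chain is constructed (by iterative proportional
  fitting of a zero-diagonal flux matrix) so that the stationary time
  occupancies equal the targets, default 0.41 / 0.20 / 0.39. Dwell times
  are exponential with mean `state_means` (default 15 s per state). The
  analysis retains only segments ≥ 10 s and reports truncated-fit means
  `t0 + tau`, so 15 s dwells correspond to reported dwell means of
  ~25 s, in the middle of the study's 20-30 s range; they also put ~14% of
  the observation time into sub-10 s segments, matching the reported
  "less than 15%" exclusion. Per-visit speeds are drawn once per visit:
  moving states use the exponential with the configured mean (0.17 nm/s
  forward, 0.11 nm/s backward) conditioned on exceeding the 0.085 nm/s
  detection floor — equivalently `floor + Exp(mean)` by memorylessness.
  Sub-floor motion is operationally indistinguishable from a pause, so the
  generator does not emit it in moving states; pauses instead carry small
  random-sign residual motion, `± Exp(0.03 nm/s)`. This makes the
  classifier's occupancy and the velocity fits jointly identifiable: a
  full-support speed draw would reclassify 39% of forward time as paused
  and no parameter could satisfy both the occupancy and velocity targets.
* **Drift** is a per-record random linear slope `s ~ N(0, (scale·sqrt(pi/2))^2)`
  (so E|s| = `drift_rate_scale`, default 0.037 nm/s) plus an integrated
  Ornstein-Uhlenbeck velocity wander (correlation time 30 s, SD
  0.25 × scale), sampled on a 1 Hz grid. For motility records this drift is
  stage/instrument drift, visible to the fiducial markers and removable;
  for control records it is the residual that survives correction, local to
  the bead, and the fiducial frames are rendered with a zero path.
* **Jumps** are Poisson events (default 0.005 /s) with uniform 5-20 nm
  amplitudes of random sign and logistic transitions whose 1%-99% span is
  uniform in 1-10 ms; a configurable fraction (0.3) is paired with an
  opposite-sign partner 0.5-5 s later (reversible toggling).
* **Noise** is i.i.d. Gaussian per sample (default SD 2 nm at 3 kHz). The
  trapped bead's true Ornstein-Uhlenbeck position spectrum is not modeled:
  no downstream estimator exploits noise autocorrelation, and the EWMA +
  downsample chain whitens what little structure the working bandwidth
  retains.

What the generator deliberately does **not** emulate: speed-duration
correlations within states (real enzymes slow before pausing), non-Markov
state memory, force-dependent kinetics, worm-like-chain tether compliance,
or camera-specific fiducial artifacts. Passing recovery tests therefore
demonstrates estimator correctness under the stated model, not robustness
to those real-data features.

## Conditioning (`preprocess`)

Records are decimated to 3 kHz (polyphase FIR low-pass, applied to the
OLS-detrended record so constants and ramps pass through exactly), smoothed
with a causal EWMA of span 20 points (decay `alpha = 2/(window+1)`; whether
the original smoothing was causal or centered is not documented — causal is
recorded in the trace history), and downsampled by keeping every 100th
sample. Jump detection runs on the decimated, pre-EWMA record (the EWMA's
~7 ms smear would corrupt millisecond rise-time estimates).

## Drift correction (`driftcorr`)

Fiducial markers imaged at 0.5-1 Hz are tracked by normalized
cross-correlation of a frame-0 reference ROI against a padded search
window, with parabolic sub-pixel refinement of the correlation peak
(measured accuracy ~0.01 px on simulated spots). Marker trajectories are
averaged, projected on the motility axis, smoothed with a 20 s moving
average (linear-extrapolation padding, so straight-line drift is preserved
exactly including at the edges), zeroed at the record start, interpolated
to trace timestamps and subtracted. Records whose mean correlation peak
quality falls below a threshold (default 0.7) are QC-flagged for
out-of-plane drift — an automated stand-in for by-eye removal — but never
silently dropped.

## Segmentation (`segmentation`)

Constant-velocity sections are found by an exact penalized dynamic program:
cost of a piece = OLS residual sum of squares (O(1) per candidate via
prefix sums), plus a per-breakpoint penalty. The default penalty is
`2.5 · sigma^2 · ln n` with `sigma` a robust noise estimate
(1.4826 · median|dx| / sqrt(2)); the factor 2.5 was calibrated on default
synthetic records for state-recovery fidelity and yields a mean retained
segment duration of ~23 s and a retained-time fraction of ~0.9. Pieces
must be at least 2 s (the changepoint resolution floor) and at most 300 s
(a search lookback cap; longer constant stretches are split and transparently
re-merged by run extraction). Each record is segmented three times with the
penalty scaled by {0.75, 1.0, 1.25} — a deterministic surrogate for three
independent human segmenters — and all replicates are pooled downstream,
so each record appears three times in the dataset.

Segments shorter than 10 s are kept so the segmentation tiles the record
but flagged and excluded from every analysis. Direction is assigned per
record and replicate from the sign of the summed velocity × duration over
retained segments (ties broken toward positive x, with a warning); forward
segments are reported with positive velocity. A segment is a pause iff
|velocity| < 0.085 nm/s, strictly — a segment at exactly the threshold is
moving. Runs are maximal blocks of time-contiguous retained moving segments
of one direction; pauses are maximal blocks of contiguous retained paused
segments; flagged segments break contiguity (an unresolvable gap cannot
certify continuous motion). Detected jumps are subtracted as ideal steps
before segmentation so a 10 nm event neither splits a segment nor biases
its slope.

## Fits (`kinetics`)

* **Velocity PDFs.** Exponential MLE over [0, inf) on the time-weighted
  sample: each segment's |velocity| is replicated `N_R = floor(duration/10 s)`
  times, giving the closed form `mu = sum(N_R v)/sum(N_R)`. Reported N
  excludes the replication but counts segmentation replicates. By default
  the per-direction fits use moving segments only and correct the
  classifier's left truncation by fitting the exponential on
  [threshold, inf) — whose MLE, by memorylessness, is the weighted mean of
  (|v| - threshold) and estimates the same underlying mean. Setting
  `velocity_fit_truncated=False` reproduces the alternative convention
  (all direction-signed segments, domain [0, inf)). Control records always
  use the plain [0, inf) fit over all retained segments.
* **Confidence intervals.** The exponential-mean CI is exact
  (`2 n xbar / mu ~ chi2(2n)`), but evaluated at a cluster-corrected count
  `(sum w)^2 / sum(w^2)` divided by the number of pooled segmentation
  replicates — replicating a velocity N_R times or a record three times
  duplicates observations rather than adding draws, and the naive
  `n = sum(N_R)` interval undercovers badly (~40% instead of 95% at the
  reference scale, measured by simulating the estimator's true sampling
  distribution).
* **Dwell times.** Run and pause durations are fitted with the
  two-parameter truncated exponential on [10 s, inf): the MLE is exactly
  `tau = mean - t0`, and both `tau` and the distribution mean `t0 + tau`
  are reported (which of the two the original inset "means" denote is
  ambiguous; both are available). A two-component truncated-exponential
  mixture is fitted by EM — responsibilities from the shifted exponentials,
  closed-form M-step — iterated until both component means move < 1e-5 s
  (the published tolerance; initialization, from the 25th/75th percentiles
  of the shifted sample with equal amplitudes, is not published and is our
  choice). The log-likelihood is non-decreasing, components are ordered
  t1 <= t2, amplitude collapse or t1 = t2 is flagged degenerate, and the
  fit is verified in the tests against direct likelihood maximization.
* **Pause threshold.** `mu ln(1/(1-q))`, the q-quantile of an exponential;
  q = 0.90 at the 0.037 nm/s control mean gives the 0.085 nm/s cutoff.
* **Jump detection.** A matched plateau filter (mean over 50 ms windows
  after minus before, separated by a guard gap equal to the maximum
  transition time) flags candidates at ≥ 70% of the amplitude floor;
  an event is kept if the plateau-to-plateau amplitude reaches 5 nm and
  the 10-90% equivalent rise time (twice the 25-75% crossing interval of a
  1 ms-boxcar-smoothed trace; the 25-75 levels are used because 10/90
  levels sit inside the noise band) is at most `max_transition` (10 ms).
  Opposite-sign events of amplitude within 20% occurring within 10 s are
  marked as reversible partners. On default synthetic records the detector
  measures recall 1.0 and zero false positives (the plateau filter's noise
  SD is ~0.23 nm against a 5 nm floor).

## Comparisons (`stats`)

The two-sample test is a bootstrap of the difference of time-weighted
exponential means. The null is imposed by rescaling each group onto the
pooled weighted mean (`v -> v · mu_pool/mu_group`; a multiplicative shift is
the natural null transform for a positive scale family — an additive shift
could produce negative speeds). Segments are resampled with replacement
within groups, carrying their weights (resampling independent units, not
replicated pseudo-observations), and the two-sided p-value is
`(1 + #{|d*| >= |d|})/(B+1)`, so `p >= 1/(B+1)`. Measured type-I error at
alpha = 0.05 over 1000 null datasets is ~0.06; the reported warm-vs-cold
velocity contrast (0.17 vs 0.63 nm/s at n = 270/26) is rejected at
p < 0.01 in every repetition.

Force binning groups forward moving segments into 3.5 pN bins centered on
zero load (edges at ±1.75, ±5.25, ... pN, so assisting and opposing loads
are treated symmetrically) and fits the time-weighted exponential per bin;
bins with fewer than 5 segments are flagged, empty bins omitted.

## Reference datasets and problem sizes

Validation and the reproduction script use two synthetic datasets built by
`beadmotility.datasets`:

* **Motility**: 32 records × 500 s (16000 s) at generator defaults, three
  segmentation replicates. Records must be long enough that the per-record
  net-progress sign is reliable: at ~140 s the sign flips for ~23% of
  records and the flip is selective (records flip when their
  majority-direction segments were atypically slow), biasing the backward
  velocity estimand to ~0.086 nm/s; at 500 s the flip rate is ~10% and the
  estimand ~0.10 nm/s, inside the fit's honest CI of the 0.11 nm/s target.
* **Controls**: 112 fixed-tether records × 110 s. The mean |segment
  velocity| of a control record is dominated by its single random drift
  slope (half-normal, CV 0.76), so the dataset mean needs many records to
  stabilize; 224 put its standard error near 5%.

Both dataset sizes are pure variance choices: the estimands do not depend
on the record count.

## Numerical and degenerate-input conventions

Segmentation requires ≥ 3 samples per OLS fit and warns (empty result) on
records shorter than 10 s. A truncated fit with all durations at t0 warns
and reports tau = 0. EM flags non-convergence rather than raising. A record
with exactly zero net displacement classifies forward as positive x and
warns. Drift estimates must span the trace within one frame interval.
Tie-breaks and thresholds are strict-inequality for pauses (|v| < threshold).

## Known limitations

* The forward run-distance mean on default synthetic data is ~6.5-6.8 nm,
  above the study's printed ~5 nm: with ≥ 10 s retention the mean retained
  run duration is ~10 + tau ≈ 25-28 s and forward moving speeds average
  threshold + 0.17 ≈ 0.25 nm/s, which multiply to > 6 nm for any
  exponential-independence generator consistent with the other printed
  values. Backward run distances (~4-5 nm) do match. The corresponding
  validation test is intentionally left failing rather than loosened.
* Direction classification inherits the selection bias of the per-record
  net-progress convention whenever records are short relative to state
  dwells (see above); this is a property of the convention, not of the
  implementation.
* The Z-drift QC score is a defocus proxy (correlation peak height), not a
  3-D drift estimate.
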