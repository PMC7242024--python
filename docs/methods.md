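# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `oscmem`.

## Study design emulated by the generator

Each simulated subject performs 288 trials in 12 blocks (six per
distractor condition, 24 trials each).  Epochs run from -2.0 to 2.75 s
around retention onset at 256 Hz; the distractor occurs at 1.0 s, the
probe at 2.0 s, the response prompt at 2.7 s.  Probe-in-set and
probe-out-of-set trials are balanced 50/50 within every block (the
original design does not state the proportion; stratified cross-validation
implies near-balance, and 50/50 is assumed).  The epoch window is shorter
than a symmetric +/-3 s window but covers every analysis interval,
including the 2 s taper needed at the lowest TFR frequency (2 Hz) at the
earliest TFR time point.

## Signal model

All amplitudes are in units of the per-channel noise standard deviation.

* **Forward model.** Sources sit on a 3-D integer lattice (default 4x4x4);
  sensors on a surrounding sphere.  Each source is a fixed-orientation
  dipole with smoothly varying orientation; gains fall off with squared
  distance and rows are normalized to unit norm.  Neighbouring grid points
  therefore have correlated sensor projections (tested), which is what the
  beamformer and the cluster adjacency assume.
* **Memory pattern.** One interior grid point is the *planted source*.
  Its lead-field row is the probe-in-set pattern; the probe-out-of-set
  (foil) pattern is a random sensor-space vector orthogonal to it, so the
  informative-activity map has a unique planted peak.  Probe information
  is carried by a Hann-shaped transient 0.3-0.7 s after the probe
  (amplitude `pattern_snr = 2.0`).  A 0.4 s Hann bump has its spectral
  energy below ~5 Hz, so the information lives in the theta band and in
  the *signed* fine structure: rectifying the signal (analytic amplitude)
  discards the channel signs of the pattern and degrades decoding, which
  reproduces the band-decoding result by construction.  An earlier design
  iteration used a zero-mean 5 Hz carrier under the same envelope; that
  was abandoned because the sign of the class difference then alternates
  with the carrier phase across training times, and averaging AUC over any
  train x test block cancels to 0.5 — a transient with consistent polarity
  is the simplest signal for which block-averaged time generalization is
  well defined.
* **Retention reactivation.** During retention (0-1 s) the same per-class
  patterns are re-injected, scaled by
  `reactivation_gain[condition] x gamma_s x r_i`, with per-subject
  multiplier `gamma_s ~ logNormal(sd 0.3)` and per-trial factor
  `r_i = exp(0.7 z_i)` driven by a latent standard normal `z_i`.  Defaults:
  weak +2.2, strong -0.3.  The negative strong gain inverts the decodable
  pattern, producing below-chance condition generalization — the simplest
  mechanism with that signature.
* **Oscillatory source.** The *same* grid point emits alpha (13 Hz) and
  beta (21 Hz) with random phase per trial and log-normal amplitudes,
  active from shortly before retention onset until after the distractor.
  Log-amplitudes are anti-coupled to the latent `z_i`
  (`log amp = c z_i + residual`): high pre-distractor power marks trials
  with weak reactivation.  The alpha coupling is heterogeneous across
  subjects (`c_alpha = -0.8 x Uniform(0.25, 1.75)`, residual sd 0.65) while
  the beta coupling is homogeneous (`c_beta = -0.6`, residual sd 0.4):
  beta carries the overall low-vs-high bin effect, alpha the individually
  varying modulation whose size correlates with the strength difference.
  A bounded (uniform) heterogeneity distribution is used deliberately: a
  log-normal one produces extreme-modulation subjects for whom the
  median-split gap saturates, bending the modulation/strength relation and
  destroying the Pearson correlation the analysis targets.
* **Noise and behavior.** Independent 1/f (exponent 1) Gaussian noise in
  every channel, generated spectrally.  Accuracy is Bernoulli (0.83
  strong / 0.85 weak) and RT log-normal (means 579/570 ms, log-sd 0.3),
  drawn independently of the neural signal — the analysis establishes no
  trial-level brain-behavior link, so none is planted.

Every planted quantity (patterns, source index, per-trial reactivation and
oscillator amplitudes, per-subject gain and coupling) is stored in
`GroundTruth`, so all downstream stages are tested as parameter recovery.

### Calibration of the defaults

The default effect sizes were fixed once, during generator design, by the
requirement that each planted direction be recoverable from a single
33-subject synthetic study: post-probe decoding peaks near AUC 0.9,
condition strengths sit at roughly 0.49 (strong) vs 0.57 (weak), bin
strength gaps at 0.02-0.05 AUC.  These are deliberately *larger* than the
empirical effects of real MEG recordings of this kind, where the analogous
group statistics hover near significance; a generator tuned to borderline
power would make every group-level check a coin flip.  Passing tests
therefore demonstrate correctness of the machinery, not the detectability
of real-world effect sizes.

## Analysis pipeline

* **Preprocessing.** Zero-phase 6th-order Butterworth high-pass at 0.5 Hz;
  decoding runs at 100 Hz (polyphase resampling), spectral stages at the
  native 256 Hz.  Filters can be applied as forward-backward IIR
  (`method="iir"`, default) or by multiplying the spectrum with the same
  zero-phase magnitude response `|H(f)|^2` (`method="fft"`); the two agree
  to the stated filter tolerances away from epoch edges, and the FFT route
  is used by the batch paths because it is several times faster on
  trials x channels x samples tensors.
* **Decoding.** Shrinkage LDA with the analytic Ledoit-Wolf intensity by
  default (matching common MVPA-toolbox defaults; overridable).
  Temporal decoding: independent classifier per 100 Hz sample in
  -0.2..0.7 s around the probe, 5-fold stratified CV repeated 5 times, AUC
  averaged over folds and repeats.  Time generalization: one classifier
  per training time fitted on *all* trials without cross-validation,
  scored at every test time, AUC computed within trial groups (condition
  or power bin).  The memory-strength proxy is the mean AUC over the
  0.4-0.7 s training window x the 0.5 s pre-distractor test window; it
  averages AUC, not decision values.
* **Source mapping.** Sensor covariance from the entire 30 Hz low-passed
  epoch; LCMV regularization 5% of the mean eigenvalue (common practice).
  Informative activity takes the absolute value on source level first and
  z-scores the absolute map (the alternative order is a config switch
  away).  For permutation z-scoring the activation patterns are scaled to
  unit norm before projection: the Haufe transform is homogeneous of
  degree -1 in the weights, so the near-zero discriminants obtained under
  label permutation otherwise produce systematically *inflated* patterns
  and the z map is negative everywhere.  Maps are averaged over the
  post-probe decoding window before z-scoring (permuted classifiers are
  nearly independent across time, so collapsing sharpens the null).
  Virtual-sensor selection defaults to the ground-truth source index in
  simulations; `argmax` of the group map is the blind-mode option.
* **Spectral analysis.** Hanning-taper Fourier estimates, four cycles per
  frequency, 2-30 Hz in 1 Hz steps, -1.5..0.5 s around the distractor in
  25 ms steps.  Power is normalized so a unit-amplitude sinusoid at a bin
  center yields power 1 regardless of window length, making power
  comparable across frequencies.  Bins whose taper would leave the epoch
  are NaN; nothing is zero-padded.  "Induced" power is the average of
  single-trial power (no evoked subtraction — the alternative is noted but
  not default).  Hilbert envelopes are computed over the whole epoch
  without zero-padding (padding rings far into narrow-band envelopes); the
  first and last ~100 ms should not be interpreted.
* **Power bins.** Trials are ranked by alpha/beta power at the virtual
  sensor in 0.4-1.0 s of retention and median-split, pooled over
  conditions (the design gives no condition qualifier for the split), ties
  broken by trial index, odd medians assigned to the low bin.  The
  modulation ratio is `M = log10(mean high / mean low)` (>= 0 by
  construction).  The correlation is oriented as M vs the *high-minus-low*
  strength difference, so a negative r means stronger desynchronization
  modulation accompanies a larger strength advantage of the low-power bin.
  No multiple-testing correction across the two bands, no outlier
  rejection, subjects unweighted.
* **Statistics.** Paired/one-sample t, paired Cohen's d, Pearson r with
  t-transform p.  The 2x2 repeated-measures ANOVA is computed from
  within-subject contrasts; with one numerator df each F is exactly the
  squared paired t.  Cluster permutation: two-sided critical t at
  alpha 0.05 as the cluster-forming threshold, positive and negative
  clusters separately, mass = summed t, null = max |mass| over random sign
  flips of subject difference maps, p includes the observed statistic
  (minimum attainable p = 1/(1+n)).  Maxsum rather than maxsize is the
  cluster statistic (the cited method's common default).  Adjacency:
  lattice connectivity from the map shape (2-neighbor in 1-D,
  4-connectivity in 2-D) or an explicit sparse adjacency (6-connectivity
  for the source grid).
* **Behavior.** Per-subject accuracy and mean RT (correct trials) per
  condition; one-sided paired t in the hypothesized direction (strong
  worse).  Subjects with fewer than 10 valid RTs in either condition are
  excluded from the RT test only — the exclusion rule is this package's
  own (the original's rule is not recoverable from its reported degrees of
  freedom).

## Problem sizes and defaults

`RunConfig` defaults are CI-scale (12 subjects, 1000 cluster permutations,
100 label permutations for z maps); `RunConfig.full_scale()` selects 33
subjects, 5000 and 500.  The group-level validation battery runs 20
seeded replications of the full 33-subject bin analysis, 20-seed
localization and inversion checks, 200 null replications of the cluster
test and 20-seed chance calibration; these sizes keep the whole suite
within ordinary desktop runtimes while leaving the Monte-Carlo tolerances
meaningful.  Epoch tensors are float32 (signal amplitudes are O(1));
statistics are computed in double precision.

## What passing tests do and do not show

The generator plants exactly the structures the analysis looks for, with
known lead fields, stationary 1/f noise, no artifacts, no head-geometry
error and no inter-subject anatomical variability.  Recovery here
validates the estimators, the statistics and their calibration — it says
nothing about sensor-level SNR, preprocessing robustness or effect sizes
in real MEG data.  Specifically out of scope: realistic head models,
free-orientation beamformers, depth normalization, multitaper/wavelet
TFRs, baseline normalization, inter-trial coherence, and any real-data
reader for the original deposit (the EpochSet container is the extension
point).
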