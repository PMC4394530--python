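# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `ldaep` package: what each stage computes, why its
defaults are what they are, and what the synthetic validation data do and
do not establish about real recordings.

## The LDAEP statistic

The loudness dependence of auditory evoked potentials (LDAEP) quantifies
how strongly the auditory N1 and P2 components grow with stimulus
intensity. For each of five tone intensities *I* ∈ {55, 65, 75, 85, 95} dB
SPL, the per-intensity averaged evoked response at the vertex electrode Cz
yields an N1 amplitude (the signed minimum in 80–130 ms post-stimulus), a
P2 amplitude (the maximum in 130–230 ms) and the peak-to-peak N1/P2
amplitude (P2 − N1). The LDAEP is the ordinary-least-squares slope of
amplitude on intensity,

    LDAEP = Σ(I − Ī)(A − Ā) / Σ(I − Ī)²   [µV/dB],

computed separately for N1 (typically negative), P2, and N1/P2. Because
OLS is linear in the response, slope(N1/P2) = slope(P2) − slope(N1) holds
identically; the suite asserts this per subject and corroborates it on all
four published group-mean triples. Window endpoints are inclusive;
amplitude ties break to the earliest latency; peaks come from averaged
responses (5 regression points), not single trials. A pharmacological
literature treats a *high* LDAEP as a marker of *weak* central
serotonergic neurotransmission, which is why the statistic is studied as a
predictor of response to serotonergic antidepressants.

## Preprocessing

Fixed stage order: band-pass filter → ocular correction → re-reference →
epoch → artifact rejection → per-intensity averaging. All stages are
deterministic; identical input gives a bit-identical result.

* **Filter.** 1–30 Hz Butterworth, 4th order, applied forward–backward
  (`sosfiltfilt`), hence zero phase: a symmetric transient's latency is
  preserved to ±1 sample (tested). The band edges are the study constants;
  order and realization are this package's choice. `band_hz=None` skips
  the stage (see *Noiseless identity* below).
* **Ocular correction.** Regression-based: blink segments are detected on
  the EOG channels (|EOG| > 50 µV, dilated ±150 ms), per-channel
  propagation coefficients of EEG on the demeaned EOG signals are
  estimated by least squares *on those segments only* (demeaning over the
  segments supplies the intercept) and subtracted everywhere. With no
  blink segment the recording passes through unchanged, so a clean
  recording is untouched. EOG channels are never modified. Correction
  precedes rejection (order config-exposed).
* **Reference.** Default linked-mastoid (M1/M2 mean subtracted from all
  EEG channels), switchable to common-average; EOG is never re-referenced.
  The reference is a documented assumption, not a reconstruction of the
  original lab's montage.
* **Epochs.** Window −100…+400 ms, inclusive bounds (501 samples at
  1 kHz), baseline −100…0 ms subtracted per channel. Events too close to a
  recording edge are kept as flagged epochs (`reason="edge"`), never
  silently dropped.
* **Rejection.** An epoch is rejected iff any *EEG* channel exceeds the
  threshold (default 70 µV — the study's printed "70 mV" is treated as a
  typographical error, since 70 mV is physiologically impossible) anywhere
  in the window. EOG channels are not screened (blinks live there by
  design). A per-intensity rejection rate ≥ 5% logs a warning; an
  intensity losing all epochs is a hard error.

## Source analysis

* **Forward model.** A 3-shell concentric-sphere conductor (brain/skull/
  scalp, radii 0.89/0.97/1.00 × 90 mm, conductivities 0.33/0.0042/0.33
  S/m), sources on a "cortical" shell at 70 mm on a Fibonacci lattice with
  the lower polar cap removed, radial orientation in the default fixed
  mode (a free-orientation mode with 3×3 standardization blocks is
  available). The analytic spherical lead field is computed through MNE's
  sphere model; rows are average-referenced; the mastoids are excluded
  from the inverse. This reduced model deliberately replaces a realistic
  6000-voxel template-head model: the estimator mathematics is identical
  and the model is small enough to test exhaustively, but localization is
  only sector-accurate — the "BA41" regions of interest are *geometric
  proxies*: lateral sectors within 25° of the left/right
  superior-temporal directions.
* **Inverse.** Standardized minimum norm (the sLORETA estimator): with
  lead field L and average-reference projector H,
  T = Lᵀ(LLᵀ + αH)⁺, R = TL, and the standardized power of source *j* at
  sensor vector x is (Tⱼx)²/Rⱼⱼ (fixed orientation) or the quadratic form
  with the inverted 3×3 diagonal block (free orientation). Sources with a
  numerically singular standardization block are flagged invalid (NaN),
  never silently zeroed. This standardization has exactly zero
  localization error for any noiseless single grid source at any α ≥ 0 —
  the suite verifies this exhaustively over every grid point, with α = 0
  and with the default α.
* **Regularization.** α = trace(LLᵀ)/(n_sensors · SNR²) with SNR = 10 by
  default; the modelled study never states its regularization, so this is
  a package default, config-exposed.
* **Source LDAEP.** Standardized power is averaged over each ROI and time
  window and regressed on intensity with the same OLS as the scalp slope.
  Because the study reports distinct N1/P2/N1-P2 source values while
  describing only a single 60–240 ms average, the package computes and
  labels all three windows (80–130, 130–230, 60–240 ms) without asserting
  which corresponds to which published value. Standardized-power units
  are arbitrary; signs and ratios are meaningful, magnitudes are not
  comparable across head models. Amplifier gain cancels end-to-end: data
  generated through a globally scaled lead field and inverted with it give
  identical slopes (tested).

## Synthetic data

The generator defines the validation conditions; nothing downstream is
tested against real EEG.

* **Stimuli.** 1000-Hz, 80-ms tones (10 ms rise/fall) at the five
  intensities in seeded-random order, each intensity equally often; the
  inter-stimulus gap (offset-to-onset) is uniform on 500–900 ms, so
  onset-to-onset intervals span 580–980 ms. Onsets snap to the 1-kHz
  sample grid.
* **Evoked components.** Gaussian-windowed N1 (negative, default latency
  100 ms) and P2 (positive, 180 ms) deflections, σ = 15 ms. Vertex
  amplitude at intensity *I* is baseline + slope × (I − 75). The baselines
  are anchored to the slopes (n1₇₅ = −4 + 20·slope_N1, p2₇₅ = 5 +
  20·slope_P2, i.e. linear growth anchored at the lowest intensity): with
  fixed baselines and realistic slopes the components would change sign
  inside the intensity range and the window-extremum measurements would
  clip. The scalp pattern is a bilateral superior-temporal tangential
  source pair projected through the package's own spherical lead field
  and normalized so the linked-mastoid-referenced Cz gain is exactly 1 —
  the same dataset therefore exercises the inverse, and ground-truth
  slopes are defined at Cz under the default reference (switching the
  reference rescales amplitudes by a known factor).
* **Noise and artifacts.** Per-channel 1/f-spectrum noise with a 10-Hz
  alpha bump (default 10 µV SD, a typical broadband scalp-EEG level);
  blinks at 12/min as 350-ms, ~150-µV deflections on the vertical EOG with
  distance-decaying frontal propagation; a Bernoulli fraction of events
  (default 2%) receives a 150–250 µV transient on a random channel. With
  4% artifact epochs the measured rejection rate is statistically
  indistinguishable from 4% (binomial check), inside the study's <5%
  regime.
* **Amplitude scale.** The published slope values (group means 0.62 and
  1.89 µV/dB) would, taken literally as vertex peak slopes, imply ±38 µV
  evoked swings over 55–95 dB — incompatible with a 70 µV rejection
  threshold and with typical AEP amplitudes. The clinical table therefore
  carries slopes on the published scale (used for all cohort statistics),
  while the EEG simulator maps them to the vertex with a fixed factor
  (`eeg_slope_scale = 0.15`), keeping averaged N1/P2 amplitudes in the
  low-µV range. The mapping is monotone, so the median split and all
  rank-based structure are unaffected; EEG-level recovery tests compare
  against the scaled truth.
* **Cohort.** 41 subjects by default: 7 male / 34 female, 15 first- / 26
  recurrent-episode, 10 smokers, 21 on hypnotics (exact rounded counts
  under a seeded permutation), ages ~N(40, 15). Subjects split 20/21 into
  low/high LDAEP groups with slope distributions 0.62 ± 0.36 and 1.89 ±
  0.52 µV/dB. Percent BDI reduction is drawn per group from a **censored
  normal** on [−50, 100] whose *censored* mean/SD equal the configured
  37.2 ± 40.9 and 70.2 ± 36.2: naive clipping would bias the means by
  several points, and a renormalized truncated normal cannot attain the
  high group's moments on these bounds at all, whereas censoring piles
  boundary mass at 100% — full remission, the clinically real ceiling.
  The parent parameters are solved from the closed-form censored moments.
  BDI_post = round(BDI_pre × (1 − reduction/100)), clipped to [0, 63]
  (BDI is an integer scale); BDI_pre ~ round(N(31, 12.4)) clipped to
  [5, 63].
* **What the generator does not emulate.** Spatially correlated noise,
  non-stationary alpha, latency jitter or habituation across trials,
  muscle/electrode artifacts with realistic spectra, medication
  pharmacokinetics, dropout, or longitudinal LDAEP change. Passing the
  recovery tests shows the estimators are correct under the generative
  model, not that they are robust to everything real EEG does.

## Cohort statistics

Responder: strictly >50% BDI reduction. Remitter: post-treatment BDI
strictly <10. Median split: values strictly below the interpolated sample
median are "low" (41 distinct values → 20 low / 21 high). All tests are
two-tailed, no multiplicity adjustment (the report counts the tests run).

The t statistics (pooled df = n₁+n₂−2; Welch with Welch–Satterthwaite
fractional df), Pearson χ² (no continuity correction — Yates would not
reproduce the published statistic from its counts), Cohen's d (|Δmean| /
pooled SD) and the odds ratios are closed-form in this package, with
scipy's distributions supplying p-values and the scipy implementations
serving as independent oracles in the tests. The "auto" t mode uses a
two-tailed F variance-ratio gate at 0.05 and reproduces the published mix
of integer and fractional dfs. The published "odds ratio" is reproduced
only by the group-odds vs whole-sample-odds definition (1.91 and 0.49);
the conventional cross-product odds ratio of the same counts is 3.91 and
is also reported, labelled as such. The accompanying log-scale 95% CI is a
delta-method approximation treating the two odds as independent; the
study's printed CI (1.02–3.58) is not reproducible from its counts under
any standard error we tried, and is documented here as an open
discrepancy, as is its Cohen's d of 0.8 where the summary statistics give
0.86, and an ANCOVA df of (1, 40) where a two-predictor model on n = 41
has (1, 38). The sex-adjusted comparison is a linear model
`outcome ~ group + sex` with a type-II F for the group term
(statsmodels); its type-I error is verified at ≈5% under a seeded null
simulation. The Kolmogorov–Smirnov normality check uses plug-in sample
mean/SD (the classical variant legacy clinical software reports, known to
be anti-conservative); it is logged, and never switches methods.

## Numerical choices and degenerate inputs

* Noiseless end-to-end identity: with zero noise/blinks/artifacts and the
  filter stage disabled, scalp slope recovery is exact to <1e-6 µV/dB (the
  residual is the N1×P2 Gaussian-overlap term, ~7e-7 at the default
  latency separation). Through the *default 1–30 Hz filter* a transient's
  peak is attenuated by a few percent — an inherent property of
  band-passing, not an implementation error — so filtered-path recovery is
  validated at 5% relative tolerance instead. Both paths are tested.
* Flat waveforms return the degenerate extremum with a `flat` flag; OLS on
  zero-variance responses defines R² = 1 (flat line fits exactly);
  zero-variance t statistics, zero-cell odds tables, constant KS inputs
  and all-identical median splits raise errors rather than returning
  NaN.
* EDF export quantizes to 16 bits over the per-channel range (error ≤ one
  step, verified through MNE's independent reader); event onsets travel in
  a TSV sidecar and round-trip exactly.

## Validation problem sizes

The automated suite runs scaled-down configurations chosen to exercise
every code path with comfortable statistical margins: 50–500 events per
recording, 3–8 simulated subjects per pipeline run, 80–254 source grids,
cohort calibration at n = 4000 (3-SE tolerance), 1000-replicate oracle
and null-simulation checks. Full study-sized runs (41 subjects × 1000
events, 254 sources) are available through the CLI and finish in tens of
minutes on one core.
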