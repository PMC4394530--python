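# ldaep

Scalp and source **LDAEP** (loudness dependence of auditory evoked
potentials) analysis, with the cohort statistics that link pretreatment
LDAEP to antidepressant treatment response, and a synthetic EEG/cohort
generator that provides ground truth for every stage.

The LDAEP is a putative inverse marker of central serotonergic activity:
for tones at five intensities *I* ∈ {55, 65, 75, 85, 95} dB SPL, the
per-intensity averaged evoked response at Cz gives N1 (minimum in
80–130 ms), P2 (maximum in 130–230 ms) and the peak-to-peak N1/P2
amplitude, and the LDAEP is the OLS slope

&nbsp;&nbsp;&nbsp;&nbsp;LDAEP = Σ(I − Ī)(A − Ā) / Σ(I − Ī)²  [µV/dB].

A parallel source-level slope is computed from sLORETA-standardized
current density (minimum-norm estimate standardized by the resolution
matrix, zero localization error for noiseless point sources) averaged
over left/right auditory-cortex proxy regions of a reduced 3-shell
spherical head model. Patients are stratified as responders (>50% BDI
reduction), remitters (post-treatment BDI < 10) and by median split of
the pretreatment N1/P2 LDAEP; group comparisons use Student/Welch/paired
t, Pearson χ² (no continuity correction), group-vs-total relative odds,
Cohen's d, and a sex-covariate general linear model.

**Who it is for:** ERP methodologists who need a fully testable LDAEP
reference pipeline, and anyone reanalysing or power-planning
LDAEP-by-treatment-response designs without access to raw clinical EEG.

## Worked example

Simulate one subject under the default study conditions (1000-Hz tones,
five intensities, 1/f + alpha noise, blinks, 2% artifact epochs), run the
full preprocessing chain (1–30 Hz zero-phase band-pass, regression blink
correction, linked-mastoid reference, −100…400 ms epochs, 70 µV
rejection) and estimate the scalp slopes:

```python
from ldaep import (GroundTruth, generate_stimulus_sequence,
                   simulate_subject_eeg, preprocess_recording,
                   compute_scalp_ldaep, two_sample_t)

seq = generate_stimulus_sequence(500, seed=7)
truth = GroundTruth()            # vertex slopes: N1 -0.06, P2 +0.14 µV/dB
raw = simulate_subject_eeg(seq, truth, seed=7)
evoked = preprocess_recording(raw)
res = compute_scalp_ldaep(evoked)
print(f"true N1/P2 slope : {truth.true_slope_n1p2:+.3f} uV/dB")
print(f"estimated N1/P2  : {res.slope_n1p2:+.3f} uV/dB (R2 = {res.r2_n1p2:.3f})")

r = two_sample_t((16, 0.95, 0.59), (25, 1.47, 0.83), mode="pooled")
print(f"pooled t = {r.value:.3f}, df = {r.df:.0f}, p = {r.p:.3f}")
```

prints

```
true N1/P2 slope : +0.200 uV/dB
estimated N1/P2  : +0.207 uV/dB (R2 = 0.942)
pooled t = -2.175, df = 39, p = 0.036
```

The subject's true intensity-dependence slope (0.200 µV/dB) is recovered
to within the peak-measurement noise at 100 epochs per intensity, and the
regression is nearly linear (R² = 0.94). The t-test compares the
pretreatment N1/P2 LDAEP of two response groups given as (n, mean, SD)
summaries: the responder group's higher slope is significant at p = 0.036.

A full simulated study — cohort generation, per-subject EEG, scalp and
source LDAEP, stratification and all group statistics, written as CSV +
markdown report with a provenance hash — is one call (or
`ldaep run-all --seed 1 --n-subjects 41 --out out/` on the command line):

```python
from ldaep import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(seed=1, n_subjects=8, n_events=300), "out/")
```

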