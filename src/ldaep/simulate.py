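"""Synthetic auditory-ERP EEG and clinical-cohort generator.

Everything downstream (preprocessing, scalp/source LDAEP, cohort statistics)
is testable against known ground truth because this module controls it:

* tone sequences — 1000-Hz, 80-ms tones at five intensities (55–95 dB SPL)
  in seeded random order with a 500–900 ms offset-to-onset gap;
* per-subject raw EEG — N1/P2 deflections at the vertex whose amplitudes
  grow linearly with dB at the subject's true slope, projected to the scalp
  through the package's own spherical head model, on top of 1/f + alpha
  background noise, blink contamination and occasional high-amplitude
  artifact epochs;
* clinical cohorts — demographics, medication metadata and pre/post
  depression scores whose percent reduction is coupled to the subject's
  LDAEP group, with group means/SDs matching the reference study's
  low/high-LDAEP stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sstats

from . import source as source_mod
from .montage import EEG_CHANNELS, EOG_CHANNELS, MASTOIDS, channel_positions, default_montage
from .preprocess import RawRecording

DEFAULT_INTENSITIES: tuple[int, ...] = (55, 65, 75, 85, 95)
SAMPLE_RATE_HZ: float = 1000.0
TONE_DURATION_S: float = 0.080
ISI_GAP_S: tuple[float, float] = (0.5, 0.9)  # offset-to-onset gap


# --------------------------------------------------------------------------
# stimulus sequences
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSequence:
    """Tone onsets (s) and intensity labels (dB SPL) of one run."""

    onsets: np.ndarray
    intensities: np.ndarray
    tone_duration_s: float = TONE_DURATION_S
    carrier_hz: float = 1000.0
    rise_fall_s: float = 0.010

    @property
    def n_events(self) -> int:
        return len(self.onsets)


def generate_stimulus_sequence(
    n_events: int,
    seed: int,
    intensities: tuple[int, ...] = DEFAULT_INTENSITIES,
    isi_gap_s: tuple[float, float] = ISI_GAP_S,
    start_s: float = 1.0,
) -> StimulusSequence:
    """Balanced, randomized tone sequence.

    Each intensity occurs ``n_events // len(intensities)`` times (the
    remainder, if any, is distributed by seeded draw without replacement);
    the order is a seeded permutation. Onset gaps are uniform on the ISI
    range plus the tone duration, snapped to the 1-kHz sample grid.
    """
    if n_events < len(intensities):
        raise ValueError(f"n_events must be >= {len(intensities)}")
    rng = np.random.default_rng(seed)
    reps = n_events // len(intensities)
    labels = np.repeat(intensities, reps)
    extra = n_events - len(labels)
    if extra:
        labels = np.concatenate([labels, rng.choice(intensities, extra, replace=False)])
    labels = rng.permutation(labels)

    gaps = rng.uniform(*isi_gap_s, size=n_events - 1) + TONE_DURATION_S
    onsets = start_s + np.concatenate([[0.0], np.cumsum(gaps)])
    onsets = np.round(onsets * SAMPLE_RATE_HZ) / SAMPLE_RATE_HZ
    return StimulusSequence(onsets=onsets, intensities=labels.astype(int))


# --------------------------------------------------------------------------
# single-subject EEG
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Per-subject truth for recovery tests.

    Slopes are µV/dB of the vertex (Cz, linked-mastoid reference) peak
    amplitudes; baselines are the amplitudes at the 75-dB midpoint. When
    left as None the baselines are derived from the slopes
    (``-4 + 20 * slope_n1`` and ``5 + 20 * slope_p2``), which anchors the
    linear growth at the lowest intensity so N1 stays negative and P2
    positive over the whole 55–95 dB range — otherwise the window-extremum
    peak measurements would clip and the intensity dependence would no
    longer be linear in the generated data.
    """

    true_slope_n1: float = -0.06
    true_slope_p2: float = 0.14
    n1_amp_75_uv: float | None = None
    p2_amp_75_uv: float | None = None
    n1_latency_ms: float = 100.0
    p2_latency_ms: float = 180.0
    component_sigma_ms: float = 15.0
    noise_sd_uv: float = 10.0
    blink_rate_per_min: float = 12.0
    artifact_epoch_fraction: float = 0.02

    def __post_init__(self):
        if self.n1_amp_75_uv is None:
            object.__setattr__(self, "n1_amp_75_uv",
                               -4.0 + 20.0 * self.true_slope_n1)
        if self.p2_amp_75_uv is None:
            object.__setattr__(self, "p2_amp_75_uv",
                               5.0 + 20.0 * self.true_slope_p2)

    @property
    def true_slope_n1p2(self) -> float:
        return self.true_slope_p2 - self.true_slope_n1


def aep_scalp_topography(channels: list[str] | None = None) -> np.ndarray:
    """Scalp pattern of the simulated AEP: a bilateral tangential source
    pair in the superior-temporal sectors of the head model, projected
    through the same spherical lead field the inverse uses, and normalized
    so the linked-mastoid-referenced Cz gain is exactly 1."""
    if channels is None:
        channels = list(EEG_CHANNELS)
    roi_dirs = [d / np.linalg.norm(d) for d in source_mod._ROI_DIRECTIONS.values()]
    positions = np.array(
        [source_mod._SPHERE_CENTER + source_mod._SOURCE_RADIUS * d for d in roi_dirs]
    )
    ori = np.tile([0.0, 0.0, 1.0], (2, 1))  # tangential, vertex-pointing
    eeg = [c for c in channels if c not in EOG_CHANNELS]
    gain = source_mod.forward_gain(positions, ori, eeg)
    topo_eeg = gain.sum(axis=1)
    cz = topo_eeg[eeg.index("Cz")]
    m = np.mean([topo_eeg[eeg.index(ch)] for ch in MASTOIDS if ch in eeg])
    topo_eeg = topo_eeg / (cz - m)
    topo = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        if ch in eeg:
            topo[i] = topo_eeg[eeg.index(ch)]
    return topo


def blink_propagation(channels: list[str]) -> np.ndarray:
    """Blink propagation factor per channel: exponential decay with distance
    from the eyes; EOG channels carry the blink itself."""
    eye = np.array([0.0, 0.095, -0.01])
    pos = channel_positions(tuple(channels))
    factors = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        if ch == "VEOGU":
            factors[i] = 1.0
        elif ch == "VEOGL":
            factors[i] = -0.6
        elif ch in ("HEOGL", "HEOGR"):
            factors[i] = 0.15
        else:
            d = np.linalg.norm(pos[ch] - eye)
            factors[i] = 0.45 * np.exp(-d / 0.055)
    return factors


def _gaussian_bump(t_s: np.ndarray, center_s: float, sigma_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_s - center_s) / sigma_s) ** 2)


def _pink_alpha_noise(rng, n_ch: int, n_samp: int, sfreq: float, sd: float,
                      alpha_weight: float = 0.35) -> np.ndarray:
    """Background noise: 1/f spectrum plus a 10-Hz alpha bump, unit-free
    shape rescaled to the requested per-channel standard deviation."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    shape += alpha_weight * np.exp(-0.5 * ((freqs - 10.0) / 1.0) ** 2)
    spec = (rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))) * shape
    noise = np.fft.irfft(spec, n=n_samp, axis=1)
    s = noise.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return noise / s * sd


def simulate_subject_eeg(
    seq: StimulusSequence,
    truth: GroundTruth,
    montage: list[str] | None = None,
    seed: int = 0,
    sfreq: float = SAMPLE_RATE_HZ,
) -> RawRecording:
    """Simulate one subject's raw recording (µV) for a stimulus sequence.

    Each tone adds a negative N1 and positive P2 Gaussian deflection whose
    vertex amplitudes are ``baseline + slope * (intensity - 75)``; noise,
    blinks, and artifact transients are controlled by ``truth``. Identical
    inputs and seed give an identical recording.
    """
    if montage is None:
        montage = default_montage()
    if "Cz" not in montage:
        raise ValueError("montage must contain Cz")
    if sum(ch in EOG_CHANNELS for ch in montage) < 2:
        raise ValueError("montage must contain at least two EOG channels")

    rng = np.random.default_rng(seed)
    n_samp = int(np.ceil(seq.onsets[-1] + 1.0)) * int(sfreq)
    n_ch = len(montage)
    data = np.zeros((n_ch, n_samp))

    # evoked component: template per event at the subject's amplitudes
    topo = aep_scalp_topography(montage)
    sigma_s = truth.component_sigma_ms / 1000.0
    tmpl_len = int(0.400 * sfreq)
    t_local = np.arange(tmpl_len) / sfreq
    g_n1 = _gaussian_bump(t_local, truth.n1_latency_ms / 1000.0, sigma_s)
    g_p2 = _gaussian_bump(t_local, truth.p2_latency_ms / 1000.0, sigma_s)
    signal = np.zeros(n_samp)
    for onset, inten in zip(seq.onsets, seq.intensities):
        a_n1 = truth.n1_amp_75_uv + truth.true_slope_n1 * (inten - 75.0)
        a_p2 = truth.p2_amp_75_uv + truth.true_slope_p2 * (inten - 75.0)
        s0 = int(round(onset * sfreq))
        s1 = min(s0 + tmpl_len, n_samp)
        signal[s0:s1] += (a_n1 * g_n1 + a_p2 * g_p2)[: s1 - s0]
    data += topo[:, None] * signal[None, :]

    # background noise (EOG channels at reduced level)
    if truth.noise_sd_uv > 0:
        noise = _pink_alpha_noise(rng, n_ch, n_samp, sfreq, truth.noise_sd_uv)
        eog_rows = np.array([ch in EOG_CHANNELS for ch in montage])
        noise[eog_rows] *= 0.5
        data += noise

    # blinks
    if truth.blink_rate_per_min > 0:
        dur_min = n_samp / sfreq / 60.0
        n_blinks = rng.poisson(truth.blink_rate_per_min * dur_min)
        if n_blinks:
            prop = blink_propagation(montage)
            blink_len = int(0.350 * sfreq)
            shape = np.hanning(blink_len)
            starts = rng.integers(0, n_samp - blink_len, size=n_blinks)
            amps = rng.normal(150.0, 30.0, size=n_blinks)
            for s0, amp in zip(starts, amps):
                data[:, s0 : s0 + blink_len] += prop[:, None] * (amp * shape)[None, :]

    # high-amplitude artifact epochs
    if truth.artifact_epoch_fraction > 0:
        hit = rng.random(seq.n_events) < truth.artifact_epoch_fraction
        eeg_rows = [i for i, ch in enumerate(montage) if ch not in EOG_CHANNELS]
        art_len = int(0.080 * sfreq)
        art_shape = np.hanning(art_len)
        for onset in seq.onsets[hit]:
            ch = int(rng.choice(eeg_rows))
            t0 = int(round(onset * sfreq)) + int(rng.uniform(0.02, 0.30) * sfreq)
            amp = rng.uniform(150.0, 250.0) * rng.choice([-1.0, 1.0])
            t1 = min(t0 + art_len, n_samp)
            data[ch, t0:t1] += amp * art_shape[: t1 - t0]

    return RawRecording(
        channels=list(montage), sfreq=sfreq, data=data, events=seq,
        meta={"seed": seed, "truth": truth},
    )


# --------------------------------------------------------------------------
# clinical cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort-generator parameters.

    Defaults mirror the reference SSRI-treatment study: 41 outpatients
    (7 male / 34 female, 15 first- / 26 recurrent-episode, 10 smokers,
    21 on hypnotics), a low/high pretreatment-LDAEP split of 20/21 with
    N1/P2 slope distributions 0.62 ± 0.36 and 1.89 ± 0.52 µV/dB, and
    group-conditional percent-BDI-reduction distributions 37.2 ± 40.9 and
    70.2 ± 36.2 (truncated to [-50, 100]).
    """

    n_subjects: int = 41
    male_fraction: float = 7 / 41
    first_episode_fraction: float = 15 / 41
    smoker_fraction: float = 10 / 41
    hypnotic_fraction: float = 21 / 41
    age_mean: float = 40.2
    age_sd: float = 15.2
    ldaep_group_means: tuple[float, float] = (0.62, 1.89)  # low, high (µV/dB)
    ldaep_group_sds: tuple[float, float] = (0.36, 0.52)
    reduction_means: tuple[float, float] = (37.2, 70.2)  # % BDI reduction
    reduction_sds: tuple[float, float] = (40.9, 36.2)
    reduction_bounds: tuple[float, float] = (-50.0, 100.0)
    bdi_pre_mean: float = 31.0
    bdi_pre_sd: float = 12.4
    drug_fractions: tuple[float, float, float] = (32 / 41, 7 / 41, 2 / 41)
    drug_names: tuple[str, str, str] = ("escitalopram", "sertraline", "paroxetine_cr")
    drug_dose_mean_sd: tuple[tuple[float, float], ...] = (
        (10.0, 4.0), (78.6, 26.7), (18.8, 8.8))
    #: maps the clinical-table N1/P2 slope onto the simulated EEG's vertex
    #: slope (µV/dB). The reference study prints slope values whose linear
    #: extrapolation over 55–95 dB would imply tens-of-µV peak swings; the
    #: EEG simulation keeps averaged N1/P2 amplitudes in the low-µV AEP
    #: range by scaling the slope down while preserving subject ranking.
    eeg_slope_scale: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        fracs = (self.male_fraction, self.first_episode_fraction,
                 self.smoker_fraction, self.hypnotic_fraction, *self.drug_fractions)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if any(s < 0 for s in (*self.ldaep_group_sds, *self.reduction_sds,
                               self.age_sd, self.bdi_pre_sd)):
            raise ValueError("standard deviations must be >= 0")


def _censored_normal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and SD of clip(N(mu, sigma), lo, hi) in closed form."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    Fa, Fb = sstats.norm.cdf(a), sstats.norm.cdf(b)
    fa, fb = sstats.norm.pdf(a), sstats.norm.pdf(b)
    z = Fb - Fa
    m = lo * Fa + hi * (1.0 - Fb) + mu * z + sigma * (fa - fb)
    m2 = (
        lo**2 * Fa
        + hi**2 * (1.0 - Fb)
        + (mu**2 + sigma**2) * z
        + 2.0 * mu * sigma * (fa - fb)
        + sigma**2 * (a * fa - b * fb)
    )
    var = max(m2 - m * m, 0.0)
    return m, np.sqrt(var)


class MatchedClippedNormal:
    """clip(N(mu, sigma), lo, hi) whose clipped mean/SD equal the targets.

    Values are restricted to [lo, hi] by censoring (piling boundary mass on
    the bounds — the natural ceiling at 100% reduction is full remission),
    and the parent parameters are solved so the *censored* distribution has
    exactly the configured moments. Naive clipping of N(mean, sd) would
    bias the group means by several points, breaking the generator's
    calibration; a renormalized truncated normal cannot even attain the
    high-reduction group's configured moments on these bounds.
    """

    def __init__(self, mean: float, sd: float, lo: float, hi: float):
        if sd <= 0:
            raise ValueError("sd must be positive (degenerate case handled upstream)")
        if not lo < mean < hi:
            raise ValueError("target mean must lie strictly inside the bounds")

        def residual(params):
            mu, log_sigma = params
            m, s = _censored_normal_moments(mu, np.exp(log_sigma), lo, hi)
            return [m - mean, s - sd]

        sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
        if not sol.success or max(abs(np.asarray(residual(sol.x)))) > 1e-6:
            raise RuntimeError(
                f"moment matching failed for mean={mean}, sd={sd} on "
                f"[{lo}, {hi}]: {sol.message}"
            )
        self.mu, self.sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
        self.lo, self.hi = lo, hi

    def rvs(self, size: int, random_state) -> np.ndarray:
        return np.clip(
            random_state.normal(self.mu, self.sigma, size), self.lo, self.hi
        )


def _exact_count_flags(rng, n: int, fraction: float) -> np.ndarray:
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    return rng.permutation(flags)


def generate_cohort(
    spec: CohortSpec = CohortSpec(), with_truth: bool = False
):
    """Generate the clinical table (and, optionally, per-subject EEG truth).

    Categorical attributes use exact rounded counts under a seeded
    permutation (n = 41 with the default sex ratio gives exactly 7 males);
    LDAEP slopes come from the subject's group distribution and percent BDI
    reduction from the group-conditional moment-matched censored normal.
    ``bdi_post = round(bdi_pre * (1 - reduction / 100))`` clipped at 0.

    Returns a DataFrame (plus ``{subject_id: GroundTruth}`` if requested).
    The true N1 and P2 slope components split the N1/P2 slope -0.3 / +0.7,
    the ratio seen in the reference study's group means.
    """
    spec.validate()
    n = spec.n_subjects
    rng = np.random.default_rng(spec.seed)

    male = _exact_count_flags(rng, n, spec.male_fraction)
    first_ep = _exact_count_flags(rng, n, spec.first_episode_fraction)
    smoker = _exact_count_flags(rng, n, spec.smoker_fraction)
    hypnotic = _exact_count_flags(rng, n, spec.hypnotic_fraction)
    high_group = rng.permutation(np.arange(n) >= n // 2)  # n//2 low, rest high

    age = np.clip(np.round(rng.normal(spec.age_mean, spec.age_sd, n)), 18, 85)
    bdi_pre = np.clip(
        np.round(rng.normal(spec.bdi_pre_mean, spec.bdi_pre_sd, n)), 5, 63
    ).astype(int)

    g = high_group.astype(int)
    slope = rng.normal(
        np.asarray(spec.ldaep_group_means)[g], np.asarray(spec.ldaep_group_sds)[g]
    )

    red = np.empty(n)
    for gi in (0, 1):
        m = g == gi
        if spec.reduction_sds[gi] == 0:
            red[m] = spec.reduction_means[gi]
        else:
            dist = MatchedClippedNormal(
                spec.reduction_means[gi], spec.reduction_sds[gi],
                *spec.reduction_bounds,
            )
            red[m] = dist.rvs(size=int(m.sum()), random_state=rng)
    bdi_post = np.clip(np.round(bdi_pre * (1.0 - red / 100.0)), 0, 63).astype(int)

    # drug assignment with exact rounded counts (largest-remainder fill)
    counts = [int(round(f * n)) for f in spec.drug_fractions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmax(spec.drug_fractions))] += 1
    drug_idx = rng.permutation(np.repeat(np.arange(len(counts)), counts))
    doses = np.array([
        max(0.5, rng.normal(*spec.drug_dose_mean_sd[i])) for i in drug_idx
    ])

    table = pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "sex": np.where(male, "M", "F"),
        "age": age.astype(int),
        "episode": np.where(first_ep, "first", "recurrent"),
        "smoker": smoker.astype(int),
        "hypnotic": hypnotic.astype(int),
        "drug": [spec.drug_names[i] for i in drug_idx],
        "dose_mg": np.round(doses, 1),
        "bdi_pre": bdi_pre,
        "bdi_post": bdi_post,
        "ldaep_group_true": np.where(high_group, "high", "low"),
        "true_slope_n1p2": slope,
    })
    if not with_truth:
        return table

    truths = {}
    for _, row in table.iterrows():
        s = row["true_slope_n1p2"] * spec.eeg_slope_scale
        truths[row["subject_id"]] = GroundTruth(
            true_slope_n1=-0.3 * s, true_slope_p2=0.7 * s,
        )
    return table, truths
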