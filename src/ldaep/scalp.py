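"""Scalp LDAEP: N1/P2 peak detection at the vertex electrode and the
intensity-dependence slope (µV/dB) by ordinary least squares over the five
stimulus intensities.

Conventions: N1 is the signed minimum in its search window (so its slope is
typically negative), P2 the maximum in its window; window endpoints are
inclusive and amplitude ties break to the earliest latency. The N1/P2
(peak-to-peak) amplitude is P2 minus N1, hence by linearity of least squares
slope_n1p2 == slope_p2 - slope_n1 identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N1_WINDOW_MS: tuple[float, float] = (80.0, 130.0)
P2_WINDOW_MS: tuple[float, float] = (130.0, 230.0)
DEFAULT_INTENSITIES: tuple[int, ...] = (55, 65, 75, 85, 95)


@dataclass(frozen=True)
class PeakMeasurement:
    intensity_db: float
    n1_amplitude: float  # µV, signed
    n1_latency_ms: float
    p2_amplitude: float
    p2_latency_ms: float
    flat: bool = False

    @property
    def peak_to_peak(self) -> float:
        return self.p2_amplitude - self.n1_amplitude


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class LdaepResult:
    slope_n1: float
    slope_p2: float
    slope_n1p2: float
    intercept_n1: float
    intercept_p2: float
    intercept_n1p2: float
    r2_n1: float
    r2_p2: float
    r2_n1p2: float
    peaks: tuple[PeakMeasurement, ...]
    channel: str


def _extremum(
    waveform: np.ndarray, times_ms: np.ndarray, window: tuple[float, float], kind: str
) -> tuple[float, float]:
    lo, hi = window
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window} ms lies outside the epoch")
    seg = waveform[mask]
    t = times_ms[mask]
    # argmin/argmax return the first occurrence -> earliest-latency tie-break
    idx = int(np.argmin(seg) if kind == "min" else np.argmax(seg))
    return float(seg[idx]), float(t[idx])


def detect_n1_p2_peaks(
    evoked,
    channel: str = "Cz",
    n1_window: tuple[float, float] = N1_WINDOW_MS,
    p2_window: tuple[float, float] = P2_WINDOW_MS,
) -> list[PeakMeasurement]:
    """Per-intensity N1 (window minimum) and P2 (window maximum) at one channel.

    A waveform that is constant over both windows is returned as the
    degenerate extremum with the ``flat`` flag set.
    """
    if channel not in evoked.channels:
        raise ValueError(f"channel {channel!r} not present")
    ci = evoked.channels.index(channel)
    out = []
    for inten in sorted(evoked.data.keys()):
        wave = np.asarray(evoked.data[inten][ci], dtype=float)
        n1_amp, n1_lat = _extremum(wave, evoked.times_ms, n1_window, "min")
        p2_amp, p2_lat = _extremum(wave, evoked.times_ms, p2_window, "max")
        both = (
            (evoked.times_ms >= min(n1_window[0], p2_window[0]))
            & (evoked.times_ms <= max(n1_window[1], p2_window[1]))
        )
        flat = bool(np.ptp(wave[both]) == 0.0)
        out.append(PeakMeasurement(float(inten), n1_amp, n1_lat, p2_amp, p2_lat, flat))
    return out


def fit_ldaep_slope(
    values, intensities=DEFAULT_INTENSITIES
) -> SlopeFit:
    """OLS slope of amplitude on stimulus intensity (µV/dB).

    Closed form: slope = Σ(x-x̄)(y-ȳ) / Σ(x-x̄)². R² is 1 for a perfect fit
    and defined as 1 when the response variance is zero (flat data fit
    exactly by a flat line).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(intensities, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and intensities must be 1-D and equal length")
    if len(x) < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct intensities")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    slope = float(xd @ yd) / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(yd @ yd)
    if syy == 0.0:
        r2 = 1.0
    else:
        resid = y - (intercept + slope * x)
        r2 = 1.0 - float(resid @ resid) / syy
    return SlopeFit(slope, intercept, r2)


def compute_scalp_ldaep(
    evoked,
    channel: str = "Cz",
    n1_window: tuple[float, float] = N1_WINDOW_MS,
    p2_window: tuple[float, float] = P2_WINDOW_MS,
) -> LdaepResult:
    """The three scalp LDAEP slopes (N1, P2, N1/P2) from per-intensity peaks."""
    peaks = detect_n1_p2_peaks(evoked, channel, n1_window, p2_window)
    if len(peaks) < 2:
        raise ValueError("need peaks at >= 2 intensities")
    inten = np.array([p.intensity_db for p in peaks])
    fit_n1 = fit_ldaep_slope([p.n1_amplitude for p in peaks], inten)
    fit_p2 = fit_ldaep_slope([p.p2_amplitude for p in peaks], inten)
    fit_pp = fit_ldaep_slope([p.peak_to_peak for p in peaks], inten)
    return LdaepResult(
        fit_n1.slope, fit_p2.slope, fit_pp.slope,
        fit_n1.intercept, fit_p2.intercept, fit_pp.intercept,
        fit_n1.r_squared, fit_p2.r_squared, fit_pp.r_squared,
        tuple(peaks), channel,
    )
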