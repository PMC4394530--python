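"""Raw-recording interchange: EDF for the signals, TSV for the events,
YAML for ground truth.

EDF (European Data Format) writing is implemented here directly — a plain
fixed-layout 16-bit format — while reading goes through MNE's EDF reader,
which also acts as an independent check of the writer in the test suite.
Samples survive the round trip to within one 16-bit quantization step of
the channel's physical range; event onsets are exact (they live in the
sidecar, not the EDF annotations).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import RawRecording
from .simulate import GroundTruth, StimulusSequence

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(raw: RawRecording, path) -> None:
    """Write a recording as plain EDF (1-s data records, 16-bit).

    The recording is zero-padded to a whole number of seconds (the
    simulator already emits whole-second recordings, so normally no
    padding occurs). Physical units are µV.
    """
    path = Path(path)
    n_ch, n_samp = raw.data.shape
    sfreq = raw.sfreq
    if sfreq != int(sfreq):
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(sfreq)  # samples per 1-s record per channel
    n_rec = math.ceil(n_samp / spr)
    data = raw.data
    if n_rec * spr != n_samp:
        data = np.pad(data, ((0, 0), (0, n_rec * spr - n_samp)))

    phys_max = np.abs(data).max(axis=1)
    phys_max = np.where(phys_max > 0, phys_max, 1.0)
    phys_max = np.ceil(phys_max * 10.0) / 10.0  # one decimal, keeps field short

    header = b"".join([
        _pad_field(0, 8),  # version
        _pad_field("X X X X", 80),  # local patient id (anonymous)
        _pad_field("Startdate X X X X", 80),
        _pad_field("01.01.00", 8),
        _pad_field("00.00.00", 8),
        _pad_field(256 + 256 * n_ch, 8),
        _pad_field("", 44),
        _pad_field(n_rec, 8),
        _pad_field(1, 8),  # record duration, s
        _pad_field(n_ch, 4),
    ])
    labels = b"".join(_pad_field(ch, 16) for ch in raw.channels)
    transducer = b"".join(_pad_field("AgAgCl electrode", 80) for _ in range(n_ch))
    dim = b"".join(_pad_field("uV", 8) for _ in range(n_ch))
    pmin = b"".join(_pad_field(f"{-m:.1f}", 8) for m in phys_max)
    pmax = b"".join(_pad_field(f"{m:.1f}", 8) for m in phys_max)
    dmin = b"".join(_pad_field(_EDF_DIG_MIN, 8) for _ in range(n_ch))
    dmax = b"".join(_pad_field(_EDF_DIG_MAX, 8) for _ in range(n_ch))
    prefilt = b"".join(_pad_field("", 80) for _ in range(n_ch))
    nsamp = b"".join(_pad_field(spr, 8) for _ in range(n_ch))
    reserved = b"".join(_pad_field("", 32) for _ in range(n_ch))

    # EDF affine map: physical = (digital - dig_min) * scale + phys_min
    scale = (phys_max * 2.0) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.clip(
        np.round((data - (-phys_max[:, None])) / scale[:, None]) + _EDF_DIG_MIN,
        _EDF_DIG_MIN, _EDF_DIG_MAX,
    ).astype("<i2")
    # records are channel-blocked: rec0[ch0 spr samples, ch1 ...], rec1[...]
    blocked = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin + dmax
                 + prefilt + nsamp + reserved)
        fh.write(blocked.tobytes())


def read_edf(path, events_path=None) -> RawRecording:
    """Read an EDF recording (via MNE) back into µV, with its events sidecar.

    Raises a format error naming the problem for malformed files or a
    missing/invalid sidecar.
    """
    import mne

    mne.set_log_level("ERROR")
    path = Path(path)
    try:
        mraw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as err:
        raise ValueError(f"malformed EDF {path.name}: {err}") from err
    data_uv = mraw.get_data() * 1e6
    events = None
    if events_path is not None:
        events = read_events(events_path)
        dur = data_uv.shape[1] / mraw.info["sfreq"]
        if np.any(np.asarray(events.onsets) >= dur):
            raise ValueError("events sidecar: onset_s beyond recording duration")
    return RawRecording(
        channels=list(mraw.ch_names), sfreq=float(mraw.info["sfreq"]),
        data=data_uv, events=events,
    )


def write_events(seq: StimulusSequence, path) -> None:
    """Events sidecar: tab-separated onset_s / intensity_db."""
    pd.DataFrame({
        "onset_s": np.asarray(seq.onsets, dtype=float),
        "intensity_db": np.asarray(seq.intensities, dtype=int),
    }).to_csv(path, sep="\t", index=False)


def read_events(path) -> StimulusSequence:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "intensity_db"):
        if col not in df.columns:
            raise ValueError(f"events sidecar missing column {col!r}")
    if np.any(df["onset_s"].to_numpy() < 0):
        raise ValueError("events sidecar: negative onset_s")
    return StimulusSequence(
        onsets=df["onset_s"].to_numpy(float),
        intensities=df["intensity_db"].to_numpy(int),
    )


def write_evoked(evoked, path, provenance: dict | None = None) -> None:
    """Tabular evoked export: one row per channel x time x intensity, with a
    JSON provenance sidecar (<path>.json) holding filter/rejection metadata."""
    import json

    rows = []
    for inten in sorted(evoked.data.keys()):
        wav = evoked.data[inten]
        for ci, ch in enumerate(evoked.channels):
            for ti, t in enumerate(evoked.times_ms):
                rows.append((inten, ch, t, wav[ci, ti]))
    pd.DataFrame(
        rows, columns=["intensity_db", "channel", "time_ms", "amplitude_uv"]
    ).to_csv(path, index=False)
    side = {
        "n_epochs_used": {str(k): v for k, v in evoked.n_epochs_used.items()},
        "rejection_rate": {str(k): v for k, v in evoked.rejection_rate.items()},
    }
    if provenance:
        side.update(provenance)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=2, sort_keys=True))


def read_evoked(path):
    """Read a tabular evoked export back into an EvokedSet."""
    from .preprocess import EvokedSet

    df = pd.read_csv(path)
    channels = list(dict.fromkeys(df["channel"]))
    times = np.sort(df["time_ms"].unique())
    data = {}
    counts = {}
    for inten, grp in df.groupby("intensity_db"):
        mat = (
            grp.pivot(index="channel", columns="time_ms", values="amplitude_uv")
            .reindex(index=channels, columns=times)
            .to_numpy()
        )
        data[int(inten)] = mat
        counts[int(inten)] = 0
    return EvokedSet(data, times.astype(float), channels, counts,
                     {k: float("nan") for k in counts})


def write_ground_truth(truths: dict[str, GroundTruth], path) -> None:
    """Ground-truth sidecar YAML, one block per subject."""
    payload = {
        sid: {k: float(v) for k, v in vars(t).items()} for sid, t in truths.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_ground_truth(path) -> dict[str, GroundTruth]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {sid: GroundTruth(**vals) for sid, vals in payload.items()}
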