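"""Electrode montage: 64 EEG channels (10-10 extension of the 10-20 system,
including the mastoids M1/M2) plus four EOG channels, with 3-D positions
taken from the standard_1005 template montage shipped with MNE."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: 64 scalp sites of a standard 10-10 cap, mastoids last.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
    "M1", "M2",
)

#: Vertical (above/below left eye) and horizontal (outer canthi) EOG.
EOG_CHANNELS: tuple[str, ...] = ("VEOGU", "VEOGL", "HEOGL", "HEOGR")

MASTOIDS: tuple[str, str] = ("M1", "M2")

#: Approximate EOG electrode positions in head coordinates (m); only used to
#: place blink sources plausibly, never for source modelling.
_EOG_POS = {
    "VEOGU": (-0.030, 0.085, 0.000),
    "VEOGL": (-0.030, 0.085, -0.030),
    "HEOGL": (-0.060, 0.065, -0.010),
    "HEOGR": (0.060, 0.065, -0.010),
}


def default_montage() -> list[str]:
    """All 68 channel labels in recording order (64 EEG then 4 EOG)."""
    return list(EEG_CHANNELS) + list(EOG_CHANNELS)


@lru_cache(maxsize=4)
def channel_positions(channels: tuple[str, ...] = EEG_CHANNELS) -> dict[str, np.ndarray]:
    """Map channel label -> 3-D position (m, head frame).

    EEG labels are looked up in MNE's ``standard_1005`` montage; EOG labels
    use the fixed approximate positions above.
    """
    import mne

    mne.set_log_level("ERROR")
    std = mne.channels.make_standard_montage("standard_1005")
    lookup = std.get_positions()["ch_pos"]
    pos: dict[str, np.ndarray] = {}
    for ch in channels:
        if ch in lookup:
            pos[ch] = np.asarray(lookup[ch], dtype=float)
        elif ch in _EOG_POS:
            pos[ch] = np.asarray(_EOG_POS[ch], dtype=float)
        else:
            raise KeyError(f"channel {ch!r} not in standard_1005 montage")
    return pos
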