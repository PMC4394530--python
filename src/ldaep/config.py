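"""Pipeline configuration: every tunable constant of the analysis in one
validated, hashable, YAML-serializable record.

Defaults are the acquisition and analysis constants of the modelled study:
1–30 Hz band-pass, 70 µV rejection threshold, N1 window 80–130 ms, P2
window 130–230 ms, intensities 55–95 dB SPL, source window 60–240 ms.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    # cohort / simulation
    n_subjects: int = 41
    n_events: int = 1000
    sample_rate_hz: float = 1000.0
    intensities_db: tuple[int, ...] = (55, 65, 75, 85, 95)
    # preprocessing
    band_hz: tuple[float, float] | None = (1.0, 30.0)
    epoch_window_ms: tuple[float, float] = (-100.0, 400.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reject_threshold_uv: float | None = 70.0
    reference: str = "linked-mastoid"
    eog_channels: tuple[str, ...] = ("VEOGU", "VEOGL")
    ocular_correction: bool = True
    # scalp LDAEP
    peak_channel: str = "Cz"
    n1_window_ms: tuple[float, float] = (80.0, 130.0)
    p2_window_ms: tuple[float, float] = (130.0, 230.0)
    # source LDAEP
    n_sources: int = 254
    source_orientation: str = "fixed"
    source_snr: float = 10.0
    source_window_ms: tuple[float, float] = (60.0, 240.0)
    run_source_analysis: bool = True
    # stratification
    responder_reduction_pct: float = 50.0
    remitter_bdi_cutoff: int = 10
    # io
    write_edf: bool = False
    montage: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_events < len(self.intensities_db):
            raise ValueError("n_events must cover every intensity")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.band_hz is not None:
            lo, hi = self.band_hz
            if not (0 < lo < hi < self.sample_rate_hz / 2):
                raise ValueError("filter band outside (0, Nyquist)")
        lo, hi = self.epoch_window_ms
        if not (lo <= 0 and hi >= max(self.p2_window_ms[1], self.source_window_ms[1])):
            raise ValueError("epoch window must cover the analysis windows")
        if self.reference not in ("linked-mastoid", "average", "none"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.montage and "Cz" not in self.montage:
            raise ValueError("montage must contain Cz")
        if self.reject_threshold_uv is not None and self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")

    def resolved_montage(self) -> list[str]:
        from .montage import default_montage

        return list(self.montage) if self.montage else default_montage()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["montage"] = list(d["montage"])
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        tupled = {}
        for k, v in payload.items():
            if isinstance(v, list):
                v = tuple(v)
            tupled[k] = v
        cfg = cls(**tupled)
        cfg.validate()
        return cfg

    def with_overrides(self, **kw) -> "PipelineConfig":
        cfg = replace(self, **kw)
        cfg.validate()
        return cfg


def _plain(obj):
    """Recursively convert tuples to lists for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Config file overrides defaults; keyword/CLI flags override the file."""
    if path is None:
        cfg = PipelineConfig(**overrides) if overrides else PipelineConfig()
        cfg.validate()
        return cfg
    return PipelineConfig.from_yaml(path, **overrides)
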