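"""Pipeline configuration: one serializable object holding every tunable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the simulate → ptt → calibrate → estimate → validate chain.

    Defaults are the documented operating point: 500-Hz analysis rate,
    4th-order zero-phase Butterworth bands 5–45 Hz (SCG) and 0.8–8 Hz (PPG),
    450-ms ensemble windows, age-banded gamma defaults 0.031/0.09 with
    clamping to [0, 10], absolute-difference bands at 5/10/15 mm Hg and
    Bland-Altman limits at ±2 SD.
    """

    analysis_fs_hz: float = 500.0
    scg_band_hz: tuple[float, float] = (5.0, 45.0)
    ppg_band_hz: tuple[float, float] = (0.8, 8.0)
    filter_order: int = 4
    window_ms: float = 450.0
    ao_edge_guard_ms: float = 40.0
    ao_min_snr: float = 3.0
    min_beats: int = 5
    gamma_young: float = 0.031
    gamma_old: float = 0.09
    age_cutoff_years: float = 40.0
    gamma_max: float = 10.0
    r_singular_tol: float = 1e-3
    band_thresholds: tuple[float, float, float] = (5.0, 10.0, 15.0)
    bland_altman_k: float = 2.0
    pct_decimals: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(d)
        for f in fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    @property
    def config_hash(self) -> str:
        """Short provenance hash embedded in every report."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)
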