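"""Pipeline configuration: every tunable threshold in one place.

Values can be overridden from a TOML file (nested sections map onto the
flat field names with ``section_field`` naming) and from CLI flags; the
precedence is flags > file > defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    # preprocessing
    rate_hz: float = 12500.0
    band_low_hz: float = 70.0
    band_high_hz: float = 2000.0
    decimation: int = 4
    flow_lowpass_hz: float = 20.0
    # phase segmentation
    flow_smooth_s: float = 0.05
    min_phase_s: float = 0.2
    min_peak_fraction: float = 0.05
    # EEMD
    eemd_ensemble: int = 100
    eemd_noise_fraction: float = 0.2
    eemd_max_imfs: int = 10
    eemd_max_siftings: int = 12
    eemd_upsample: int = 2
    # Hilbert spectrum
    freq_bin_hz: float = 5.0
    if_smooth_samples: int = 31   # spectrum binning (envelope-weighted)
    if_median_samples: int = 11   # detection dispersion (median)
    # candidate detection
    dispersion_window_s: float = 0.1
    dispersion_threshold_hz: float = 40.0
    min_segment_s: float = 0.1
    rule_dispersion_hz: float = 25.0
    rule_min_duration_s: float = 0.15
    # region growing / linking
    seed_percentile: float = 75.0
    growth_floor: float = 0.10
    max_thickness_bins: int = 4
    gap_t_cas_s: float = 0.05
    gap_f_cas_hz: float = 20.0
    gap_t_normal_s: float = 0.02
    gap_f_normal_hz: float = 10.0
    min_duration_s: float = 0.1  # strict > (the 100 ms CAS definition)
    intensity_square_h: bool = True
    # BDR thresholds
    pitch_cutoff_hz: float = 200.0
    inclusion_threshold_pct: float = 5.0
    category_low_pct: float = 33.0
    category_high_pct: float = 66.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dispersion_threshold_hz", "min_segment_s", "freq_bin_hz",
                     "pitch_cutoff_hz", "inclusion_threshold_pct",
                     "min_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.category_low_pct < self.category_high_pct:
            raise ValueError("category bounds must be ordered")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        flat.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**flat)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(
            self, **{k: v for k, v in overrides.items() if v is not None})

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        digest = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
        return {"config": d, "config_hash": digest, "seed": self.seed}
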