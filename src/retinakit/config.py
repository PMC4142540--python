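"""Pipeline configuration: one structured object drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a full simulate -> STA -> classify ->
    stats (+ ERG) run. Serializable to YAML and embedded verbatim in every
    report for provenance."""

    seed: int = 0
    # stimulus
    grid_rows: int = 19
    grid_cols: int = 19
    frame_rate_hz: float = 60.0
    checker_size_um: float = 100.0
    duration_s: float = 900.0
    # population
    n_on: int = 4
    n_off: int = 16
    conditions: tuple[str, ...] = ("control", "blocker")
    # STA
    window_ms: float = 300.0
    n_lags: int = 18
    z_min: float = 4.0
    # classification
    pca_variance_cutoff: float = 0.90
    k_clusters: int = 5
    # ERG branch
    erg_profiles: tuple[str, ...] = ("degu_scotopic", "rat_scotopic")
    erg_replicates: int = 4
    erg_noise_sd_uv: float = 5.0
    erg_baseline_window_ms: float = 100.0
    erg_fit_halfwidth_ms: float = 25.0

    def validate(self) -> "PipelineConfig":
        positive = ["frame_rate_hz", "duration_s", "window_ms", "z_min",
                    "pca_variance_cutoff", "erg_baseline_window_ms",
                    "erg_fit_halfwidth_ms"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_lags < 1 or self.k_clusters < 1:
            raise ConfigError("n_lags and k_clusters must be >= 1")
        frame_ms = 1000.0 / self.frame_rate_hz
        if abs(self.n_lags * frame_ms - self.window_ms) > frame_ms:
            raise ConfigError(
                f"n_lags * frame interval ({self.n_lags * frame_ms:.2f} ms) "
                f"does not match window_ms ({self.window_ms:.2f} ms)")
        if self.n_on + self.n_off < 1:
            raise ConfigError("population must contain at least one cell")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["erg_profiles"] = list(self.erg_profiles)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "conditions" in data:
            data = {**data, "conditions": tuple(data["conditions"])}
        if "erg_profiles" in data:
            data = {**data, "erg_profiles": tuple(data["erg_profiles"])}
        return cls(**data).validate()
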