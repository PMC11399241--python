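"""Run configuration: structured-text (YAML) with override precedence.

Effective settings are assembled as CLI overrides > config file > defaults.
All stochastic steps funnel through the single mandatory ``seed``, which is
recorded in every artifact's metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parameters of a simulate -> reconstruct -> fit -> fret run."""

    preset: str = "cy3cy5_beads"
    scene_overrides: dict = field(default_factory=dict)
    # acquisition
    n_delays: int = 301
    delay_step_fs: float = 0.75
    n_time_bins: int = 512
    time_window_ns: float = 10.0
    irf_fwhm_ps: float = 50.0
    irf_t0_ns: float = 0.5
    photon_budget: float = 1e6
    seed: int = 1
    # reconstruction
    mask_threshold: float = 0.05
    normalize: bool = True
    pad_factor: int = 4
    window: str | None = None
    # fitting
    n_components: int = 2
    n_max: int = 4
    weights: str = "auto"
    # output
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = {
            "n_delays": self.n_delays, "delay_step_fs": self.delay_step_fs,
            "n_time_bins": self.n_time_bins,
            "time_window_ns": self.time_window_ns,
            "irf_fwhm_ps": self.irf_fwhm_ps,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.photon_budget < 0:
            raise ValueError("photon_budget must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic steps")

    def asdict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and keyword
    overrides (highest precedence).  Unknown keys are rejected."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
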