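"""Pipeline configuration.

Every threshold the analysis is defined by is the default here and every
default can be overridden from YAML or keyword arguments: 2-cm map bins with
3-cm Gaussian smoothing and a > 5 cm/s speed filter; spatial information
> 0.3 bits/spike and covariate-adjusted trial-type effect at p < 0.05 for
cell screening; 250-ms task and 20-ms replay decoding windows (5-ms step,
10x compression); mean + 3 SD burst and ripple thresholds with < 2 cm/s
immobility; < 25 cm continuity and the four-window distance criterion;
dual shuffles, 5000 each, at p < 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulation (used when no session directory is given)
    simulation: dict = field(default_factory=dict)
    # place maps
    bin_width_cm: float = 2.0
    kernel_sd_cm: float = 3.0
    speed_min_cm_s: float = 5.0
    # screening
    si_threshold_bits: float = 0.3
    screen_alpha: float = 0.05
    min_mean_rate_hz: float = 0.1
    max_mean_rate_hz: float = 5.0
    # decoding
    rate_floor_hz: float = 0.01
    task_window_s: float = 0.25
    replay_window_s: float = 0.020
    replay_step_s: float = 0.005
    compression_factor: float = 10.0
    dip_alpha: float = 0.05
    # event detection
    burst_threshold_sd: float = 3.0
    ripple_threshold_sd: float = 3.0
    immobility_speed_cm_s: float = 2.0
    # path replay
    continuity_cm: float = 25.0
    distance_criterion_cm: float = 100.0
    n_shuffles: int = 5000
    significance_alpha: float = 0.05
    # trial type
    ref_window_s: float = 0.200
    ref_step_s: float = 0.100
    ref_bin_cm: float = 20.0
    pseudocount: float = 1.0
    # session statistics
    goal_vicinity_cm: float = 20.0
    experience_ratio: tuple = (60, 40, 40)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["experience_ratio"] = list(self.experience_ratio)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
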