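"""Run configuration: every stage parameter with its standard default.

Defaults reproduce the published analysis settings: 5-probe geometric means,
10 smoothing rounds, peak threshold 1.05, efficiency cutoff 1.1 (10%), 5-kb
merge and match distances, 1000-probe (~250 kb) regional windows, +/-3-probe
ChIP assignment, 0.6-kb minimum BrdU track, 3-kb gap cutoff, and lowest-10%
baseline correction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "oriscope_out"
    condition: str = "sim"

    # synthetic genome and truth
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 5_600_000, "chrII": 4_500_000, "chrIII": 2_500_000}
    )
    probe_spacing: int = 250
    n_origins: int = 300
    min_spacing: int = 20_000
    efficiency_model: str = "domain-structured"
    replication_extent_kb: float = 7.0
    noise_cv: float = 0.05
    dye_bias: float = 1.0
    baseline_offset: float = 0.15
    n_repeats: int = 2

    # normalization
    geomean_window: int = 5
    outlier_k: float = 5.0
    baseline_fraction: float = 0.10
    baseline_mode: str = "divide"

    # origin calling
    smoothing_rounds: int = 10
    peak_threshold: float = 1.05
    prominence: float = 0.01
    efficiency_cutoff: float = 1.1
    merge_kb: float = 5.0
    match_kb: float = 5.0

    # regional profiles
    window_probes: int = 1000
    window_step: int = 1
    tiled: bool = False

    # Cdc45 ChIP
    chip_reach_probes: int = 3
    cdc45_gain: float = 0.01
    cdc45_background: float = 0.1

    # combing
    n_fibers: int = 30
    min_track_kb: float = 0.6
    gap_cutoff_kb: float = 3.0
    iod_mode: str = "midpoint"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)
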