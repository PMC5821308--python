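"""Cdc45 ChIP-chip: origin-level binding, regional profiles, display smoothing.

Cdc45 is a limiting pre-initiation-complex factor whose origin occupancy
tracks firing efficiency.  Origins come from the replication pipeline, never
from peak calling on the ChIP signal itself; per-origin binding is the highest
IP/input value within 3 probes of the origin position, read from raw probe
values (smoothing is for display only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .calling import OriginSet
from .copy_number import RatioTrack, average_replicates, window_geomean
from .regional import ComparisonStats, RegionalProfile, regional_profile, spearman_rho
from .synthetic import ProbeGrid

__all__ = [
    "Cdc45Track",
    "cdc45_at_origins",
    "regional_cdc45",
    "display_smooth",
    "binding_efficiency_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class Cdc45Track:
    """Per-probe Cdc45 IP/input enrichment aligned to a probe grid."""

    grid: ProbeGrid
    values: dict[str, np.ndarray]
    replicate: str = "1"

    def __post_init__(self) -> None:
        for name in self.grid.chrom_names:
            v = np.asarray(self.values[name], dtype=float)
            if len(v) != len(self.grid.positions[name]):
                raise ValueError(f"track not aligned with grid on {name!r}")
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"IP/input values on {name!r} must be finite and > 0")
            self.values[name] = v

    def as_ratio_track(self) -> RatioTrack:
        return RatioTrack.from_values(self.grid, self.values)


def cdc45_at_origins(track: Cdc45Track, origins: OriginSet, reach: int = 3) -> np.ndarray:
    """Per-origin binding: max IP/input within ``reach`` probes of the origin.

    The window is inclusive (+/- ``reach`` probes, 7 probes by default).
    Origins off the grid are assigned to the nearest probe with a warning.
    """
    if reach < 0:
        raise ValueError("reach must be >= 0")
    grid = track.grid
    out = np.empty(len(origins))
    n_off_grid = 0
    for i, call in enumerate(origins):
        pos = grid.positions[call.chrom]
        j = grid.nearest_probe(call.chrom, call.position)
        if pos[j] != call.position:
            n_off_grid += 1
        lo, hi = max(0, j - reach), min(len(pos), j + reach + 1)
        out[i] = track.values[call.chrom][lo:hi].max()
    if n_off_grid:
        logger.warning("%d of %d origins were off-grid; nearest probes used",
                       n_off_grid, len(origins))
    return out


def regional_cdc45(
    origins: OriginSet,
    binding: np.ndarray,
    grid: ProbeGrid,
    window: int = 1000,
    step: int = 1,
    tiled: bool = False,
) -> RegionalProfile:
    """Regional profile of origin-assigned Cdc45 values (same windowing as
    efficiency profiles)."""
    return regional_profile(
        origins, grid, values=binding, window=window, step=step, tiled=tiled, kind="cdc45"
    )


def display_smooth(rep1: Cdc45Track, rep2: Cdc45Track, window: int = 5) -> Cdc45Track:
    """Display track: per-replicate 5-probe moving geometric mean, then the
    arithmetic mean of the two replicates.  Quantitative analyses use raw
    probe values; this smoothing exists for plotting only."""
    if rep1.grid != rep2.grid:
        raise ValueError("replicate tracks are aligned to different grids")
    s1 = window_geomean(rep1.as_ratio_track(), window)
    s2 = window_geomean(rep2.as_ratio_track(), window)
    avg = average_replicates(s1, s2)
    return Cdc45Track(grid=rep1.grid, values=avg.values, replicate="mean")


def binding_efficiency_correlation(binding: np.ndarray, efficiency: np.ndarray) -> ComparisonStats:
    """Spearman correlation between per-origin Cdc45 binding and efficiency."""
    return spearman_rho(binding, efficiency)
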