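"""Two-channel array normalization: from hybridizations to copy-number ratios.

The normalization chain converts raw channel intensities into per-probe
replicated/unreplicated copy-number ratios on a common baseline:

1. per-hybridization ratio, with the dye-swapped hybridization's channels
   flipped so both share the replicated/unreplicated orientation;
2. moving geometric mean over five consecutive probes (never across
   chromosome boundaries; windows shrink at chromosome ends);
3. arithmetic average of the two dye-swapped hybridizations;
4. robust outlier removal on log-ratios (running median / MAD);
5. arithmetic average of biological repeats;
6. baseline correction: the median of the lowest 10% of ratios estimates the
   unreplicated level, and the whole track is normalized so that this level
   equals 1.  The reported correction factor is ``median - 1``.

On the corrected scale a ratio of 1.1 corresponds to an origin efficiency of
10% (``efficiency = (ratio - 1) * 100``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import HybridizationPair, ProbeGrid

__all__ = [
    "RatioTrack",
    "BaselineReport",
    "probe_ratio",
    "window_geomean",
    "average_replicates",
    "remove_outliers",
    "baseline_correct",
    "normalize_condition",
    "ratio_to_efficiency",
    "efficiency_to_ratio",
]


@dataclass
class RatioTrack:
    """Per-probe copy-number ratios aligned 1:1 with a probe grid.

    ``values`` holds the replicated/unreplicated ratio; ``valid`` flags probes
    that survived QC (invalid probes keep a placeholder value and are ignored
    by every downstream operation).
    """

    grid: ProbeGrid
    values: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in self.grid.chrom_names:
            n = len(self.grid.positions[name])
            if len(self.values[name]) != n or len(self.valid[name]) != n:
                raise ValueError(f"track not aligned with grid on {name!r}")
            v = self.values[name][self.valid[name]]
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"valid ratios on {name!r} must be finite and > 0")

    def copy(self) -> "RatioTrack":
        return RatioTrack(
            grid=self.grid,
            values={k: v.copy() for k, v in self.values.items()},
            valid={k: v.copy() for k, v in self.valid.items()},
        )

    @property
    def n_valid(self) -> int:
        return int(sum(m.sum() for m in self.valid.values()))

    def valid_values(self) -> np.ndarray:
        """All valid ratios, concatenated in grid order."""
        return np.concatenate(
            [self.values[n][self.valid[n]] for n in self.grid.chrom_names]
        )

    @classmethod
    def constant(cls, grid: ProbeGrid, value: float = 1.0) -> "RatioTrack":
        return cls(
            grid=grid,
            values={n: np.full(len(grid.positions[n]), float(value)) for n in grid.chrom_names},
            valid={n: np.ones(len(grid.positions[n]), dtype=bool) for n in grid.chrom_names},
        )

    @classmethod
    def from_values(cls, grid: ProbeGrid, values: dict[str, np.ndarray]) -> "RatioTrack":
        return cls(
            grid=grid,
            values={k: np.asarray(v, dtype=float).copy() for k, v in values.items()},
            valid={k: np.isfinite(np.asarray(v, dtype=float)) & (np.asarray(v) > 0) for k, v in values.items()},
        )


@dataclass(frozen=True)
class BaselineReport:
    """Outcome of the baseline correction.

    ``median`` is the lowest-decile median m of the input ratios, ``factor``
    the reported correction factor m - 1 (printed as 0.1-0.2 in typical HU
    experiments), ``fraction`` the fraction of probes used, ``n_used`` their
    count and ``mode`` how the track was adjusted ("divide" or "subtract").
    """

    median: float
    factor: float
    fraction: float
    n_used: int
    mode: str

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("baseline median must be positive")


def _check_same_grid(a: RatioTrack, b: RatioTrack) -> None:
    if a.grid != b.grid:
        raise ValueError("tracks are aligned to different probe grids")


def probe_ratio(pair: HybridizationPair) -> tuple[RatioTrack, RatioTrack]:
    """Per-probe ratios for both hybridizations, oriented replicated/unreplicated.

    The swapped hybridization's channels are flipped before division.  Probes
    with a non-positive or non-finite intensity in either channel are flagged
    invalid; all others are unaffected.
    """
    grid = pair.grid
    tracks = []
    for hyb in (pair.first, pair.second):
        values: dict[str, np.ndarray] = {}
        valid: dict[str, np.ndarray] = {}
        for name in grid.chrom_names:
            c1 = np.asarray(hyb.ch1[name], dtype=float)
            c2 = np.asarray(hyb.ch2[name], dtype=float)
            rep, unrep = (c2, c1) if hyb.swapped else (c1, c2)
            ok = np.isfinite(rep) & np.isfinite(unrep) & (rep > 0) & (unrep > 0)
            r = np.ones_like(rep)
            np.divide(rep, unrep, out=r, where=ok)
            values[name] = r
            valid[name] = ok
        tracks.append(RatioTrack(grid=grid, values=values, valid=valid))
    return tracks[0], tracks[1]


def _rolling_geomean(values: np.ndarray, valid: np.ndarray, window: int):
    logs = np.zeros_like(values)
    np.log(values, out=logs, where=valid)
    kernel = np.ones(window)
    half = window // 2
    n = len(values)
    # full convolution + centered slice: robust when the chromosome is
    # shorter than the window (np.convolve "same" would change the length)
    s = np.convolve(np.where(valid, logs, 0.0), kernel, mode="full")[half: half + n]
    c = np.convolve(valid.astype(float), kernel, mode="full")[half: half + n]
    out_valid = c > 0.5
    out = np.ones_like(values)
    out[out_valid] = np.exp(s[out_valid] / c[out_valid])
    return out, out_valid


def window_geomean(track: RatioTrack, window: int = 5) -> RatioTrack:
    """Centered moving geometric mean over ``window`` probes, per chromosome.

    Windows never span chromosomes and shrink (are truncated) at chromosome
    ends, so the output has the same length as the grid.  Invalid probes are
    excluded from the mean; a window with no valid probe yields an invalid
    output probe.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive probe count")
    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for name in track.grid.chrom_names:
        values[name], valid[name] = _rolling_geomean(
            track.values[name], track.valid[name], window
        )
    return RatioTrack(grid=track.grid, values=values, valid=valid)


def average_replicates(a: RatioTrack, b: RatioTrack) -> RatioTrack:
    """Per-probe arithmetic mean of two tracks on the same grid.

    A probe is invalid in the output only if it is invalid in both inputs;
    where exactly one input is valid, its value is carried through.
    """
    _check_same_grid(a, b)
    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for name in a.grid.chrom_names:
        va, vb = a.values[name], b.values[name]
        ma, mb = a.valid[name], b.valid[name]
        both = ma & mb
        out = np.ones_like(va)
        out[both] = 0.5 * (va[both] + vb[both])
        only_a = ma & ~mb
        only_b = mb & ~ma
        out[only_a] = va[only_a]
        out[only_b] = vb[only_b]
        values[name] = out
        valid[name] = ma | mb
    return RatioTrack(grid=a.grid, values=values, valid=valid)


def remove_outliers(
    track: RatioTrack,
    k: float = 5.0,
    window: int = 51,
    min_log_dev: float = math.log(2.5),
) -> RatioTrack:
    """Flag gross per-probe artifacts with a running-median/MAD filter.

    A probe is invalidated when its log-ratio deviates from the chromosome-wise
    running median (window of ``window`` probes) by more than ``k`` times the
    chromosome's scaled MAD of those deviations AND by more than
    ``min_log_dev``.  The absolute floor restricts the filter to
    order-of-magnitude hybridization artifacts: genuine origin peaks (ratios
    up to ~2) sit below it, and on a noise-free track nothing is flagged even
    though the MAD is then zero.  Values of surviving probes are untouched.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    out = track.copy()
    for name in track.grid.chrom_names:
        v, m = out.values[name], out.valid[name]
        if not m.any():
            continue
        logv = pd.Series(np.where(m, np.log(v, where=m, out=np.zeros_like(v)), np.nan))
        runmed = logv.rolling(window, center=True, min_periods=1).median().to_numpy()
        resid = np.abs(logv.to_numpy() - runmed)
        mad = 1.4826 * np.nanmedian(resid[m]) if m.any() else 0.0
        cutoff = max(k * mad, min_log_dev)
        bad = m & (resid > cutoff)
        out.valid[name] = m & ~bad
    return out


def baseline_correct(
    track: RatioTrack, fraction: float = 0.10, mode: str = "divide"
) -> tuple[RatioTrack, BaselineReport]:
    """Set the unreplicated baseline of a ratio track to 1.

    The median m of the lowest ``fraction`` of valid ratios estimates the
    unreplicated DNA level (in HU, a sizable share of the genome remains
    unreplicated and carries the lowest ratios).  In ``"divide"`` mode every
    ratio is divided by m; in ``"subtract"`` mode ``m - 1`` is subtracted.
    Either way the reported correction factor is ``m - 1`` and, after
    correction, the lowest-decile median equals 1 exactly.
    """
    if mode not in ("divide", "subtract"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    vv = track.valid_values()
    if vv.size < 10:
        raise ValueError(f"need at least 10 valid probes, have {vv.size}")
    n_low = max(1, int(math.floor(fraction * vv.size)))
    lowest = np.sort(vv)[:n_low]
    m = float(np.median(lowest))
    out = track.copy()
    for name in out.grid.chrom_names:
        sel = out.valid[name]
        if mode == "divide":
            out.values[name][sel] = out.values[name][sel] / m
        else:
            out.values[name][sel] = out.values[name][sel] - (m - 1.0)
    return out, BaselineReport(
        median=m, factor=m - 1.0, fraction=fraction, n_used=n_low, mode=mode
    )


def normalize_condition(
    repeats: list[HybridizationPair],
    geomean_window: int = 5,
    outlier_k: float = 5.0,
    baseline_fraction: float = 0.10,
    baseline_mode: str = "divide",
) -> tuple[RatioTrack, BaselineReport]:
    """Full normalization of one condition from its dye-swapped repeat pairs.

    Order of operations: per-hybridization ratio -> 5-probe geometric mean ->
    dye-swap average -> outlier removal -> biological-repeat average ->
    baseline correction.  Returns the corrected ("non-smoothed") track that
    origin efficiencies are read from, together with the baseline report.
    """
    if not repeats:
        raise ValueError("need at least one hybridization pair")
    per_repeat: list[RatioTrack] = []
    for pair in repeats:
        t1, t2 = probe_ratio(pair)
        t1 = window_geomean(t1, geomean_window)
        t2 = window_geomean(t2, geomean_window)
        avg = average_replicates(t1, t2)
        per_repeat.append(remove_outliers(avg, k=outlier_k))
    track = per_repeat[0]
    for other in per_repeat[1:]:
        track = average_replicates(track, other)
    return baseline_correct(track, fraction=baseline_fraction, mode=baseline_mode)


def ratio_to_efficiency(ratio):
    """Origin efficiency (%) from a baseline-normalized copy-number ratio.

    ``efficiency = (ratio - 1) * 100``: a corrected copy number of 1.1 means
    the locus is replicated in 10% of cells.  Sub-baseline ratios give
    negative efficiencies and are reported as-is.
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ratios must be positive")
    out = (arr - 1.0) * 100.0
    return float(out) if np.isscalar(ratio) or arr.ndim == 0 else out


def efficiency_to_ratio(efficiency):
    """Inverse of :func:`ratio_to_efficiency`."""
    arr = np.asarray(efficiency, dtype=float)
    out = 1.0 + arr / 100.0
    return float(out) if np.isscalar(efficiency) or arr.ndim == 0 else out
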