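"""Regional (windowed) profiles along chromosomes and comparison statistics.

Replication efficiency domains are multi-hundred-kb chromosomal regions of
coherently high or low origin usage.  They are visualized and compared through
regional profiles: the mean of an origin-level quantity (efficiency in %, or
Cdc45 IP/input) over windows of 1000 probes (~250 kb), slid along each
chromosome.  Differences of regional profiles between conditions, deviation
histograms of a profile around its mean, Spearman rank correlations and
two-sided Welch t-tests quantify how a replication program is reorganized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calling import OriginSet
from .synthetic import ProbeGrid

__all__ = [
    "RegionalProfile",
    "ComparisonStats",
    "DeviationHistogram",
    "regional_profile",
    "difference_profile",
    "deviation_histogram",
    "spearman_rho",
    "ttest_two_sided",
]


@dataclass
class RegionalProfile:
    """Windowed averages of an origin-level quantity along chromosomes.

    Per chromosome, ``starts``/``ends`` give the bp coordinates of the first
    and last probe of each window and ``values`` the window mean; windows that
    contain no origin carry NaN (an empty window is flagged, never zero-
    filled, since zero would masquerade as 0% efficiency).
    """

    kind: str  # "efficiency" or "cdc45"
    window: int  # window width in probes
    step: int  # slide in probes
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    values: dict[str, np.ndarray]

    @property
    def chrom_names(self) -> list[str]:
        return list(self.values)

    def centers(self, chrom: str) -> np.ndarray:
        return 0.5 * (self.starts[chrom] + self.ends[chrom])

    def all_values(self, drop_empty: bool = True) -> np.ndarray:
        v = np.concatenate([self.values[c] for c in self.values])
        return v[~np.isnan(v)] if drop_empty else v

    def compatible_with(self, other: "RegionalProfile") -> bool:
        return (
            self.window == other.window
            and self.step == other.step
            and list(self.values) == list(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )


@dataclass(frozen=True)
class ComparisonStats:
    """A Spearman rank correlation and/or a two-sided Welch t-test result."""

    n: int
    rho: float | None = None
    rho_p: float | None = None
    t_stat: float | None = None
    t_p: float | None = None
    note: str = ""

    @property
    def flagged(self) -> bool:
        return bool(self.note)


@dataclass(frozen=True)
class DeviationHistogram:
    """Histogram of regional-profile deviations from the profile mean."""

    counts: np.ndarray
    edges: np.ndarray
    deviations: np.ndarray

    @property
    def variance(self) -> float:
        return float(np.var(self.deviations))


def regional_profile(
    origins: OriginSet,
    grid: ProbeGrid,
    values: np.ndarray | None = None,
    window: int = 1000,
    step: int = 1,
    tiled: bool = False,
    kind: str = "efficiency",
) -> RegionalProfile:
    """Windowed mean of per-origin values along each chromosome.

    Origins are mapped to their nearest grid probe; each window of ``window``
    consecutive probes averages the values of the origins it contains, sliding
    by ``step`` probes (``tiled=True`` uses non-overlapping windows, i.e.
    ``step = window``).  A window larger than a chromosome degenerates to a
    single truncated window covering the whole chromosome.
    """
    if values is None:
        values = origins.efficiencies()
    values = np.asarray(values, dtype=float)
    if len(values) != len(origins):
        raise ValueError("values must align with origins")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if tiled:
        step = window

    # per-probe accumulation of origin values
    sums = {n: np.zeros(len(grid.positions[n])) for n in grid.chrom_names}
    counts = {n: np.zeros(len(grid.positions[n])) for n in grid.chrom_names}
    for call, val in zip(origins, values):
        if np.isnan(val):
            continue
        j = grid.nearest_probe(call.chrom, call.position)
        sums[call.chrom][j] += val
        counts[call.chrom][j] += 1

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    for name in grid.chrom_names:
        pos = grid.positions[name]
        n = len(pos)
        w = min(window, n)
        cs = np.concatenate([[0.0], np.cumsum(sums[name])])
        cc = np.concatenate([[0.0], np.cumsum(counts[name])])
        lo = np.arange(0, n - w + 1, step)
        hi = lo + w
        wsum = cs[hi] - cs[lo]
        wcount = cc[hi] - cc[lo]
        with np.errstate(invalid="ignore"):
            mean = np.where(wcount > 0, wsum / np.maximum(wcount, 1), np.nan)
        starts[name] = pos[lo].astype(float)
        ends[name] = pos[hi - 1].astype(float)
        means[name] = mean
    return RegionalProfile(
        kind=kind, window=window, step=step, starts=starts, ends=ends, values=means
    )


def difference_profile(a: RegionalProfile, b: RegionalProfile) -> RegionalProfile:
    """Per-window difference ``a - b`` of two aligned regional profiles.

    Windows empty in either input are empty in the output.  Profiles must
    share grid, window and step.
    """
    if not a.compatible_with(b):
        raise ValueError("profiles have mismatched windows and cannot be differenced")
    values = {c: a.values[c] - b.values[c] for c in a.values}
    return RegionalProfile(
        kind=f"{a.kind}-difference",
        window=a.window,
        step=a.step,
        starts={c: a.starts[c].copy() for c in a.starts},
        ends={c: a.ends[c].copy() for c in a.ends},
        values=values,
    )


def deviation_histogram(profile: RegionalProfile, bins: int = 20) -> DeviationHistogram:
    """Histogram of each window's deviation from the profile's overall mean.

    A bimodal deviation histogram is the signature of distinct high- and
    low-efficiency domains; equalized programs give a unimodal, narrower one.
    """
    v = profile.all_values(drop_empty=True)
    if v.size == 0:
        raise ValueError("profile has no non-empty windows")
    dev = v - v.mean()
    counts, edges = np.histogram(dev, bins=bins)
    return DeviationHistogram(counts=counts, edges=edges, deviations=dev)


def _paired_finite(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be aligned")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman_rho(x, y) -> ComparisonStats:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    NaN pairs are dropped.  Constant input yields an undefined rho, returned
    as NaN with a note.
    """
    x, y = _paired_finite(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ComparisonStats(n=int(x.size), rho=float("nan"), rho_p=float("nan"),
                               note="constant input: rho undefined")
    res = stats.spearmanr(x, y)
    return ComparisonStats(n=int(x.size), rho=float(res.statistic), rho_p=float(res.pvalue))


def ttest_two_sided(a, b, equal_var: bool = False) -> ComparisonStats:
    """Independent-samples t-test, two-sided (Welch by default).

    ``equal_var=True`` selects the pooled-variance variant.  Two zero-variance
    samples yield an undefined statistic, returned as NaN with a note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    n = int(a.size + b.size)
    if np.var(a) == 0 and np.var(b) == 0:
        if float(a.mean()) == float(b.mean()):
            return ComparisonStats(n=n, t_stat=0.0, t_p=1.0,
                                   note="zero variance in both samples")
        return ComparisonStats(n=n, t_stat=float("nan"), t_p=float("nan"),
                               note="zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonStats(n=n, t_stat=float(res.statistic), t_p=float(res.pvalue))
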