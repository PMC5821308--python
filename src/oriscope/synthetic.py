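"""Synthetic genomes, origin maps, and simulated array/combing data.

This module generates inputs with the statistical structure that the analysis
pipeline assumes, so that every downstream stage can be validated by parameter
recovery against a known ground truth:

* a tiling-array probe grid (~250 bp spacing, fission-yeast-like genome of
  three chromosomes),
* an origin map with per-origin firing efficiencies (% of cells in which the
  origin fires), optionally organized in alternating low/high efficiency
  domains along the chromosomes,
* dye-swapped two-channel hybridization pairs of S-phase-in-hydroxyurea
  against unreplicated DNA.  Hydroxyurea stalls forks near initiation sites;
  because stalling distances vary between cells, the population-average
  replicated fraction around a fired origin is fully replicated within a
  short core and decays linearly to zero at the maximal extent (~7 kb by
  default, within the 10-15 kb the assay can reach),
* Cdc45 pre-initiation-complex occupancy tracks whose origin-level signal is
  proportional to efficiency, and
* single-molecule (combed) DNA fibers on which each covered origin fires
  independently with probability efficiency/100, yielding BrdU-labeled tracks.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CHROMOSOMES",
    "DEFAULT_PROBE_SPACING",
    "ProbeGrid",
    "TruthOriginMap",
    "Hybridization",
    "HybridizationPair",
    "FiberRecord",
    "make_genome",
    "place_origins",
    "expected_ratio",
    "simulate_hu_pair",
    "simulate_cdc45_track",
    "simulate_fibers",
]

#: Fission-yeast-like default genome: three chromosomes of 5.6, 4.5 and 2.5 Mb.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 5_600_000),
    ("chrII", 4_500_000),
    ("chrIII", 2_500_000),
)

#: Default probe spacing in bp (60-mer oligos every ~250 nt on the array).
DEFAULT_PROBE_SPACING: int = 250


@dataclass(frozen=True)
class ProbeGrid:
    """Ordered per-chromosome probe coordinates defining the signal lattice.

    Positions are 1-based bp, strictly increasing within each chromosome and
    contained in ``[1, chromosome length]``.
    """

    chromosomes: tuple[tuple[str, int], ...]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if sorted(self.positions) != sorted(names):
            raise ValueError("positions must cover exactly the declared chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            pos = np.asarray(self.positions[name])
            if pos.ndim != 1 or len(pos) == 0:
                raise ValueError(f"chromosome {name!r} has no probes")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions on {name!r} are not strictly increasing")
            if pos[0] < 1 or pos[-1] > length:
                raise ValueError(f"probe positions on {name!r} fall outside [1, {length}]")

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for cname, length in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(name)

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def nearest_probe(self, chrom: str, position: float) -> int:
        """Index (within the chromosome) of the probe nearest to ``position``."""
        pos = self.positions[chrom]
        i = int(np.searchsorted(pos, position))
        if i == 0:
            return 0
        if i >= len(pos):
            return len(pos) - 1
        return i if pos[i] - position < position - pos[i - 1] else i - 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeGrid):
            return NotImplemented
        return self.chromosomes == other.chromosomes and all(
            np.array_equal(self.positions[n], other.positions[n]) for n in self.positions
        )


@dataclass
class TruthOriginMap:
    """Ground-truth origin locations and firing efficiencies.

    ``origins`` has columns ``chrom``, ``position`` (bp), ``efficiency``
    (percent of cells firing, in [0, 100]) and ``domain`` (region tag, may be
    empty).  Rows are sorted by (chrom, position) in the chromosome order of
    the generating grid.
    """

    origins: pd.DataFrame
    replication_extent_kb: float = 7.0  # maximal fork reach from the origin
    core_kb: float = 2.0  # half-width of the fully replicated core
    min_spacing: int = 0

    def __post_init__(self) -> None:
        eff = self.origins["efficiency"].to_numpy()
        if np.any((eff < 0) | (eff > 100)):
            raise ValueError("efficiencies must lie in [0, 100]")
        for _, sub in self.origins.groupby("chrom", sort=False):
            d = np.diff(sub["position"].to_numpy())
            if np.any(d <= 0):
                raise ValueError("origins must be sorted and unique per chromosome")
            if self.min_spacing and np.any(d < self.min_spacing):
                raise ValueError("origin spacing below the configured minimum")

    def __len__(self) -> int:
        return len(self.origins)

    def scaled(self, factor: float) -> "TruthOriginMap":
        """Uniformly scale all efficiencies by ``factor`` (clipped to 100%)."""
        df = self.origins.copy()
        df["efficiency"] = np.clip(df["efficiency"] * factor, 0.0, 100.0)
        return TruthOriginMap(df, self.replication_extent_kb, self.core_kb, self.min_spacing)

    def pulled_to_mean(self, factor: float) -> "TruthOriginMap":
        """Pull every efficiency toward the genome mean: m + factor*(e - m).

        ``factor`` < 1 equalizes efficiencies between domains, emulating the
        effect of extending G1 before S-phase entry.
        """
        df = self.origins.copy()
        m = df["efficiency"].mean()
        df["efficiency"] = np.clip(m + factor * (df["efficiency"] - m), 0.0, 100.0)
        return TruthOriginMap(df, self.replication_extent_kb, self.core_kb, self.min_spacing)


@dataclass
class Hybridization:
    """One two-channel hybridization aligned to a probe grid.

    ``ch1``/``ch2`` are per-probe channel intensities.  For a non-swapped
    hybridization ch1 carries the replicated (S in HU) sample and ch2 the
    unreplicated sample; a dye swap exchanges the two.
    """

    grid: ProbeGrid
    ch1: dict[str, np.ndarray]
    ch2: dict[str, np.ndarray]
    swapped: bool


@dataclass
class HybridizationPair:
    """Two dye-swapped hybridizations of the same biological sample."""

    first: Hybridization
    second: Hybridization

    def __post_init__(self) -> None:
        if self.first.grid != self.second.grid:
            raise ValueError("both hybridizations must share one probe grid")

    @property
    def grid(self) -> ProbeGrid:
        return self.first.grid


@dataclass
class FiberRecord:
    """A single combed DNA molecule with BrdU-labeled intervals (kb).

    ``chrom``/``start_bp`` record where a synthetic fiber was drawn from; for
    fibers measured on real slides the genomic source is unknown and the
    fields stay empty/NaN.
    """

    fiber_id: str
    length_kb: float
    intervals: list[tuple[float, float]] = field(default_factory=list)
    chrom: str = ""
    start_bp: float = float("nan")

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ValueError("fiber length must be positive")
        prev_end = -math.inf
        for start, end in self.intervals:
            if not (0.0 <= start < end <= self.length_kb):
                raise ValueError(
                    f"interval ({start}, {end}) outside fiber [0, {self.length_kb}]"
                )
            if start < prev_end:
                raise ValueError("labeled intervals must be sorted and non-overlapping")
            prev_end = end


def make_genome(
    chrom_lengths: list[int] | tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES,
    probe_spacing: int = DEFAULT_PROBE_SPACING,
    seed: int = 0,
    jitter: int = 0,
    names: list[str] | None = None,
) -> ProbeGrid:
    """Build a probe grid with (approximately) regular spacing.

    Without jitter, probes sit at ``spacing, 2*spacing, ...`` so each
    chromosome carries ``floor(length / spacing)`` probes.  With ``jitter``,
    each position is perturbed by a uniform integer offset in ``[-jitter,
    jitter]`` and then forced back to a strictly increasing, in-bounds lattice.
    """
    if probe_spacing <= 0:
        raise ValueError("probe spacing must be positive")
    if isinstance(chrom_lengths[0], (tuple, list)):
        chroms = tuple((str(n), int(length)) for n, length in chrom_lengths)
    else:
        if names is None:
            names = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
        chroms = tuple((n, int(length)) for n, length in zip(names, chrom_lengths))
    for name, length in chroms:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    for name, length in chroms:
        n = length // probe_spacing
        if n == 0:
            raise ValueError(f"chromosome {name!r} shorter than one probe spacing")
        pos = (np.arange(1, n + 1) * probe_spacing).astype(np.int64)
        if jitter:
            pos = pos + rng.integers(-jitter, jitter + 1, size=n)
            pos = np.clip(pos, 1, length)
            # restore strict monotonicity where jitter caused collisions
            pos = np.maximum.accumulate(pos)
            dup = np.flatnonzero(np.diff(pos) == 0)
            while dup.size:
                pos[dup + 1] += 1
                pos = np.minimum(pos, length)
                pos = np.maximum.accumulate(pos)
                dup = np.flatnonzero(np.diff(pos) == 0)
        positions[name] = pos
    return ProbeGrid(chromosomes=chroms, positions=positions)


def _allocate(counts_total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``counts_total`` by ``weights``."""
    quota = counts_total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = counts_total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def place_origins(
    grid: ProbeGrid,
    n_origins: int = 300,
    efficiency_model: str = "domain-structured",
    min_spacing: int = 20_000,
    seed: int = 0,
    *,
    domain_means: tuple[float, float] = (15.0, 35.0),
    uniform_mean: float = 25.0,
    efficiency_sd: float = 8.0,
    efficiency_range: tuple[float, float] = (2.0, 70.0),
    segments_per_chromosome: int = 2,
    replication_extent_kb: float = 7.0,
    core_kb: float = 2.0,
) -> TruthOriginMap:
    """Place origins on the grid with known efficiencies.

    ``efficiency_model`` is ``"domain-structured"`` (contiguous chromosome
    segments alternate between a low-mean and a high-mean normal efficiency
    distribution, giving the regional profile genuine peaks and troughs) or
    ``"uniform"`` (one normal distribution around ``uniform_mean``).
    Efficiencies are clipped to ``efficiency_range``.  Origins are at least
    ``min_spacing`` bp apart.
    """
    if efficiency_model not in ("domain-structured", "uniform"):
        raise ValueError(f"unknown efficiency model {efficiency_model!r}")
    if n_origins <= 0:
        raise ValueError("n_origins must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in grid.chromosomes], dtype=float)
    per_chrom = _allocate(n_origins, lengths)

    rows = []
    for (name, length), n in zip(grid.chromosomes, per_chrom):
        if n == 0:
            continue
        slack = length - 1 - (n - 1) * min_spacing
        if slack <= 0:
            raise ValueError(
                f"cannot pack {n} origins with spacing {min_spacing} on {name!r} ({length} bp)"
            )
        offsets = np.sort(rng.uniform(0, slack, size=n))
        pos = (1 + offsets + np.arange(n) * min_spacing).astype(np.int64)
        seg_len = length / segments_per_chromosome
        for k, p in enumerate(pos):
            if efficiency_model == "uniform":
                mean, domain = uniform_mean, ""
            else:
                seg = min(int(p // seg_len), segments_per_chromosome - 1)
                # alternate the phase between chromosomes so domains vary
                low_first = (grid.chrom_names.index(name) % 2) == 0
                is_low = (seg % 2 == 0) == low_first
                mean = domain_means[0] if is_low else domain_means[1]
                domain = "low" if is_low else "high"
            eff = float(np.clip(rng.normal(mean, efficiency_sd), *efficiency_range))
            rows.append((name, int(p), eff, domain))

    df = pd.DataFrame(rows, columns=["chrom", "position", "efficiency", "domain"])
    df["chrom"] = pd.Categorical(df["chrom"], categories=grid.chrom_names, ordered=True)
    df = df.sort_values(["chrom", "position"], ignore_index=True)
    df["chrom"] = df["chrom"].astype(str)
    return TruthOriginMap(
        df,
        replication_extent_kb=replication_extent_kb,
        core_kb=core_kb,
        min_spacing=min_spacing,
    )


def expected_ratio(
    truth: TruthOriginMap, grid: ProbeGrid, baseline_offset: float = 0.0
) -> dict[str, np.ndarray]:
    """Noise-free expected replicated/unreplicated ratio per probe.

    Each origin contributes ``efficiency/100`` times a distance shape that is
    1 within ``core_kb`` of the origin (fully replicated core) and decays
    linearly to 0 at ``replication_extent_kb`` (per-cell variability in how
    far forks progress before HU stalls them).  Contributions of overlapping
    origins are summed and capped at 1 (a probe cannot be replicated in more
    than 100% of cells).  The ratio is
    ``(1 + baseline_offset) * (1 + replicated fraction)``.
    """
    if baseline_offset < 0:
        raise ValueError("baseline offset must be >= 0")
    extent = truth.replication_extent_kb * 1000.0
    core = truth.core_kb * 1000.0
    if not 0 <= core <= extent:
        raise ValueError("core_kb must lie in [0, replication_extent_kb]")
    out: dict[str, np.ndarray] = {}
    for name in grid.chrom_names:
        pos = grid.positions[name].astype(float)
        frac = np.zeros_like(pos)
        sub = truth.origins[truth.origins["chrom"] == name]
        for opos, eff in zip(sub["position"].to_numpy(), sub["efficiency"].to_numpy()):
            lo = np.searchsorted(pos, opos - extent)
            hi = np.searchsorted(pos, opos + extent, side="right")
            if lo >= hi:
                continue
            d = np.abs(pos[lo:hi] - opos)
            if extent > core:
                shape = np.clip((extent - d) / (extent - core), 0.0, 1.0)
            else:
                shape = (d <= extent).astype(float)
            frac[lo:hi] += (eff / 100.0) * shape
        np.minimum(frac, 1.0, out=frac)
        out[name] = (1.0 + baseline_offset) * (1.0 + frac)
    return out


def _lognormal_cv(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_hu_pair(
    truth: TruthOriginMap,
    grid: ProbeGrid,
    noise_cv: float = 0.05,
    dye_bias: float = 1.0,
    baseline_offset: float = 0.15,
    seed: int = 0,
    base_intensity: float = 1000.0,
) -> HybridizationPair:
    """Simulate a dye-swapped pair of HU copy-number hybridizations.

    Per probe and per hybridization, one multiplicative lognormal noise draw
    (mean 1, coefficient of variation ``noise_cv``) perturbs the replicated
    channel, so the measured two-channel ratio of each hybridization has CV
    ``noise_cv`` around the expected ratio.  ``dye_bias`` multiplies channel 1
    of the non-swapped hybridization only, emulating a dye-specific gain that
    the dye-swap design is meant to cancel.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    expected = expected_ratio(truth, grid, baseline_offset=baseline_offset)

    def one(swapped: bool, bias: float) -> Hybridization:
        ch1: dict[str, np.ndarray] = {}
        ch2: dict[str, np.ndarray] = {}
        for name in grid.chrom_names:
            n = len(grid.positions[name])
            rep = expected[name] * base_intensity * _lognormal_cv(rng, noise_cv, n)
            unrep = np.full(n, base_intensity)
            if swapped:
                ch1[name], ch2[name] = unrep, rep
            else:
                ch1[name], ch2[name] = rep * bias, unrep
        return Hybridization(grid=grid, ch1=ch1, ch2=ch2, swapped=swapped)

    return HybridizationPair(first=one(False, dye_bias), second=one(True, 1.0))


def simulate_cdc45_track(
    truth: TruthOriginMap,
    grid: ProbeGrid,
    gain: float = 0.01,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    background: float = 0.1,
    footprint_probes: int = 8,
    replicate: str = "1",
):
    """Simulate a per-probe Cdc45 IP/input occupancy track.

    The probe nearest each origin carries ``background + gain * efficiency``,
    decaying linearly to ``background`` over ``footprint_probes`` probes;
    overlapping footprints take the stronger signal.  Multiplicative lognormal
    noise with CV ``noise_cv`` is applied per probe.
    """
    from .chip import Cdc45Track  # local import: chip does not import synthetic

    if gain <= 0:
        raise ValueError("gain must be positive")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for name in grid.chrom_names:
        pos = grid.positions[name]
        v = np.full(len(pos), background, dtype=float)
        sub = truth.origins[truth.origins["chrom"] == name]
        for opos, eff in zip(sub["position"].to_numpy(), sub["efficiency"].to_numpy()):
            j = grid.nearest_probe(name, opos)
            lo = max(0, j - footprint_probes)
            hi = min(len(pos), j + footprint_probes + 1)
            k = np.abs(np.arange(lo, hi) - j)
            peak = background + gain * eff * np.clip(1.0 - k / footprint_probes, 0.0, 1.0)
            v[lo:hi] = np.maximum(v[lo:hi], peak)
        v *= _lognormal_cv(rng, noise_cv, len(v))
        values[name] = v
    return Cdc45Track(grid=grid, values=values, replicate=replicate)


def simulate_fibers(
    truth: TruthOriginMap,
    grid: ProbeGrid,
    n_fibers: int = 30,
    fiber_length_kb: tuple[float, float] = (150.0, 400.0),
    track_halfwidth_kb: float = 3.0,
    seed: int = 0,
) -> list[FiberRecord]:
    """Simulate combed DNA fibers with BrdU tracks at fired origins.

    Each fiber is a random genomic window (chromosome chosen by length, start
    uniform, length uniform in ``fiber_length_kb``).  Every origin inside the
    window fires independently with probability ``efficiency / 100``; a fired
    origin yields a labeled interval of half-width ``track_halfwidth_kb``
    clipped to the fiber.  Overlapping raw intervals are unioned.
    """
    if n_fibers <= 0:
        raise ValueError("n_fibers must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in grid.chromosomes], dtype=float)
    pchrom = lengths / lengths.sum()
    fibers: list[FiberRecord] = []
    for i in range(n_fibers):
        ci = rng.choice(len(lengths), p=pchrom)
        cname, clen = grid.chromosomes[ci]
        flen_kb = float(rng.uniform(*fiber_length_kb))
        flen_kb = min(flen_kb, clen / 1000.0)
        start_bp = float(rng.uniform(0, clen - flen_kb * 1000.0))
        end_bp = start_bp + flen_kb * 1000.0
        sub = truth.origins[
            (truth.origins["chrom"] == cname)
            & (truth.origins["position"] >= start_bp)
            & (truth.origins["position"] <= end_bp)
        ]
        raw: list[tuple[float, float]] = []
        for opos, eff in zip(sub["position"].to_numpy(), sub["efficiency"].to_numpy()):
            if rng.random() < eff / 100.0:
                center = (opos - start_bp) / 1000.0
                s = max(0.0, center - track_halfwidth_kb)
                e = min(flen_kb, center + track_halfwidth_kb)
                if e > s:
                    raw.append((s, e))
        raw.sort()
        merged: list[tuple[float, float]] = []
        for s, e in raw:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        fibers.append(
            FiberRecord(
                fiber_id=f"fiber{i:04d}",
                length_kb=flen_kb,
                intervals=merged,
                chrom=cname,
                start_bp=start_bp,
            )
        )
    return fibers
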