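"""Origin identification and efficiency assignment from copy-number tracks.

Origins appear as peaks of increased copy number in S-phase-in-HU samples.
The calling chain is:

1. iterative smoothing: the 5-probe moving geometric mean applied for 10
   rounds;
2. candidate peaks: strict local maxima (plateau ties resolved to the central
   probe) whose smoothed apex exceeds 1.05 and whose prominence over the
   higher flanking minimum is at least 0.01 (a deterministic stand-in for
   manual confirmation of peaks);
3. efficiency assignment from the *non-smoothed* baseline-corrected track:
   each candidate takes the maximum raw ratio within +/-2 probes of its apex,
   candidates below copy number 1.1 (10% efficiency) are discarded;
4. merging: origins less than 5 kb apart are considered a single origin and
   assigned to the position with the higher copy number (the replicated
   extent around an origin in HU can reach 10-15 kb, so sub-5-kb peaks are
   not independent initiation sites).

Origins from two datasets are considered the same site when their positions
are within 5 kb of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .copy_number import RatioTrack, ratio_to_efficiency, window_geomean
from .synthetic import ProbeGrid

__all__ = [
    "OriginCall",
    "OriginSet",
    "Candidate",
    "MatchResult",
    "iterative_smooth",
    "detect_candidate_peaks",
    "assign_efficiency",
    "merge_close_origins",
    "match_origins",
    "augment_origin_list",
    "efficiencies_at_fixed_list",
    "call_origins",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OriginCall:
    """A called replication initiation site."""

    chrom: str
    position: int  # bp, on a grid probe
    copy_number: float  # raw (non-smoothed) corrected ratio at the apex
    efficiency: float  # (copy_number - 1) * 100, percent of cells firing
    provenance: str = "de-novo"  # or "supplemental-list"


@dataclass
class OriginSet:
    """An ordered collection of origin calls for one condition."""

    calls: list[OriginCall] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: (c.chrom, c.position))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __getitem__(self, i: int) -> OriginCall:
        return self.calls[i]

    def efficiencies(self) -> np.ndarray:
        return np.array([c.efficiency for c in self.calls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.chrom, c.position, c.copy_number, c.efficiency, c.provenance)
                for c in self.calls
            ],
            columns=["chrom", "position", "copy_number", "efficiency_pct", "provenance"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "OriginSet":
        calls = [
            OriginCall(
                chrom=str(r.chrom),
                position=int(r.position),
                copy_number=float(r.copy_number),
                efficiency=float(r.efficiency_pct),
                provenance=str(getattr(r, "provenance", "de-novo")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(calls=calls, label=label)


@dataclass(frozen=True)
class Candidate:
    """A candidate peak on the smoothed track."""

    chrom: str
    index: int  # probe index within the chromosome
    position: int  # bp
    height: float  # smoothed apex value


@dataclass
class MatchResult:
    """Outcome of matching two origin sets by position."""

    pairs: list[tuple[OriginCall, OriginCall, float]]
    a_only: list[OriginCall]
    b_only: list[OriginCall]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def iterative_smooth(track: RatioTrack, rounds: int = 10, window: int = 5) -> RatioTrack:
    """Apply the moving geometric mean ``rounds`` times (0 returns the input)."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    out = track
    for _ in range(rounds):
        out = window_geomean(out, window)
    return out


def detect_candidate_peaks(
    smoothed: RatioTrack, threshold: float = 1.05, prominence: float = 0.01
) -> list[Candidate]:
    """Find candidate origin peaks on a smoothed track.

    A candidate is a probe that is a strict local maximum (plateaus resolved
    to the central probe, left-of-center for even plateau widths), with apex
    value strictly above ``threshold`` and prominence of at least
    ``prominence`` over the higher flanking minimum.  Invalid probes are
    bridged by linear interpolation before peak finding so that isolated
    flagged probes cannot split a peak.
    """
    candidates: list[Candidate] = []
    for name in smoothed.grid.chrom_names:
        v = smoothed.values[name].astype(float).copy()
        ok = smoothed.valid[name]
        if not ok.any():
            continue
        if not ok.all():
            idx = np.arange(len(v))
            v[~ok] = np.interp(idx[~ok], idx[ok], v[ok])
        peaks, _ = find_peaks(v, prominence=prominence if prominence > 0 else None)
        pos = smoothed.grid.positions[name]
        for p in peaks:
            if v[p] > threshold and ok[p]:
                candidates.append(
                    Candidate(chrom=name, index=int(p), position=int(pos[p]), height=float(v[p]))
                )
    return candidates


def assign_efficiency(
    candidates: list[Candidate],
    raw_track: RatioTrack,
    cutoff: float = 1.1,
    halfwidth: int = 2,
    label: str = "",
    provenance: str = "de-novo",
) -> OriginSet:
    """Assign efficiencies to candidates from the non-smoothed track.

    Each candidate takes the maximum valid raw ratio within ``halfwidth``
    probes of its apex; candidates whose value falls below ``cutoff``
    (copy number 1.1 = 10% efficiency) are discarded.
    """
    calls: list[OriginCall] = []
    for cand in candidates:
        v = raw_track.values[cand.chrom]
        m = raw_track.valid[cand.chrom]
        lo = max(0, cand.index - halfwidth)
        hi = min(len(v), cand.index + halfwidth + 1)
        window_vals = v[lo:hi][m[lo:hi]]
        if window_vals.size == 0:
            continue
        cn = float(window_vals.max())
        if cn < cutoff:
            continue
        calls.append(
            OriginCall(
                chrom=cand.chrom,
                position=cand.position,
                copy_number=cn,
                efficiency=ratio_to_efficiency(cn),
                provenance=provenance,
            )
        )
    return OriginSet(calls=calls, label=label)


def merge_close_origins(origins: OriginSet, min_sep: float = 5000.0) -> OriginSet:
    """Merge same-chromosome origins closer than ``min_sep`` bp.

    Applied iteratively (closest pair first; ties to the leftmost pair) until
    no pair remains below the separation; each merge keeps the member with the
    higher copy number (tie: leftmost).
    """
    calls = sorted(origins.calls, key=lambda c: (c.chrom, c.position))
    while True:
        best = None  # (distance, index)
        for i in range(len(calls) - 1):
            a, b = calls[i], calls[i + 1]
            if a.chrom != b.chrom:
                continue
            d = b.position - a.position
            if d < min_sep and (best is None or d < best[0]):
                best = (d, i)
        if best is None:
            break
        i = best[1]
        a, b = calls[i], calls[i + 1]
        keep = a if a.copy_number >= b.copy_number else b
        calls[i : i + 2] = [keep]
    return OriginSet(calls=calls, label=origins.label)


def match_origins(a: OriginSet, b: OriginSet, tol: float = 5000.0) -> MatchResult:
    """Greedy one-to-one matching of origins between two sets.

    Same-chromosome pairs are considered in order of increasing distance; a
    pair is matched when both members are still free and their distance is
    strictly below ``tol``.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, ca in enumerate(a.calls):
        for j, cb in enumerate(b.calls):
            if ca.chrom != cb.chrom:
                continue
            d = abs(ca.position - cb.position)
            if d < tol:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[OriginCall, OriginCall, float]] = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((a.calls[i], b.calls[j], float(d)))
    a_only = [c for i, c in enumerate(a.calls) if i not in used_a]
    b_only = [c for j, c in enumerate(b.calls) if j not in used_b]
    return MatchResult(pairs=matched, a_only=a_only, b_only=b_only)


def call_origins(
    track: RatioTrack,
    rounds: int = 10,
    window: int = 5,
    threshold: float = 1.05,
    prominence: float = 0.01,
    cutoff: float = 1.1,
    merge_bp: float = 5000.0,
    label: str = "",
    provenance: str = "de-novo",
) -> OriginSet:
    """Full de-novo calling on a baseline-corrected track.

    Smooth (``rounds`` x ``window``-probe geometric mean), detect candidate
    peaks above ``threshold``, read efficiencies off the raw track with the
    ``cutoff`` applied, then merge origins closer than ``merge_bp``.
    """
    smoothed = iterative_smooth(track, rounds=rounds, window=window)
    cands = detect_candidate_peaks(smoothed, threshold=threshold, prominence=prominence)
    oset = assign_efficiency(cands, track, cutoff=cutoff, label=label, provenance=provenance)
    return merge_close_origins(oset, min_sep=merge_bp)


def augment_origin_list(
    base: OriginSet,
    extra_track: RatioTrack,
    cutoff: float = 1.1,
    rounds: int = 10,
    threshold: float = 1.05,
    prominence: float = 0.01,
    merge_bp: float = 5000.0,
    match_tol: float = 5000.0,
) -> OriginSet:
    """Extend an origin list with sites found only in another condition.

    De-novo calls on ``extra_track`` (full pipeline) that do not match any
    base origin within ``match_tol`` are appended with provenance
    ``"supplemental-list"``; the union is re-sorted.  This mirrors building a
    fixed cross-condition origin list from a permissive condition in which
    otherwise-silent origins fire.
    """
    extra = call_origins(
        extra_track,
        rounds=rounds,
        threshold=threshold,
        prominence=prominence,
        cutoff=cutoff,
        merge_bp=merge_bp,
        provenance="supplemental-list",
    )
    res = match_origins(extra, base, tol=match_tol)
    new_calls = list(base.calls) + [replace(c, provenance="supplemental-list") for c in res.a_only]
    return OriginSet(calls=new_calls, label=base.label)


def efficiencies_at_fixed_list(
    origins: OriginSet, track: RatioTrack, window: int = 5
) -> np.ndarray:
    """Per-origin efficiencies read from a track at fixed origin positions.

    For each origin, the maximum valid ratio within the ``window``-probe
    window centered on the origin's nearest probe is converted to an
    efficiency.  Origins that do not sit exactly on a probe are assigned to
    the nearest probe (a warning is logged).  Origins whose window holds no
    valid probe yield NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive probe count")
    half = window // 2
    grid = track.grid
    out = np.full(len(origins), np.nan)
    n_off_grid = 0
    for i, call in enumerate(origins):
        pos = grid.positions[call.chrom]
        j = grid.nearest_probe(call.chrom, call.position)
        if pos[j] != call.position:
            n_off_grid += 1
        lo, hi = max(0, j - half), min(len(pos), j + half + 1)
        vals = track.values[call.chrom][lo:hi][track.valid[call.chrom][lo:hi]]
        if vals.size:
            out[i] = ratio_to_efficiency(float(vals.max()))
    if n_off_grid:
        logger.warning("%d of %d origins were off-grid; nearest probes used",
                       n_off_grid, len(origins))
    return out
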