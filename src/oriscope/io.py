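"""Readers and writers for the plain-text formats the pipeline touches.

Conventions: TSV coordinates are 1-based inclusive probe/origin positions;
BED and bedGraph are 0-based half-open.  Origins and probes are strandless
(the array design has no strand), so the BED strand column is ``"."``.
Round-trip identity (``read(write(x)) == x``) holds for every type.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import OriginSet
from .combing import IodSummary
from .copy_number import BaselineReport, RatioTrack
from .regional import ComparisonStats, RegionalProfile
from .synthetic import (
    FiberRecord,
    Hybridization,
    HybridizationPair,
    ProbeGrid,
    TruthOriginMap,
)

__all__ = [
    "write_hybridization_pair",
    "read_hybridization_pair",
    "write_ratio_track",
    "read_ratio_track",
    "write_origins_tsv",
    "read_origins_tsv",
    "write_origins_bed",
    "read_origins_bed",
    "write_truth_tsv",
    "write_truth_bed",
    "write_fibers",
    "read_fibers",
    "write_profile_tsv",
    "write_profile_bedgraph",
    "write_baseline_report",
    "write_iods",
    "write_stats_report",
    "grid_from_frame",
]


def _check_positions(df: pd.DataFrame) -> None:
    if (df["position"] < 1).any():
        raise ValueError("positions must be >= 1 (1-based coordinates)")


def grid_from_frame(df: pd.DataFrame, chrom_lengths: dict[str, int] | None = None) -> ProbeGrid:
    """Reconstruct a probe grid from a per-probe table.

    Chromosome order follows first appearance.  Lengths default to the last
    probe position of each chromosome unless ``chrom_lengths`` is given.
    """
    _check_positions(df)
    names = list(dict.fromkeys(df["chrom"].astype(str)))
    positions: dict[str, np.ndarray] = {}
    chroms = []
    for name in names:
        pos = df.loc[df["chrom"] == name, "position"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"duplicate probe positions on {name!r}")
        positions[name] = pos
        length = int(chrom_lengths[name]) if chrom_lengths else int(pos[-1])
        chroms.append((name, length))
    return ProbeGrid(chromosomes=tuple(chroms), positions=positions)


# -- hybridizations -----------------------------------------------------------

def write_hybridization_pair(pair: HybridizationPair, path: str | Path) -> None:
    """TSV with columns chrom, position, ch1, ch2, hyb (1|2), orientation."""
    grid = pair.grid
    frames = []
    for idx, hyb in enumerate((pair.first, pair.second), start=1):
        for name in grid.chrom_names:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "position": grid.positions[name],
                        "ch1": hyb.ch1[name],
                        "ch2": hyb.ch2[name],
                        "hyb": idx,
                        "orientation": "swapped" if hyb.swapped else "normal",
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_hybridization_pair(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> HybridizationPair:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _check_positions(df)
    grid = grid_from_frame(df[df["hyb"] == 1], chrom_lengths)
    hybs = []
    for idx in (1, 2):
        sub = df[df["hyb"] == idx]
        if sub.empty:
            raise ValueError(f"hybridization {idx} missing from {path}")
        swapped = sub["orientation"].iloc[0] == "swapped"
        ch1 = {n: sub.loc[sub["chrom"] == n, "ch1"].to_numpy(float) for n in grid.chrom_names}
        ch2 = {n: sub.loc[sub["chrom"] == n, "ch2"].to_numpy(float) for n in grid.chrom_names}
        hybs.append(Hybridization(grid=grid, ch1=ch1, ch2=ch2, swapped=swapped))
    return HybridizationPair(first=hybs[0], second=hybs[1])


# -- ratio tracks -------------------------------------------------------------

def write_ratio_track(track: RatioTrack, path: str | Path) -> None:
    """TSV with columns chrom, position, ratio, valid."""
    frames = [
        pd.DataFrame(
            {
                "chrom": name,
                "position": track.grid.positions[name],
                "ratio": track.values[name],
                "valid": track.valid[name].astype(int),
            }
        )
        for name in track.grid.chrom_names
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_ratio_track(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> RatioTrack:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    grid = grid_from_frame(df, chrom_lengths)
    values = {n: df.loc[df["chrom"] == n, "ratio"].to_numpy(float) for n in grid.chrom_names}
    if "valid" in df.columns:
        valid = {
            n: df.loc[df["chrom"] == n, "valid"].to_numpy().astype(bool)
            for n in grid.chrom_names
        }
    else:
        valid = {n: np.isfinite(values[n]) & (values[n] > 0) for n in grid.chrom_names}
    for n in grid.chrom_names:  # placeholder for invalid probes
        values[n] = np.where(valid[n], values[n], 1.0)
    return RatioTrack(grid=grid, values=values, valid=valid)


# -- origin sets --------------------------------------------------------------

def write_origins_tsv(origins: OriginSet, path: str | Path) -> None:
    origins.to_frame().to_csv(path, sep="\t", index=False)


def read_origins_tsv(path: str | Path, label: str = "") -> OriginSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _check_positions(df)
    return OriginSet.from_frame(df, label=label)


def write_origins_bed(origins: OriginSet, path: str | Path) -> None:
    """BED6, 0-based half-open single-probe intervals, score = efficiency x 10."""
    with open(path, "w") as fh:
        for i, c in enumerate(origins):
            fh.write(
                f"{c.chrom}\t{c.position - 1}\t{c.position}\tori{i + 1:04d}"
                f"\t{int(round(c.efficiency * 10))}\t.\n"
            )


def read_origins_bed(path: str | Path, label: str = "") -> OriginSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, _name, score = line.split("\t")[:5]
            if int(start) < 0:
                raise ValueError("negative BED start coordinate")
            eff = int(score) / 10.0
            rows.append((chrom, int(start) + 1, 1.0 + eff / 100.0, eff, "de-novo"))
    df = pd.DataFrame(
        rows, columns=["chrom", "position", "copy_number", "efficiency_pct", "provenance"]
    )
    return OriginSet.from_frame(df, label=label)


# -- truth maps ---------------------------------------------------------------

def write_truth_tsv(truth: TruthOriginMap, path: str | Path) -> None:
    truth.origins.to_csv(path, sep="\t", index=False)


def write_truth_bed(truth: TruthOriginMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(truth.origins.itertuples(index=False)):
            fh.write(
                f"{r.chrom}\t{r.position - 1}\t{r.position}\tori{i + 1:04d}"
                f"\t{int(round(r.efficiency * 10))}\t.\n"
            )


# -- fibers -------------------------------------------------------------------

def write_fibers(fibers: list[FiberRecord], path: str | Path) -> None:
    """TSV: fiber_id, length_kb, track_start_kb, track_end_kb (one row per
    interval; fibers without intervals get one row with empty bounds).
    Synthetic fibers additionally carry chrom and start_bp provenance."""
    rows = []
    for f in fibers:
        for s, e in f.intervals or [(np.nan, np.nan)]:
            rows.append((f.fiber_id, f.length_kb, s, e, f.chrom, f.start_bp))
    pd.DataFrame(
        rows,
        columns=["fiber_id", "length_kb", "track_start_kb", "track_end_kb", "chrom", "start_bp"],
    ).to_csv(path, sep="\t", index=False)


def read_fibers(path: str | Path) -> list[FiberRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    has_prov = "chrom" in df.columns
    fibers = []
    for fid, sub in df.groupby("fiber_id", sort=False):
        intervals = [
            (float(r.track_start_kb), float(r.track_end_kb))
            for r in sub.itertuples(index=False)
            if np.isfinite(r.track_start_kb)
        ]
        intervals.sort()
        chrom = str(sub["chrom"].iloc[0]) if has_prov and pd.notna(sub["chrom"].iloc[0]) else ""
        start = float(sub["start_bp"].iloc[0]) if has_prov else float("nan")
        fibers.append(
            FiberRecord(
                fiber_id=str(fid),
                length_kb=float(sub["length_kb"].iloc[0]),
                intervals=intervals,
                chrom=chrom,
                start_bp=start,
            )
        )
    return fibers


# -- profiles, reports --------------------------------------------------------

def write_profile_tsv(profile: RegionalProfile, path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "chrom": name,
                "window_start": profile.starts[name].astype(int),
                "window_end": profile.ends[name].astype(int),
                "center": profile.centers(name),
                "value": profile.values[name],
            }
        )
        for name in profile.chrom_names
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_profile_bedgraph(profile: RegionalProfile, path: str | Path) -> None:
    """bedGraph (0-based half-open); empty windows are skipped."""
    with open(path, "w") as fh:
        for name in profile.chrom_names:
            for s, e, v in zip(
                profile.starts[name], profile.ends[name], profile.values[name]
            ):
                if np.isnan(v):
                    continue
                fh.write(f"{name}\t{int(s) - 1}\t{int(e)}\t{v:.6g}\n")


def write_baseline_report(report: BaselineReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "lowest_decile_median": report.median,
                "correction_factor": report.factor,
                "fraction": report.fraction,
                "n_probes_used": report.n_used,
                "mode": report.mode,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_iods(summary: IodSummary, path: str | Path) -> None:
    """TSV of pooled IOD values plus a header line of summary fields."""
    with open(path, "w") as fh:
        fh.write(
            f"# condition={summary.label} n_iods={summary.n_iods} "
            f"n_fibers={summary.n_fibers} total_kb={summary.total_length_kb:.1f} "
            f"median_kb={summary.median_kb:.2f}\n"
        )
        fh.write("iod_kb\n")
        for v in summary.iods:
            fh.write(f"{v:.3f}\n")


def write_stats_report(rows: list[tuple[str, ComparisonStats]], path: str | Path) -> None:
    """TSV report of labeled comparisons (raw p-values; no multiple-testing
    correction is applied anywhere in the pipeline)."""
    df = pd.DataFrame(
        [
            (label, s.n, s.rho, s.rho_p, s.t_stat, s.t_p, s.note)
            for label, s in rows
        ],
        columns=["comparison", "n", "spearman_rho", "rho_p", "t_stat", "t_p", "note"],
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
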