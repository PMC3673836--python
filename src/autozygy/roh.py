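"""Runs-of-homozygosity calling from a window track, and F_ROH.

A run of homozygosity is called where at least two consecutive 1-Mbp
windows show reduced heterozygosity.  Called segments are then made
comparable with pedigree-simulation output by merging segments
separated by gaps smaller than 500 kbp and removing segments smaller
than 2 Mbp (merge first, then filter).  F_ROH is the summed ROH length
divided by the effective (unmasked, autosomal) genome size.

The heterozygosity threshold behind "reduced" is not a fixed constant
of the method: by default it is 0.25 x the genome-wide median density
of unmasked windows, which is scale-free with respect to the overall
diversity level; an absolute threshold can be supplied instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ROHSegment",
    "ROHCallset",
    "default_het_threshold",
    "call_roh",
    "postprocess_segments",
    "postprocess_intervals",
    "compute_f_roh",
    "summarize_callset",
]


@dataclass(frozen=True)
class ROHSegment:
    chrom: str
    start: int
    end: int
    n_windows: int = 0
    mean_het_per_kbp: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass(frozen=True)
class ROHCallset:
    segments: tuple[ROHSegment, ...]
    effective_genome: int

    @property
    def total_roh(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def f_roh(self) -> float:
        return self.total_roh / self.effective_genome


def default_het_threshold(windows: pd.DataFrame, factor: float = 0.25) -> float:
    """``factor`` x the median het density of unmasked, counted windows."""
    dens = windows.loc[~windows["masked_out"], "het_per_kbp"].dropna()
    if dens.empty:
        raise ValueError("no unmasked windows with a density to set a threshold from")
    return factor * float(dens.median())


def _eligible_tracks(windows: pd.DataFrame, min_size_fraction: float = 0.5):
    """Per-chromosome window arrays, dropping short windows (< half the
    nominal size); only the trailing window of a chromosome can be short."""
    nominal = int((windows["end"] - windows["start"]).max())
    for chrom, grp in windows.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("start")
        keep = (grp["end"] - grp["start"]) >= min_size_fraction * nominal
        yield chrom, grp.loc[keep]


def call_roh(
    windows: pd.DataFrame,
    het_threshold: float | None = None,
    min_windows: int = 2,
) -> list[ROHSegment]:
    """Maximal runs of >= ``min_windows`` consecutive low-het windows.

    A window is low-het when it is unmasked and its density is strictly
    below ``het_threshold``.  A single masked window inside a run is
    tolerated (it contributes neither to the window count nor to the
    density) but two or more consecutive masked windows break the run,
    as does any unmasked window at or above the threshold.  Segments
    span from the first to the last low-het window of the run.
    """
    if het_threshold is None:
        het_threshold = default_het_threshold(windows)
    if het_threshold <= 0:
        raise ValueError("het_threshold must be positive")

    segments: list[ROHSegment] = []
    for chrom, grp in _eligible_tracks(windows):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        masked = grp["masked_out"].to_numpy()
        dens = grp["het_per_kbp"].to_numpy(dtype=float)

        run: list[int] = []  # indices of low-het windows in current run
        masked_streak = 0

        def flush(run_idx: list[int]) -> None:
            if len(run_idx) >= min_windows:
                segments.append(
                    ROHSegment(
                        chrom=str(chrom),
                        start=int(starts[run_idx[0]]),
                        end=int(ends[run_idx[-1]]),
                        n_windows=len(run_idx),
                        mean_het_per_kbp=float(np.mean(dens[run_idx])),
                    )
                )

        for i in range(len(grp)):
            if masked[i]:
                masked_streak += 1
                if masked_streak >= 2:
                    flush(run)
                    run = []
                continue
            masked_streak = 0
            if dens[i] < het_threshold:
                run.append(i)
            else:
                flush(run)
                run = []
        flush(run)
    return segments


def postprocess_intervals(
    intervals: list[tuple[str, int, int]],
    min_length: int = 2_000_000,
    max_gap: int = 500_000,
) -> list[tuple[str, int, int]]:
    """Merge-then-filter on plain (chrom, start, end) tuples.

    Adjacent same-chromosome intervals separated by a gap strictly
    smaller than ``max_gap`` are merged (the merged span includes the
    gap); afterwards intervals shorter than ``min_length`` are removed.
    """
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged: list[list] = [list(ivs[0])]
    for chrom, s, e in ivs[1:]:
        last = merged[-1]
        if chrom == last[0] and s - last[2] < max_gap:
            last[2] = max(last[2], e)
        else:
            merged.append([chrom, s, e])
    return [(c, s, e) for c, s, e in merged if e - s >= min_length]


def postprocess_segments(
    segments: list[ROHSegment],
    min_length: int = 2_000_000,
    max_gap: int = 500_000,
) -> list[ROHSegment]:
    """Merge-then-filter for called segments (window metadata is
    recomputed as the sum/length-weighted mean over merged parts)."""
    if not segments:
        return []
    segs = sorted(segments, key=lambda s: (s.chrom, s.start))
    merged: list[dict] = []
    for s in segs:
        if merged and s.chrom == merged[-1]["chrom"] and s.start - merged[-1]["end"] < max_gap:
            m = merged[-1]
            w = m["n_windows"] + s.n_windows
            if w > 0 and not (np.isnan(m["mean_het"]) or np.isnan(s.mean_het_per_kbp)):
                m["mean_het"] = (
                    m["mean_het"] * m["n_windows"] + s.mean_het_per_kbp * s.n_windows
                ) / w
            m["n_windows"] = w
            m["end"] = max(m["end"], s.end)
        else:
            merged.append(
                dict(
                    chrom=s.chrom,
                    start=s.start,
                    end=s.end,
                    n_windows=s.n_windows,
                    mean_het=s.mean_het_per_kbp,
                )
            )
    return [
        ROHSegment(m["chrom"], m["start"], m["end"], m["n_windows"], m["mean_het"])
        for m in merged
        if m["end"] - m["start"] >= min_length
    ]


def compute_f_roh(segments: list[ROHSegment], effective_genome: int) -> ROHCallset:
    """Callset with F_ROH = total ROH length / effective genome size."""
    if effective_genome <= 0:
        raise ValueError("effective_genome must be positive")
    segs = tuple(sorted(segments, key=lambda s: (s.chrom, s.start)))
    prev: ROHSegment | None = None
    for s in segs:
        if prev is not None and s.chrom == prev.chrom and s.start < prev.end:
            raise RuntimeError("overlapping segments: post-processing contract violated")
        prev = s
    return ROHCallset(segs, effective_genome)


def summarize_callset(callset: ROHCallset, large_threshold: int = 2_000_000) -> dict:
    """Deterministic summary: totals, large-segment count, per-chromosome."""
    per_chrom: dict[str, int] = {}
    for s in callset.segments:
        per_chrom[s.chrom] = per_chrom.get(s.chrom, 0) + s.length
    return {
        "n_segments": len(callset.segments),
        "n_large": sum(1 for s in callset.segments if s.length > large_threshold),
        "largest": max((s.length for s in callset.segments), default=0),
        "total_roh": callset.total_roh,
        "effective_genome": callset.effective_genome,
        "f_roh": callset.f_roh,
        "per_chromosome": per_chrom,
    }


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    rows = [
        dict(
            chrom=s.chrom,
            start=s.start,
            end=s.end,
            length=s.length,
            n_windows=s.n_windows,
            mean_het_per_kbp=s.mean_het_per_kbp,
        )
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "length", "n_windows", "mean_het_per_kbp"],
    )


def write_summary_json(callset: ROHCallset, path, **extra) -> None:
    payload = summarize_callset(callset)
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
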